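"""Simulation rounds: the perceive -> decide -> move loop and its scoring.

A round runs one agent from a start position until it leaves the arena
("dies") or reaches the maximum lifespan ``T_max``.  Two objectives are
supported:

* ``survive`` — the score is the number of steps completed while staying
  inside the closed arena;
* ``explore`` — the score is the number of distinct grid cells entered at
  least once (the starting cell is credited at t=0; cells are credited
  from the agent position at integer time steps only, so cells flown over
  mid-step are not counted).

An agent evaluation is 4 scored rounds from supplied start positions with
the fixed initial headings ``(0, -pi, -pi/2, pi/2)``, plus a 5th
monitoring round from the arena centre with heading 0 whose score is
recorded for cross-generation comparison but never enters the fitness.

``evaluate_population`` is a vectorized equivalent of per-agent
``evaluate_agent`` used by the genetic algorithm; it advances every
(agent, round) walker in lock-step with numpy and produces the same
scores as the scalar loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .brain import BrainParams, forward, steering_angle
from .geometry import (
    TWO_PI,
    WALL_BEARINGS,
    AgentState,
    ArenaConfig,
    cell_index,
    perceive,
    step,
    wrap_angle,
)

#: Initial headings of the four scored rounds, in fixed order.
ROUND_HEADINGS = (0.0, -math.pi, -math.pi / 2.0, math.pi / 2.0)

OBJECTIVES = ("survive", "explore")


@dataclass
class RoundResult:
    """Outcome of one round of one agent.

    ``trajectory`` has one row per decision step (time, position, heading,
    wall cues and the turn taken from that state) plus a final row for the
    end state, whose ``delta_phi`` is NaN and whose wall cues are NaN if
    the agent died outside the arena.
    """

    trajectory: pd.DataFrame
    turns: np.ndarray
    steps_survived: int
    score: int
    turn_cost: float
    death_cause: str  # "wall" or "lifespan"
    objective: str


@dataclass
class EvaluationResult:
    """Aggregate of the 4 scored rounds plus the monitoring round."""

    total_score: float
    total_turn_cost: float
    penalized_score: float
    reference_score: float
    rounds: Sequence[RoundResult] | None = None


def _check_objective(objective: str) -> None:
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}; expected one of {OBJECTIVES}")


def exploration_credit(visited: set, cell: int):
    """Credit a cell on first visit.  Returns ``(visited, credited)``."""
    credited = cell not in visited
    visited.add(cell)
    return visited, credited


def run_round(
    params: BrainParams,
    arena: ArenaConfig,
    objective: str,
    start,
    heading0: float,
) -> RoundResult:
    """Run one full round from ``start`` with initial heading ``heading0``."""
    _check_objective(objective)
    x0, y0 = float(start[0]), float(start[1])
    state = AgentState(x=x0, y=y0, heading=heading0)
    if objective == "explore":
        exploration_credit(state.visited_cells, cell_index(x0, y0, arena))

    rows = []
    turns = []
    survive_score = 0
    death_cause = "lifespan"
    for t in range(arena.max_lifespan):
        p = perceive(state, arena)
        o1 = forward(params, p.wall_distance_norm, p.wall_angle_norm)
        dphi = steering_angle(o1, arena.steering_increment)
        rows.append(
            (t, state.x, state.y, state.heading, p.wall_distance, p.wall_angle, dphi, True)
        )
        turns.append(dphi)
        state = step(state, dphi, arena)
        if not state.alive:
            death_cause = "wall"
            break
        survive_score += 1
        if objective == "explore":
            exploration_credit(state.visited_cells, cell_index(state.x, state.y, arena))

    # terminal row: no decision is taken from the end state
    t_end = len(rows)
    if state.alive:
        p_end = perceive(state, arena)
        rows.append(
            (t_end, state.x, state.y, state.heading, p_end.wall_distance, p_end.wall_angle, np.nan, True)
        )
    else:
        rows.append((t_end, state.x, state.y, state.heading, np.nan, np.nan, np.nan, False))

    trajectory = pd.DataFrame(
        rows, columns=["time", "x", "y", "heading", "d_w", "theta_w", "delta_phi", "alive"]
    )
    score = survive_score if objective == "survive" else len(state.visited_cells)
    return RoundResult(
        trajectory=trajectory,
        turns=np.asarray(turns),
        steps_survived=survive_score,
        score=score,
        turn_cost=state.turn_cost_accum,
        death_cause=death_cause,
        objective=objective,
    )


def evaluate_agent(
    params: BrainParams,
    arena: ArenaConfig,
    objective: str,
    start_positions,
    keep_rounds: bool = False,
) -> EvaluationResult:
    """Run the 4 scored rounds plus the centre monitoring round.

    ``start_positions`` are the four scored-round starts; round ``k`` uses
    the fixed heading ``ROUND_HEADINGS[k]``.
    """
    start_positions = np.asarray(start_positions, dtype=float)
    if start_positions.shape != (4, 2):
        raise ValueError("start_positions must be four (x, y) points")
    rounds = []
    total_score = 0.0
    total_cost = 0.0
    for start, heading0 in zip(start_positions, ROUND_HEADINGS):
        result = run_round(params, arena, objective, start, heading0)
        total_score += result.score
        total_cost += result.turn_cost
        rounds.append(result)
    centre = (arena.side_length / 2.0, arena.side_length / 2.0)
    reference = run_round(params, arena, objective, centre, 0.0)
    rounds.append(reference)
    return EvaluationResult(
        total_score=total_score,
        total_turn_cost=total_cost,
        penalized_score=total_score - total_cost,
        reference_score=reference.score,
        rounds=rounds if keep_rounds else None,
    )


def evaluate_population(
    genomes: np.ndarray,
    n_hidden: int,
    arena: ArenaConfig,
    objective: str,
    start_positions: np.ndarray,
):
    """Vectorized evaluation of a whole population.

    Parameters
    ----------
    genomes : (n, 4*n_hidden+1) array
        One flat genome per agent (see :func:`steerevolve.brain.pack`).
    start_positions : (n, 4, 2) array
        Scored-round starts per agent (broadcast from (1, 4, 2) to share
        starts across agents).

    Returns
    -------
    dict with per-agent arrays ``total_score``, ``turn_cost``,
    ``penalized_score`` and ``reference_score``.
    """
    _check_objective(objective)
    genomes = np.asarray(genomes, dtype=float)
    n = genomes.shape[0]
    h = n_hidden
    if genomes.shape[1] != 4 * h + 1:
        raise ValueError("genome length does not match n_hidden")
    starts = np.broadcast_to(np.asarray(start_positions, dtype=float), (n, 4, 2))

    L = arena.side_length
    half = arena.max_wall_distance
    s = arena.speed
    i_steer = arena.steering_increment
    p_t = arena.turning_penalty
    n_side = arena.grid_cells_per_side
    cell = arena.cell_size
    bearings = np.asarray(WALL_BEARINGS)

    # walker layout: index = agent * 5 + round; rounds 0-3 scored, 4 = centre
    W = 5 * n
    agent_of = np.repeat(np.arange(n), 5)
    round_of = np.tile(np.arange(5), n)
    x = np.where(round_of < 4, starts[agent_of, np.minimum(round_of, 3), 0], L / 2.0)
    y = np.where(round_of < 4, starts[agent_of, np.minimum(round_of, 3), 1], L / 2.0)
    heading = wrap_angle(np.where(round_of < 4, np.asarray(ROUND_HEADINGS + (0.0,))[round_of], 0.0))

    # per-walker parameter views (same layout as brain.unpack)
    hw = genomes[agent_of, : 2 * h].reshape(W, h, 2)
    hb = genomes[agent_of, 2 * h : 3 * h]
    ow = genomes[agent_of, 3 * h : 4 * h]
    ob = genomes[agent_of, 4 * h]

    alive = np.ones(W, dtype=bool)
    survive_score = np.zeros(W, dtype=np.int64)
    turn_cost = np.zeros(W)
    if objective == "explore":
        visited = np.zeros((W, arena.n_cells), dtype=bool)
        col = np.minimum((x // cell).astype(np.int64), n_side - 1)
        row = np.minimum((y // cell).astype(np.int64), n_side - 1)
        visited[np.arange(W), row * n_side + col] = True

    for _ in range(arena.max_lifespan):
        if not alive.any():
            break
        # perception (left, right, bottom, top) with first-min tie-breaking
        d4 = np.stack((x, L - x, y, L - y))
        idx = np.argmin(d4, axis=0)
        d_w = d4[idx, np.arange(W)]
        theta_w = wrap_angle(heading - bearings[idx])
        dn = d_w / half
        tn = (theta_w + math.pi) / TWO_PI
        # network forward pass, written exactly as the scalar brain.forward
        z = hb + hw[:, :, 0] * dn[:, None] + hw[:, :, 1] * tn[:, None]
        hid = expit(z)
        o1 = expit(ob + np.sum(ow * hid, axis=-1))
        dphi = (o1 - 0.5) * i_steer

        new_heading = wrap_angle(heading + dphi)
        new_x = x + s * np.cos(new_heading)
        new_y = y + s * np.sin(new_heading)
        inside = (new_x >= 0.0) & (new_x <= L) & (new_y >= 0.0) & (new_y <= L)

        turn_cost = turn_cost + np.where(alive, p_t * dphi * dphi, 0.0)
        heading = np.where(alive, new_heading, heading)
        x = np.where(alive, new_x, x)
        y = np.where(alive, new_y, y)
        alive_after = alive & inside
        survive_score += alive_after
        if objective == "explore":
            live = np.flatnonzero(alive_after)
            if live.size:
                col = np.minimum((x[live] // cell).astype(np.int64), n_side - 1)
                row = np.minimum((y[live] // cell).astype(np.int64), n_side - 1)
                visited[live, row * n_side + col] = True
        alive = alive_after

    if objective == "explore":
        round_score = visited.sum(axis=1)
    else:
        round_score = survive_score

    round_score = round_score.reshape(n, 5)
    turn_cost = turn_cost.reshape(n, 5)
    total_score = round_score[:, :4].sum(axis=1).astype(float)
    total_cost = turn_cost[:, :4].sum(axis=1)
    return {
        "total_score": total_score,
        "turn_cost": total_cost,
        "penalized_score": total_score - total_cost,
        "reference_score": round_score[:, 4].astype(float),
    }


def write_trajectory(result: RoundResult, path) -> None:
    """Write a round trajectory as CSV (columns: time, x, y, heading,
    d_w, theta_w, delta_phi, alive)."""
    result.trajectory.to_csv(path, index=False)


def read_trajectory(path) -> pd.DataFrame:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    return pd.read_csv(path)
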