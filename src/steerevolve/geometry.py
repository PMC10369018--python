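"""Square-arena geometry: wall perception and kinematic state updates.

The arena is the closed square ``[0, L]^2`` with the origin at the
bottom-left corner, ``y`` increasing upward and angles measured
counterclockwise-positive, wrapped to ``(-pi, pi]``.  An agent perceives
two cues: its distance ``d_w`` to the closest point on any wall and the
signed angle ``theta_w`` between its heading and the bearing to that
point.  ``theta_w = 0`` means the agent faces the wall orthogonally;
``theta_w > 0`` means the wall lies clockwise of the heading, i.e. on
the agent's right-hand side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * math.pi

#: Fixed wall order used for tie-breaking: left (x=0), right (x=L),
#: bottom (y=0), top (y=L).  Bearings are the outward direction from an
#: interior point toward the closest point of each wall.
WALL_BEARINGS = (math.pi, 0.0, -math.pi / 2.0, math.pi / 2.0)


class DeadAgentError(ValueError):
    """Raised when a dead agent (outside the arena) is queried for perception."""


def wrap_angle(angle):
    """Wrap an angle (scalar or array, radians) to ``(-pi, pi]``."""
    wrapped = (np.asarray(angle) + math.pi) % TWO_PI - math.pi  # [-pi, pi)
    wrapped = np.where(wrapped == -math.pi, math.pi, wrapped)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class ArenaConfig:
    """Arena and locomotion parameters.

    Parameters
    ----------
    side_length : float
        Side of the square arena, in pixels.
    grid_cells_per_side : int
        The arena is discretized into ``grid_cells_per_side**2`` equal
        square cells for the exploration score (default 20, i.e. 400
        cells of 30 px).
    speed : float
        Constant displacement per time step, in pixels (slow condition: 5).
    steering_increment : float
        Maximum turning scale ``i_steering`` in ``[0, 2*pi]``; the turn per
        step is ``(o1 - 0.5) * i_steering``.
    max_lifespan : int
        Maximum number of time steps per round (``T_max``).
    turning_penalty : float
        Cost coefficient ``p_t >= 0``; each turn costs ``p_t * dphi**2``
        (penalty condition: 0.33).
    """

    side_length: float = 600.0
    grid_cells_per_side: int = 20
    speed: float = 50.0
    steering_increment: float = TWO_PI
    max_lifespan: int = 5000
    turning_penalty: float = 0.0

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.grid_cells_per_side < 1:
            raise ValueError("grid_cells_per_side must be >= 1")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if not 0.0 <= self.steering_increment <= TWO_PI:
            raise ValueError("steering_increment must lie in [0, 2*pi]")
        if self.max_lifespan < 0:
            raise ValueError("max_lifespan must be >= 0")
        if self.turning_penalty < 0:
            raise ValueError("turning_penalty must be >= 0")

    @property
    def n_cells(self) -> int:
        return self.grid_cells_per_side**2

    @property
    def cell_size(self) -> float:
        return self.side_length / self.grid_cells_per_side

    @property
    def max_wall_distance(self) -> float:
        """Largest possible distance to the nearest wall (arena centre)."""
        return self.side_length / 2.0


@dataclass
class AgentState:
    """Kinematic state of one agent."""

    x: float
    y: float
    heading: float
    alive: bool = True
    step_count: int = 0
    visited_cells: set = field(default_factory=set)
    turn_cost_accum: float = 0.0

    def __post_init__(self) -> None:
        self.heading = wrap_angle(self.heading)


@dataclass(frozen=True)
class Percept:
    """Wall cues as perceived by an agent, raw and normalized to [0, 1]."""

    wall_distance: float
    wall_angle: float
    wall_distance_norm: float
    wall_angle_norm: float


def _require_inside(x: float, y: float, arena: ArenaConfig) -> None:
    L = arena.side_length
    if not (0.0 <= x <= L and 0.0 <= y <= L):
        raise DeadAgentError(
            f"point ({x}, {y}) lies outside the closed arena [0, {L}]^2"
        )


def closest_wall(x: float, y: float, arena: ArenaConfig):
    """Closest boundary point and its distance for an interior point.

    Returns ``((wx, wy), distance)``.  Ties (centre, diagonals) are broken
    by the fixed wall order left, right, bottom, top.
    """
    _require_inside(x, y, arena)
    L = arena.side_length
    distances = (x, L - x, y, L - y)
    idx = int(np.argmin(distances))
    wall_point = ((0.0, y), (L, y), (x, 0.0), (x, L))[idx]
    return wall_point, float(distances[idx])


def perceive(state: AgentState, arena: ArenaConfig) -> Percept:
    """Compute the wall cues ``(d_w, theta_w)`` and their normalized forms.

    ``theta_w = wrap(heading - bearing)`` where the bearing is the direction
    from the agent to the closest wall point; ``d_w`` is normalized by
    ``L/2`` (the maximum distance-to-wall inside the square) and
    ``theta_w`` by mapping ``(-pi, pi] -> [0, 1]``.
    """
    if not state.alive:
        raise DeadAgentError("dead agent queried for perception")
    _require_inside(state.x, state.y, arena)
    L = arena.side_length
    distances = (state.x, L - state.x, state.y, L - state.y)
    idx = int(np.argmin(distances))
    d_w = float(distances[idx])
    theta_w = wrap_angle(state.heading - WALL_BEARINGS[idx])
    return Percept(
        wall_distance=d_w,
        wall_angle=theta_w,
        wall_distance_norm=d_w / arena.max_wall_distance,
        wall_angle_norm=(theta_w + math.pi) / TWO_PI,
    )


def step(state: AgentState, turn: float, arena: ArenaConfig) -> AgentState:
    """Advance one time step: turn first, then move with the new heading.

    The heading update precedes the position update, so the displacement
    uses the post-turn heading.  Crossing the arena boundary is a valid
    outcome that sets ``alive = False``; it is not an error.  The turning
    cost ``p_t * turn**2`` accrues on every step, including a killing one.
    """
    heading = wrap_angle(state.heading + turn)
    x = state.x + arena.speed * math.cos(heading)
    y = state.y + arena.speed * math.sin(heading)
    L = arena.side_length
    alive = (0.0 <= x <= L) and (0.0 <= y <= L)
    return AgentState(
        x=x,
        y=y,
        heading=heading,
        alive=alive,
        step_count=state.step_count + 1,
        visited_cells=state.visited_cells,
        turn_cost_accum=state.turn_cost_accum + arena.turning_penalty * turn * turn,
    )


def cell_index(x: float, y: float, arena: ArenaConfig) -> int:
    """Row-major index of the grid cell containing ``(x, y)``.

    Cells are half-open ``[a, b)`` in both axes, so interior edges belong to
    the higher-index cell; the far arena boundary belongs to the last cell.
    """
    _require_inside(x, y, arena)
    n = arena.grid_cells_per_side
    size = arena.cell_size
    col = min(int(x // size), n - 1)
    row = min(int(y // size), n - 1)
    return row * n + col
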