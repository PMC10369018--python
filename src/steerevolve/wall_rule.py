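"""The empirical fish wall-avoidance rule and network-structure validation.

Rummy-nose tetra avoid walls by turning away from them at short range; a
simplified closed form for the turn per step is the product of an odd
angular part and a Gaussian radial decay::

    dphi = sin(theta_w) * exp(-(d_w / l_w)**2)

with ``l_w`` the interaction range.  Under the sign convention used here
(``theta_w > 0`` means wall to the right), a positive ``dphi`` is a left
turn, i.e. away from the wall.

Networks of 1..6 hidden neurons are fitted to this rule by least squares
in output space (targets ``o1* = dphi / i_steering + 0.5``, the inverse
of the steering map), so the fitted object is directly a usable brain.
Comparing fit quality across sizes measures how many hidden neurons the
wall-avoidance task needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import brain
from .geometry import TWO_PI, ArenaConfig


@dataclass(frozen=True)
class EmpiricalRuleParams:
    """Interaction range ``l_w`` (pixels) of the wall-avoidance rule."""

    interaction_range: float = 60.0

    def __post_init__(self) -> None:
        if self.interaction_range <= 0:
            raise ValueError("interaction_range must be positive")


@dataclass
class RuleGrid:
    """Binned map over (theta_w, d_w) of mean turning angle.

    ``mean_turn`` is NaN where ``counts`` is zero (empty bins are flagged,
    never silently zero).
    """

    angle_bin_edges: np.ndarray  # (n_angle+1,) over (-pi, pi]
    distance_bin_edges: np.ndarray  # (n_dist+1,) over [0, L/2]
    mean_turn: np.ndarray  # (n_angle, n_dist)
    counts: np.ndarray  # (n_angle, n_dist)

    @property
    def angle_centers(self) -> np.ndarray:
        e = self.angle_bin_edges
        return (e[:-1] + e[1:]) / 2.0

    @property
    def distance_centers(self) -> np.ndarray:
        e = self.distance_bin_edges
        return (e[:-1] + e[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (angle, distance) bin."""
        a, d = np.meshgrid(self.angle_centers, self.distance_centers, indexing="ij")
        return pd.DataFrame(
            {
                "angle_bin_center": a.ravel(),
                "distance_bin_center": d.ravel(),
                "mean_turn": self.mean_turn.ravel(),
                "count": self.counts.ravel(),
            }
        )


@dataclass
class TrainingSet:
    """Grid of normalized inputs with target outputs in o1-space."""

    inputs: np.ndarray  # (N, 2): columns (d_w_norm, theta_w_norm)
    target_o1: np.ndarray  # (N,)
    i_steering: float


@dataclass(frozen=True)
class FitConfig:
    """Optimizer budget for supervised fits (matched across network sizes)."""

    restarts: int = 8
    max_nfev: int = 400
    init_scale: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.restarts < 1 or self.max_nfev < 1:
            raise ValueError("restarts and max_nfev must be >= 1")


def empirical_turn(theta_w, d_w, params: EmpiricalRuleParams):
    """Turn prescribed by the wall-avoidance rule (radians; |dphi| <= 1)."""
    d = np.asarray(d_w, dtype=float)
    if np.any(d < 0):
        raise ValueError("d_w must be >= 0")
    out = np.sin(theta_w) * np.exp(-((d / params.interaction_range) ** 2))
    if np.ndim(theta_w) == 0 and np.ndim(d_w) == 0:
        return float(out)
    return out


def rule_training_set(
    params: EmpiricalRuleParams,
    arena: ArenaConfig,
    n_angle: int = 36,
    n_dist: int = 30,
) -> TrainingSet:
    """Regular grid over theta_w in (-pi, pi], d_w in [0, L/2], with targets
    mapped to output space by the inverse steering map."""
    if n_angle < 2 or n_dist < 2:
        raise ValueError("grid sizes must be >= 2")
    i_steer = arena.steering_increment
    if i_steer < 2.0:
        # max |dphi*| is 1 rad and the steering map covers [-i/2, i/2]
        raise ValueError(
            "steering_increment too small to represent the rule's 1-rad turns"
        )
    theta = -math.pi + (np.arange(n_angle) + 0.5) * TWO_PI / n_angle
    dist = np.linspace(0.0, arena.max_wall_distance, n_dist)
    tt, dd = np.meshgrid(theta, dist, indexing="ij")
    dphi = empirical_turn(tt, dd, params)
    inputs = np.column_stack(
        [
            dd.ravel() / arena.max_wall_distance,
            (tt.ravel() + math.pi) / TWO_PI,
        ]
    )
    return TrainingSet(inputs=inputs, target_o1=dphi.ravel() / i_steer + 0.5, i_steering=i_steer)


def _residuals(genome: np.ndarray, n_hidden: int, inputs: np.ndarray, target: np.ndarray):
    p = brain.unpack(genome, n_hidden)
    return brain.forward(p, inputs[:, 0], inputs[:, 1]) - target


def fit_network_to_rule(
    n_hidden: int,
    training_set: TrainingSet,
    config: FitConfig = FitConfig(),
) -> tuple[brain.BrainParams, float]:
    """Least-squares fit of an ``n_hidden``-neuron brain to the training set.

    Runs ``config.restarts`` random restarts and keeps the best; returns
    the fitted brain and its RMSE in turning-angle units (radians).
    Restarts whose loss is non-finite are discarded; if every restart
    diverges a RuntimeError is raised.
    """
    if training_set.inputs.size == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed)
    n_params = brain.param_count(n_hidden)
    best_cost = np.inf
    best_genome = None
    for _ in range(config.restarts):
        x0 = rng.normal(0.0, config.init_scale, n_params)
        try:
            sol = least_squares(
                _residuals,
                x0,
                args=(n_hidden, training_set.inputs, training_set.target_o1),
                method="lm",
                max_nfev=config.max_nfev,
            )
        except Exception:
            continue
        if np.isfinite(sol.cost) and sol.cost < best_cost:
            best_cost = sol.cost
            best_genome = sol.x
    if best_genome is None:
        raise RuntimeError("all fitting restarts diverged")
    res = _residuals(best_genome, n_hidden, training_set.inputs, training_set.target_o1)
    rmse = float(np.sqrt(np.mean(res**2)) * training_set.i_steering)
    return brain.unpack(best_genome, n_hidden), rmse


def evaluate_rule_grid(
    turn_source,
    arena: ArenaConfig,
    n_angle: int = 36,
    n_dist: int = 30,
) -> RuleGrid:
    """Deterministic turn-angle surface at bin centres.

    ``turn_source`` is either an :class:`EmpiricalRuleParams` (closed-form
    rule) or a :class:`~steerevolve.brain.BrainParams` (network response).
    """
    angle_edges = np.linspace(-math.pi, math.pi, n_angle + 1)
    dist_edges = np.linspace(0.0, arena.max_wall_distance, n_dist + 1)
    theta = (angle_edges[:-1] + angle_edges[1:]) / 2.0
    dist = (dist_edges[:-1] + dist_edges[1:]) / 2.0
    tt, dd = np.meshgrid(theta, dist, indexing="ij")
    if isinstance(turn_source, EmpiricalRuleParams):
        turn = empirical_turn(tt, dd, turn_source)
    elif isinstance(turn_source, brain.BrainParams):
        o1 = brain.forward(
            turn_source,
            dd / arena.max_wall_distance,
            (tt + math.pi) / TWO_PI,
        )
        turn = brain.steering_angle(o1, arena.steering_increment)
    else:
        raise TypeError("turn_source must be EmpiricalRuleParams or BrainParams")
    return RuleGrid(
        angle_bin_edges=angle_edges,
        distance_bin_edges=dist_edges,
        mean_turn=np.asarray(turn),
        counts=np.ones_like(turn),
    )


def compare_structures(
    n_hidden_list,
    training_set: TrainingSet,
    config: FitConfig = FitConfig(),
) -> pd.DataFrame:
    """Fit each hidden-layer size with a matched optimizer budget.

    Returns a DataFrame with columns ``n_hidden`` and ``rmse`` (radians);
    the RMSE profile over sizes measures the cognitive difficulty of the
    wall-avoidance task.
    """
    sizes = list(n_hidden_list)
    if not sizes:
        raise ValueError("n_hidden_list must be nonempty")
    rows = []
    for k in sizes:
        _, rmse = fit_network_to_rule(k, training_set, config)
        rows.append({"n_hidden": k, "rmse": rmse})
    return pd.DataFrame(rows)
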