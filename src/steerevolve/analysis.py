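"""Post-hoc trajectory statistics.

All functions consume trajectory DataFrames as written by
:mod:`steerevolve.simulate` (columns ``time, x, y, heading, d_w, theta_w,
delta_phi, alive``); only rows with a finite ``delta_phi`` are decision
steps and enter turning statistics, while presence statistics use every
row with finite wall cues.

Angles are averaged with the circular mean ``atan2(sum sin, sum cos)``.
The signed turn ``dphi_plus = delta_phi * sign(theta_w)`` is positive
when the agent turns away from the wall; steps facing the wall exactly
(``theta_w == 0``) contribute 0.  Near/far wall regimes follow the
empirical analysis: within 50 px of the wall and beyond 150 px.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ArenaConfig, wrap_angle
from .wall_rule import RuleGrid

NEAR_WALL_PX = 50.0
FAR_WALL_PX = 150.0
SMALL_ANGLE_CUTOFF = math.radians(60.0)


@dataclass
class AngleDistribution:
    """Histogram of turning angles for one wall regime.

    ``densities`` integrate to 1 over the binned range; an empty regime is
    flagged (``empty = True``) rather than returned as silent zeros.
    """

    bin_edges: np.ndarray
    densities: np.ndarray
    regime: str
    n_samples: int
    empty: bool = False


@dataclass
class GaussianFit:
    """Moment-based normal fit to small far-wall turns."""

    mean: float
    sd: float
    ks_distance: float
    n_samples: int
    degenerate: bool = False


def circular_mean(angles) -> float:
    """Circular mean in (-pi, pi]; NaN when the resultant vanishes.

    Raises on empty input; inputs whose sine and cosine sums both fall
    below 1e-12 (e.g. antipodal pairs) have no defined mean direction.
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("circular_mean of an empty set is undefined")
    s, c = np.sum(np.sin(a)), np.sum(np.cos(a))
    if math.hypot(s, c) < 1e-12:
        return float("nan")
    return wrap_angle(math.atan2(s, c))


def _as_frames(trajectories) -> list[pd.DataFrame]:
    if isinstance(trajectories, pd.DataFrame):
        return [trajectories]
    return list(trajectories)


def _decision_rows(trajectories) -> pd.DataFrame:
    frames = _as_frames(trajectories)
    if not frames:
        raise ValueError("no trajectories given")
    df = pd.concat(frames, ignore_index=True)
    return df[np.isfinite(df["delta_phi"])]


def _presence_rows(trajectories) -> pd.DataFrame:
    df = pd.concat(_as_frames(trajectories), ignore_index=True)
    return df[np.isfinite(df["theta_w"]) & np.isfinite(df["d_w"])]


def inferred_rule_heatmap(
    trajectories,
    arena: ArenaConfig,
    n_angle: int = 36,
    n_dist: int = 30,
) -> RuleGrid:
    """Behavioural rule of interaction: per-(theta_w, d_w) bin circular
    mean of the turns actually taken.  Empty bins are NaN."""
    df = _decision_rows(trajectories)
    if df.empty:
        raise ValueError("trajectories contain no decision steps")
    angle_edges = np.linspace(-math.pi, math.pi, n_angle + 1)
    dist_edges = np.linspace(0.0, arena.max_wall_distance, n_dist + 1)
    ai = np.clip(np.digitize(df["theta_w"], angle_edges) - 1, 0, n_angle - 1)
    di = np.clip(np.digitize(df["d_w"], dist_edges) - 1, 0, n_dist - 1)
    shape = (n_angle, n_dist)
    sin_sum = np.zeros(shape)
    cos_sum = np.zeros(shape)
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(sin_sum, (ai, di), np.sin(df["delta_phi"]))
    np.add.at(cos_sum, (ai, di), np.cos(df["delta_phi"]))
    np.add.at(counts, (ai, di), 1)
    with np.errstate(invalid="ignore"):
        mean_turn = np.arctan2(sin_sum, cos_sum)
    defined = (counts > 0) & (np.hypot(sin_sum, cos_sum) >= 1e-12)
    mean_turn = np.where(defined, mean_turn, np.nan)
    return RuleGrid(
        angle_bin_edges=angle_edges,
        distance_bin_edges=dist_edges,
        mean_turn=mean_turn,
        counts=counts,
    )


def presence_density(
    trajectories,
    arena: ArenaConfig,
    n_angle: int = 36,
    n_dist: int = 30,
) -> RuleGrid:
    """Normalized 2-D occupancy histogram over (theta_w, d_w); the
    ``mean_turn`` slot carries the probability mass per bin (sums to 1)."""
    df = _presence_rows(trajectories)
    if df.empty:
        raise ValueError("trajectories contain no perceived states")
    angle_edges = np.linspace(-math.pi, math.pi, n_angle + 1)
    dist_edges = np.linspace(0.0, arena.max_wall_distance, n_dist + 1)
    counts, _, _ = np.histogram2d(
        df["theta_w"], df["d_w"], bins=[angle_edges, dist_edges]
    )
    return RuleGrid(
        angle_bin_edges=angle_edges,
        distance_bin_edges=dist_edges,
        mean_turn=counts / counts.sum(),
        counts=counts.astype(np.int64),
    )


def signed_turns(trajectories, regime: str = "all", near: float = NEAR_WALL_PX, far: float = FAR_WALL_PX) -> np.ndarray:
    """Signed turns ``dphi_plus = delta_phi * sign(theta_w)`` restricted to
    a wall regime (``near``: d_w < 50 px; ``far``: d_w > 150 px; ``all``)."""
    df = _decision_rows(trajectories)
    if regime == "near":
        df = df[df["d_w"] < near]
    elif regime == "far":
        df = df[df["d_w"] > far]
    elif regime != "all":
        raise ValueError(f"unknown regime {regime!r}")
    return (df["delta_phi"] * np.sign(df["theta_w"])).to_numpy()


def signed_turn_distribution(
    trajectories,
    regime: str = "near",
    n_bins: int = 36,
    near: float = NEAR_WALL_PX,
    far: float = FAR_WALL_PX,
) -> AngleDistribution:
    """Histogram of the signed turn in a wall regime, normalized to
    integrate to 1 over (-pi, pi]."""
    values = signed_turns(trajectories, regime, near=near, far=far)
    edges = np.linspace(-math.pi, math.pi, n_bins + 1)
    if values.size == 0:
        return AngleDistribution(
            bin_edges=edges,
            densities=np.zeros(n_bins),
            regime=regime,
            n_samples=0,
            empty=True,
        )
    densities, _ = np.histogram(values, bins=edges, density=True)
    return AngleDistribution(
        bin_edges=edges,
        densities=densities,
        regime=regime,
        n_samples=int(values.size),
    )


def gaussian_small_angle_fit(
    turns,
    cutoff: float = SMALL_ANGLE_CUTOFF,
    min_samples: int = 30,
) -> GaussianFit:
    """Moment fit of a normal to turns with ``|dphi| < cutoff``.

    Reports the Kolmogorov-Smirnov distance to the fitted normal as a
    descriptive goodness statistic (no hypothesis-test verdict).
    """
    t = np.asarray(turns, dtype=float)
    small = t[np.abs(t) < cutoff]
    if small.size < min_samples:
        raise ValueError(
            f"need >= {min_samples} small-angle samples, got {small.size}"
        )
    mean = float(small.mean())
    sd = float(small.std(ddof=1))
    if sd == 0.0:
        return GaussianFit(mean=mean, sd=0.0, ks_distance=float("nan"),
                           n_samples=int(small.size), degenerate=True)
    ks = stats.kstest(small, "norm", args=(mean, sd)).statistic
    return GaussianFit(mean=mean, sd=sd, ks_distance=float(ks), n_samples=int(small.size))


def segment_length_estimate(trajectory, uturn_threshold: float = math.pi / 2.0) -> float:
    """Median distance between consecutive U-turn positions (pixels).

    U-turns are decision steps with ``|delta_phi| > uturn_threshold``;
    with fewer than two U-turns the estimate is undefined (NaN).
    """
    df = _decision_rows(trajectory)
    uturns = df[np.abs(df["delta_phi"]) > uturn_threshold]
    if len(uturns) < 2:
        return float("nan")
    dx = np.diff(uturns["x"].to_numpy())
    dy = np.diff(uturns["y"].to_numpy())
    return float(np.median(np.hypot(dx, dy)))


def wall_following_fraction(trajectory, band: float = 100.0) -> float:
    """Fraction of perceived states within ``band`` pixels of the wall."""
    df = _presence_rows(trajectory)
    if df.empty:
        raise ValueError("trajectory contains no perceived states")
    return float((df["d_w"] < band).mean())


def near_wall_turn_signs(
    trajectories,
    near: float = NEAR_WALL_PX,
) -> tuple[float, float]:
    """Pooled circular-mean turn near the wall, split by wall side.

    Returns ``(mean_turn_wall_right, mean_turn_wall_left)``: under a
    wall-avoiding rule the first is positive (left turn) and the second
    negative, mirroring the antisymmetry of the rule of interaction.
    """
    df = _decision_rows(trajectories)
    df = df[df["d_w"] < near]
    right = df[df["theta_w"] > 0]["delta_phi"]
    left = df[df["theta_w"] < 0]["delta_phi"]
    if right.empty or left.empty:
        return float("nan"), float("nan")
    return circular_mean(right), circular_mean(left)
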