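"""Experiment configuration, persistence and reference fixtures.

Configs are flat-ish JSON.  The reference condition (600 px arena, 400
cells, speed 50, steering increment 2*pi, 3 hidden neurons, explore
objective, no turning penalty) is the default; named variants override
single knobs (``speed: 5`` slow condition, ``turning_penalty: 0.33``
penalty condition, ``goal: survive``).  Flat aliases matching the
conventional parameter-table names (``max_turning_angle``, ``n_hidden``,
``goal``, ``speed``, ``turning_penalty``) are accepted alongside the
nested ``arena`` / ``ga`` / ``mutation`` sections.
"""

from __future__ import annotations

import dataclasses
import functools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import brain
from .evolve import GAConfig, MutationConfig
from .geometry import ArenaConfig, cell_index
from .wall_rule import EmpiricalRuleParams, FitConfig, fit_network_to_rule, rule_training_set


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the trajectory statistics."""

    near_wall_px: float = 50.0
    far_wall_px: float = 150.0
    uturn_threshold: float = math.pi / 2.0
    wall_band_px: float = 100.0


@dataclass(frozen=True)
class ExperimentConfig:
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    objective: str = "explore"
    n_hidden: int = 3
    ga: GAConfig = field(default_factory=GAConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0


_FLAT_ALIASES = {
    "max_turning_angle": ("arena", "steering_increment"),
    "speed": ("arena", "speed"),
    "turning_penalty": ("arena", "turning_penalty"),
    "goal": (None, "objective"),
    "n_hidden": (None, "n_hidden"),
    "seed": (None, "seed"),
}

_SECTIONS = {
    "arena": ArenaConfig,
    "ga": GAConfig,
    "analysis": AnalysisConfig,
}


def _build_section(cls, overrides: dict, path: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in overrides.items():
        if key not in known:
            raise ValueError(f"unknown configuration key '{path}.{key}'")
        if key == "mutation":
            value = _build_section(MutationConfig, value, f"{path}.mutation")
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> ExperimentConfig:
    """Read and validate a JSON config; an empty file means all defaults.

    Unknown keys raise a ValueError naming the key.
    """
    text = Path(path).read_text().strip()
    data = json.loads(text) if text else {}
    return config_from_dict(data)


def config_from_dict(data: dict) -> ExperimentConfig:
    sections: dict[str, dict] = {"arena": {}, "ga": {}, "analysis": {}}
    top: dict = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"configuration section '{key}' must be a mapping")
            sections[key].update(value)
        elif key in _FLAT_ALIASES:
            section, name = _FLAT_ALIASES[key]
            if section is None:
                top[name] = value
            else:
                sections[section][name] = value
        elif key in ("objective",):
            top[key] = value
        else:
            raise ValueError(f"unknown configuration key '{key}'")
    cfg = ExperimentConfig(
        arena=_build_section(ArenaConfig, sections["arena"], "arena"),
        ga=_build_section(GAConfig, sections["ga"], "ga"),
        analysis=_build_section(AnalysisConfig, sections["analysis"], "analysis"),
        **top,
    )
    if cfg.objective not in ("survive", "explore"):
        raise ValueError(f"invalid objective {cfg.objective!r}")
    if cfg.n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    return cfg


def config_to_dict(cfg: ExperimentConfig) -> dict:
    return {
        "arena": dataclasses.asdict(cfg.arena),
        "objective": cfg.objective,
        "n_hidden": cfg.n_hidden,
        "ga": dataclasses.asdict(cfg.ga),
        "analysis": dataclasses.asdict(cfg.analysis),
        "seed": cfg.seed,
    }


def save_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(cfg), indent=2) + "\n")


def save_brain(params: brain.BrainParams, path, meta: dict | None = None) -> None:
    """Persist a brain as JSON: hidden-layer size plus the flat genome."""
    payload = {
        "n_hidden": params.n_hidden,
        "genome": brain.pack(params).tolist(),
    }
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_brain(path) -> brain.BrainParams:
    payload = json.loads(Path(path).read_text())
    return brain.unpack(np.asarray(payload["genome"], dtype=float), payload["n_hidden"])


# --- reference fixtures -------------------------------------------------

def fixture_zero_brain(n_hidden: int = 3) -> brain.BrainParams:
    """All-zero genome: output 0.5 everywhere, so the agent never turns."""
    return brain.BrainParams.zeros(n_hidden)


@functools.lru_cache(maxsize=4)
def fixture_avoider_brain(
    interaction_range: float = 60.0,
    n_hidden: int = 3,
    seed: int = 0,
) -> brain.BrainParams:
    """A wall-avoiding brain fitted to the empirical rule (deterministic).

    Regenerated on demand from the closed-form rule with a fixed seed;
    cached because the fit takes a few seconds.
    """
    arena = ArenaConfig()
    ts = rule_training_set(EmpiricalRuleParams(interaction_range), arena)
    params, _ = fit_network_to_rule(n_hidden, ts, FitConfig(seed=seed))
    return params


def fixture_boustrophedon_path(arena: ArenaConfig | None = None) -> pd.DataFrame:
    """Scripted lawn-mower trajectory visiting every grid cell once.

    Walks the cell centres row by row, alternating direction; by
    construction its exploration score is exactly the cell count.  The
    frame has the standard trajectory columns (wall cues NaN, headings
    synthesized from the displacement).
    """
    arena = arena or ArenaConfig()
    n = arena.grid_cells_per_side
    size = arena.cell_size
    xs, ys = [], []
    for row in range(n):
        cols = range(n) if row % 2 == 0 else range(n - 1, -1, -1)
        for col in cols:
            xs.append((col + 0.5) * size)
            ys.append((row + 0.5) * size)
    xs, ys = np.asarray(xs), np.asarray(ys)
    heading = np.zeros_like(xs)
    heading[:-1] = np.arctan2(np.diff(ys), np.diff(xs))
    heading[-1] = heading[-2]
    return pd.DataFrame(
        {
            "time": np.arange(xs.size),
            "x": xs,
            "y": ys,
            "heading": heading,
            "d_w": np.nan,
            "theta_w": np.nan,
            "delta_phi": np.nan,
            "alive": True,
        }
    )


def exploration_score_of_path(path: pd.DataFrame, arena: ArenaConfig) -> int:
    """Distinct grid cells visited by a scripted path."""
    cells = {cell_index(x, y, arena) for x, y in zip(path["x"], path["y"])}
    return len(cells)
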