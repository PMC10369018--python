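"""Genetic algorithm over steering-network genomes.

One generation evaluates every agent (4 scored rounds + 1 monitoring
round), converts penalized scores to a normalized fitness, samples the
next generation's parents with replacement proportionally to fitness,
and mutates each copied genome with independent small (33%, sd 0.5) and
large (1%, sd 5) Gaussian perturbations per parameter.

The initial population is a Latin hypercube design in ``[-50, 50]`` per
parameter; the maximin criterion is approximated by drawing several
candidate designs and keeping the one with the largest minimum pairwise
distance.  Mutated parameters are not clipped: the initial range is an
initialization range, not a constraint.

Every source of randomness derives from one master seed through named
substreams (``init``, ``starts``, ``selection``, ``mutation``), so runs
are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import qmc

from .geometry import ArenaConfig
from .simulate import evaluate_population

_STREAMS = ("init", "starts", "selection", "mutation")


@dataclass(frozen=True)
class MutationConfig:
    """Two-scale Gaussian mutation, applied independently per parameter."""

    small_prob: float = 0.33
    small_sd: float = 0.5
    large_prob: float = 0.01
    large_sd: float = 5.0

    def __post_init__(self) -> None:
        for p in (self.small_prob, self.large_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("mutation probabilities must lie in [0, 1]")
        if self.small_sd <= 0 or self.large_sd <= 0:
            raise ValueError("mutation standard deviations must be positive")


@dataclass(frozen=True)
class GAConfig:
    """Sizes and operators of one evolution run."""

    n: int = 500
    generations: int = 60
    mutation: MutationConfig = field(default_factory=MutationConfig)
    lhs_candidates: int = 20
    shared_starts: bool = False


@dataclass
class Population:
    genomes: np.ndarray  # (n, genome_length)
    generation_index: int = 0


@dataclass
class GenerationRecord:
    """Per-generation summary statistics."""

    generation_index: int
    best_penalized_score: float
    mean_penalized_score: float
    best_reference_score: float
    best_genome: np.ndarray


def init_population_lhs(
    n: int,
    genome_length: int,
    low: float = -50.0,
    high: float = 50.0,
    seed=None,
    candidates: int = 20,
) -> Population:
    """Latin hypercube initial population in ``[low, high]^genome_length``.

    Each of ``candidates`` scrambled LHS designs is scored by its minimum
    pairwise distance; the best (maximin) design is kept.
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    if candidates < 1:
        raise ValueError("candidates must be >= 1")
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=genome_length, seed=rng)
    best = None
    best_sep = -np.inf
    for _ in range(candidates):
        design = sampler.random(n)
        sep = pdist(design).min()
        if sep > best_sep:
            best_sep = sep
            best = design
    genomes = qmc.scale(best, low, high)
    return Population(genomes=genomes, generation_index=0)


def fitness_from_scores(penalized_scores) -> np.ndarray:
    """Min-max interpolate scores to [0, 1], then normalize to sum 1.

    An all-equal generation (max == min) gets the uniform fitness ``1/n``.
    """
    scores = np.asarray(penalized_scores, dtype=float)
    if scores.ndim != 1 or scores.size == 0:
        raise ValueError("penalized_scores must be a nonempty 1-D array")
    if not np.all(np.isfinite(scores)):
        raise ValueError("penalized_scores must be finite")
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.full(scores.size, 1.0 / scores.size)
    u = (scores - lo) / (hi - lo)
    return u / u.sum()


def select_parents(fitnesses, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` independent fitness-proportional draws with replacement."""
    f = np.asarray(fitnesses, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
        raise ValueError("fitnesses must be nonnegative and sum to 1")
    return rng.choice(f.size, size=n, replace=True, p=f / f.sum())


def mutate(genomes: np.ndarray, config: MutationConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply two-scale Gaussian mutation elementwise to an array of genomes.

    Both mutation kinds are independent per parameter and may co-occur.
    The draw order (small mask, large mask, small noise, large noise) is
    fixed so identical seeds give identical offspring.
    """
    genomes = np.asarray(genomes, dtype=float)
    small_mask = rng.random(genomes.shape) < config.small_prob
    large_mask = rng.random(genomes.shape) < config.large_prob
    small_noise = rng.normal(0.0, config.small_sd, genomes.shape)
    large_noise = rng.normal(0.0, config.large_sd, genomes.shape)
    return genomes + small_mask * small_noise + large_mask * large_noise


def run_evolution(
    arena: ArenaConfig,
    objective: str,
    ga: GAConfig,
    seed: int,
    n_hidden: int = 3,
    init_genomes: np.ndarray | None = None,
) -> tuple[list[GenerationRecord], Population]:
    """Run the full GA loop and return per-generation records.

    ``init_genomes`` replaces the LHS initial population when given (used
    e.g. to plant known genomes).  The returned population is the last
    evaluated one; its record is the final list entry.
    """
    genome_length = 4 * n_hidden + 1
    streams = dict(zip(_STREAMS, np.random.SeedSequence(seed).spawn(len(_STREAMS))))
    rng_starts = np.random.default_rng(streams["starts"])
    rng_selection = np.random.default_rng(streams["selection"])
    rng_mutation = np.random.default_rng(streams["mutation"])

    if init_genomes is not None:
        genomes = np.array(init_genomes, dtype=float)
        if genomes.shape != (ga.n, genome_length):
            raise ValueError("init_genomes shape must be (n, 4*n_hidden+1)")
    else:
        genomes = init_population_lhs(
            ga.n,
            genome_length,
            seed=np.random.default_rng(streams["init"]),
            candidates=ga.lhs_candidates,
        ).genomes

    records: list[GenerationRecord] = []
    population = Population(genomes=genomes, generation_index=0)
    for gen in range(ga.generations):
        shape = (1, 4, 2) if ga.shared_starts else (ga.n, 4, 2)
        starts = rng_starts.uniform(0.0, arena.side_length, size=shape)
        result = evaluate_population(population.genomes, n_hidden, arena, objective, starts)
        penalized = result["penalized_score"]
        best = int(np.argmax(penalized))
        records.append(
            GenerationRecord(
                generation_index=gen,
                best_penalized_score=float(penalized[best]),
                mean_penalized_score=float(penalized.mean()),
                best_reference_score=float(result["reference_score"][best]),
                best_genome=population.genomes[best].copy(),
            )
        )
        if gen == ga.generations - 1:
            break
        fitness = fitness_from_scores(penalized)
        parents = select_parents(fitness, ga.n, rng_selection)
        offspring = mutate(population.genomes[parents], ga.mutation, rng_mutation)
        population = Population(genomes=offspring, generation_index=gen + 1)
    return records, population


def records_to_frame(records: Sequence[GenerationRecord]):
    """Generation log as a DataFrame (one row per generation)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "generation": [r.generation_index for r in records],
            "best_penalized_score": [r.best_penalized_score for r in records],
            "mean_penalized_score": [r.mean_penalized_score for r in records],
            "best_reference_score": [r.best_reference_score for r in records],
        }
    )
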