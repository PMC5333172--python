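"""Mutation / truncation-selection / free-recombination simulation.

A population of haploid genotypes (four regulatory loci) evolves under
per-base substitution at rate mu, truncation selection on the rms-score
F against a fixed wild-type expression target, and free recombination
that shuffles whole loci between two parents (no break points within a
locus).  The simulation is seeded with genetically identical copies of
the founder, so generation 0 has F = 0 throughout.

Per generation the recorder keeps the elite (the ``elite_size`` most fit
individuals), their annotations and scores, and one uniformly chosen
elite member whose annotation feeds the TFBS tracking algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import PWM, SiteAnnotation, TFBS, annotate_genotype
from .expression import ExpressionState, ModelParams, TimeGrid, rms_score, simulate_batch
from .synthetic import Genotype, TFProfile

logger = logging.getLogger(__name__)


@dataclass
class EvoConfig:
    """Population-simulation knobs.

    Defaults mirror the full-scale study conditions (100 haploid
    individuals, mu = 0.001 substitutions/bp/generation, top-20
    truncation) with a scaled-down generation count.
    """

    population_size: int = 100
    mu: float = 0.001
    generations: int = 300
    elite_size: int = 20
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.elite_size <= self.population_size:
            raise ValueError("elite_size must be in [1, population_size]")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")


@dataclass
class Individual:
    genotype: Genotype
    annotation: SiteAnnotation | None = None
    F: float = np.nan


@dataclass
class GenerationRecord:
    """State recorded for one generation.

    ``F_all`` holds every individual's score sorted ascending;
    ``elite_sites`` the annotations (site lists) of the elite in rank
    order; ``tracked_rank`` the elite rank of the tracked individual
    whose sites are in ``tracked_sites``.
    """

    generation: int
    F_all: np.ndarray
    elite_sites: list[list[TFBS]]
    tracked_rank: int
    tracked_sites: list[TFBS]

    @property
    def elite_F(self) -> np.ndarray:
        return self.F_all[: len(self.elite_sites)]


# ---------------------------------------------------------------------------
# Operators


def mutate(genotype: Genotype, mu: float, rng: np.random.Generator) -> Genotype:
    """Independent per-base substitution within the represented sequence.

    Each accessible base mutates with probability mu, uniformly to one
    of the three other bases; lengths never change.  Positions outside
    the accessibility mask are not represented and never mutate.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be in [0, 1]")
    child = genotype.copy()
    if mu == 0.0:
        return child
    for locus in child.locus_names:
        idx = child.accessible_positions(locus)
        if len(idx) == 0:
            continue
        hit = rng.random(len(idx)) < mu
        k = int(hit.sum())
        if k == 0:
            continue
        pos = idx[hit]
        seq = child.loci[locus]
        seq[pos] = (seq[pos] + rng.integers(1, 4, size=k).astype(np.uint8)) % 4
    return child


def eligible_count(F_sorted: np.ndarray, elite_size: int) -> int:
    """Size of the breeding pool: everyone at least as fit as the
    rank-``elite_size`` individual, ties included."""
    cutoff = F_sorted[elite_size - 1]
    return int(np.searchsorted(F_sorted, cutoff, side="right"))


def select_parents(
    F_sorted: np.ndarray, elite_size: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw two parent ranks uniformly, with replacement, from the pool."""
    n = eligible_count(F_sorted, elite_size)
    pair = rng.integers(0, n, size=2)
    return int(pair[0]), int(pair[1])


def recombine(
    parent_a: Genotype, parent_b: Genotype, rng: np.random.Generator
) -> Genotype:
    """Free recombination: each locus inherited whole from either parent
    with probability 1/2, independently (no within-locus break points)."""
    if parent_a.locus_names != parent_b.locus_names:
        raise ValueError("parents must share the same locus structure")
    picks = rng.random(len(parent_a.locus_names)) < 0.5
    child = parent_a.copy()
    for take_a, locus in zip(picks, parent_a.locus_names):
        src = parent_a if take_a else parent_b
        child.loci[locus] = src.loci[locus].copy()
    return child


# ---------------------------------------------------------------------------
# Driver


def evaluate_population(
    genotypes: Sequence[Genotype],
    pwms: Sequence[PWM],
    params: ModelParams,
    profiles: dict[str, TFProfile],
    U: ExpressionState,
    grid: TimeGrid | None = None,
) -> tuple[list[SiteAnnotation], np.ndarray]:
    """Annotate and score a set of genotypes against the wild type.

    Individuals whose dynamics blow up receive F = +inf (they are never
    selected) and are logged.
    """
    anns = [annotate_genotype(g, pwms) for g in genotypes]
    states = simulate_batch(anns, params, grid, profiles)
    F = np.empty(len(anns))
    for i, st in enumerate(states):
        if st is None:
            logger.warning("individual %d: expression blow-up, F = inf", i)
            F[i] = np.inf
        else:
            F[i] = rms_score(st, U)
    return anns, F


def evolve(
    config: EvoConfig,
    founder: Genotype,
    pwms: Sequence[PWM],
    params: ModelParams,
    profiles: dict[str, TFProfile],
    U: ExpressionState,
    grid: TimeGrid | None = None,
    progress: bool = False,
) -> list[GenerationRecord]:
    """Run the full population simulation; fully reproducible from seed.

    A single generator seeded with ``config.rng_seed`` drives parent
    choice, locus inheritance, mutation and the tracked-individual draw,
    in that fixed per-generation order.
    """
    rng = np.random.default_rng(config.rng_seed)
    N = config.population_size

    # generation 0: identical founders, evaluated once
    ann0, F0 = evaluate_population([founder], pwms, params, profiles, U, grid)
    pop = [founder.copy() for _ in range(N)]
    anns = [ann0[0]] * N
    F = np.full(N, F0[0])
    records: list[GenerationRecord] = []
    records.append(_record(0, F, anns, config, rng))

    founder_digest = _digest(founder)
    for g in range(1, config.generations + 1):
        order = np.argsort(F, kind="stable")
        F_sorted = F[order]
        pool = eligible_count(F_sorted, config.elite_size)
        children: list[Genotype] = []
        for _ in range(N):
            ia, ib = rng.integers(0, pool, size=2)
            child = recombine(pop[order[ia]], pop[order[ib]], rng)
            children.append(mutate(child, config.mu, rng))
        # unchanged children (always under mu=0) reuse the founder's score
        reuse = [
            i for i, c in enumerate(children) if _digest(c) == founder_digest
        ] if config.mu == 0.0 else []
        if len(reuse) == N:
            anns = [anns[0]] * N
            F = np.full(N, F0[0])
        else:
            anns, F = evaluate_population(children, pwms, params, profiles, U, grid)
        pop = children
        records.append(_record(g, F, anns, config, rng))
        if progress and g % 25 == 0:
            logger.info(
                "generation %d: best F=%.4g elite mean sites=%.1f",
                g,
                F.min(),
                np.mean([len(r) for r in records[-1].elite_sites]),
            )
    return records


def _digest(genotype: Genotype) -> bytes:
    import hashlib

    h = hashlib.sha1()
    for locus in genotype.locus_names:
        h.update(genotype.loci[locus].tobytes())
    return h.digest()


def _record(
    g: int,
    F: np.ndarray,
    anns: list[SiteAnnotation],
    config: EvoConfig,
    rng: np.random.Generator,
) -> GenerationRecord:
    order = np.argsort(F, kind="stable")
    elite = order[: config.elite_size]
    tracked_rank = int(rng.integers(0, config.elite_size))
    return GenerationRecord(
        generation=g,
        F_all=F[order].copy(),
        elite_sites=[list(anns[i].sites) for i in elite],
        tracked_rank=tracked_rank,
        tracked_sites=list(anns[elite[tracked_rank]].sites),
    )
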