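"""Genetic-algorithm search over the three accuracy-relevant parameters.

Only ``max_edges``, ``max_p`` and ``min_s`` change binning accuracy, so the
search space is a small discrete grid over those. Fitness is the number of
high-quality bins — at least 90% complete with at most 5% contamination —
measured against the generating truth of a simulated community. The GA uses
binary tournament selection, one-point crossover, per-gene mutation, and
elitism, with early stopping once the best fitness has been flat for three
generations past the minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .graph_cluster import BinningParams
from .pipeline import run_binning
from .synthetic_eval import Community, evaluate_bins

logger = logging.getLogger(__name__)

__all__ = ["GAConfig", "FitnessRecord", "ga_search", "truth_fitness", "DEFAULT_SPACE"]

DEFAULT_SPACE: dict[str, list] = {
    "max_edges": [50, 100, 200, 400, 800],
    "max_p": [80.0, 85.0, 90.0, 95.0, 97.0],
    "min_s": [50.0, 60.0, 70.0, 80.0, 90.0],
}


@dataclass(frozen=True)
class GAConfig:
    population: int = 10
    selection_size: int = 3
    mutation_rate: float = 0.05
    crossover_rate: float = 0.01
    min_generations: int = 3
    max_generations: int = 10
    tournament: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate <= 1.0 and 0.0 <= self.crossover_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if self.population < self.selection_size:
            raise ValueError("population must be >= selection size")


@dataclass
class FitnessRecord:
    params: dict
    hq_bins: int


def _decode(genome: tuple[int, ...], names: list[str], space: dict) -> dict:
    return {n: space[n][g] for n, g in zip(names, genome)}


def ga_search(
    fitness,
    space: dict[str, list],
    cfg: GAConfig | None = None,
) -> tuple[FitnessRecord, list[FitnessRecord]]:
    """Maximise ``fitness(params dict) -> number`` over a discrete grid.

    Deterministic for a fixed ``cfg.seed``. Returns the best-ever record and
    the history of every distinct parameter set evaluated. Fitness values
    are cached, so re-visited genomes cost nothing.
    """
    cfg = cfg or GAConfig()
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("empty parameter space")
    names = sorted(space)
    sizes = [len(space[n]) for n in names]
    rng = np.random.default_rng(cfg.seed)

    cache: dict[tuple[int, ...], float] = {}
    history: list[FitnessRecord] = []

    def evaluate(genome: tuple[int, ...]) -> float:
        if genome not in cache:
            params = _decode(genome, names, space)
            val = fitness(params)
            cache[genome] = val
            history.append(FitnessRecord(params=params, hq_bins=val))
        return cache[genome]

    def random_genome() -> tuple[int, ...]:
        return tuple(int(rng.integers(0, s)) for s in sizes)

    # initial population: distinct individuals while the space allows, so a
    # small grid is covered instead of wasting evaluations on duplicates
    space_size = int(np.prod(sizes))
    population: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    while len(population) < cfg.population:
        g = random_genome()
        if g in seen and len(seen) < space_size:
            continue
        seen.add(g)
        population.append(g)
    best_genome: tuple[int, ...] | None = None
    best_fit = -np.inf
    flat = 0

    for gen in range(cfg.max_generations):
        fits = [evaluate(g) for g in population]
        ranked = sorted(zip(population, fits), key=lambda t: (-t[1], t[0]))
        if ranked[0][1] > best_fit:
            best_fit = ranked[0][1]
            best_genome = ranked[0][0]
            flat = 0
        else:
            flat += 1
        logger.info("generation %d: best fitness %s", gen, best_fit)
        if gen + 1 >= cfg.min_generations and flat >= 3:
            break
        if gen + 1 == cfg.max_generations:
            break

        def tournament() -> tuple[int, ...]:
            picks = [population[int(rng.integers(0, len(population)))]
                     for _ in range(cfg.tournament)]
            return max(picks, key=lambda g: (cache[g], tuple(-x for x in g)))

        elites = [g for g, _ in ranked[: cfg.selection_size]]
        offspring: list[tuple[int, ...]] = []
        while len(elites) + len(offspring) < cfg.population:
            p1, p2 = tournament(), tournament()
            child = list(p1)
            if len(sizes) > 1 and rng.random() < cfg.crossover_rate:
                cut = int(rng.integers(1, len(sizes)))
                child = list(p1[:cut]) + list(p2[cut:])
            for k in range(len(sizes)):
                if rng.random() < cfg.mutation_rate:
                    child[k] = int(rng.integers(0, sizes[k]))
            offspring.append(tuple(child))
        population = elites + offspring

    assert best_genome is not None
    return FitnessRecord(params=_decode(best_genome, names, space), hq_bins=best_fit), history


def truth_fitness(
    params: BinningParams | dict, community: Community
) -> int:
    """Number of high-quality bins (>= 90% complete, <= 5% contamination,
    judged against the community's generating truth) produced by a full
    binner run with ``params``. A binner failure scores 0."""
    if isinstance(params, dict):
        params = replace(BinningParams(), **params)
    try:
        bins, _ = run_binning(community.contigs, community.coverage, params)
        report = evaluate_bins(bins, community.truth, community.lengths)
    except Exception:
        logger.exception("binner failed for %s; fitness 0", params)
        return 0
    return report.hq_bins(completeness=0.9, precision=0.95)
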