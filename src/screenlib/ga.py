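"""Genetic algorithm for optimal library subset selection.

An individual is an ordered set of N distinct compounds drawn from the
pool of candidate compounds; a population holds M individuals.  Each
generation, the fittest third of the population (rounded down to an even
parent count) survives unchanged — elitism guarantees the best fitness
never decreases — and randomly paired parents produce children by a
midpoint single-point crossover until the remaining two thirds of the
slots are filled.  Children are repaired (inherited duplicates replaced
by fresh pool compounds) and mutated (10% of positions resampled from
the pool by default).  After a fixed number of generations the fittest
individual is the selected library.

Baseline libraries, for comparison, are the fittest of a small number of
uniformly random N-subsets of the property-filtered pool (10% of N
draws), with no evolution and no use of predictions in the selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from screenlib.fitness import COMMON_RATIO, FitnessContext


@dataclass(frozen=True)
class GAConfig:
    """Run parameters of the genetic algorithm.

    ``library_size`` is N, ``population_size`` is M (typically 10% of N),
    ``parent_fraction`` the share of the population kept as parents.
    """

    library_size: int
    population_size: int
    generations: int = 300
    mutation_rate: float = 0.10
    parent_fraction: float = 1 / 3
    r: float = COMMON_RATIO
    seed: int = 0

    def __post_init__(self) -> None:
        if self.library_size < 2:
            raise ValueError("library_size must be >= 2")
        if self.population_size < 3:
            raise ValueError("population_size must be >= 3")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass
class GAResult:
    """Outcome of one evolution run."""

    best_ids: tuple[str, ...]
    best_fitness: float
    trajectory: pd.DataFrame  # columns: generation, best_fitness, mean_fitness
    config: GAConfig


def init_population(
    pool_size: int, cfg: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """M individuals of N distinct pool indices, sampled uniformly."""
    if pool_size < cfg.library_size:
        raise ValueError(
            f"pool of {pool_size} cannot fill a library of {cfg.library_size}"
        )
    return np.stack(
        [
            rng.choice(pool_size, size=cfg.library_size, replace=False)
            for _ in range(cfg.population_size)
        ]
    )


def parent_count(population_size: int, parent_fraction: float = 1 / 3) -> int:
    """Largest even number <= parent_fraction * M, at least 2.

    Parents are mated in pairs, hence the even rounding.
    """
    if population_size < 6:
        raise ValueError("population_size must be >= 6 to form parents and children")
    p = int(population_size * parent_fraction)
    p -= p % 2
    return max(p, 2)


def select_parents(fitnesses: np.ndarray, p: int) -> np.ndarray:
    """Indices of the ``p`` fittest individuals; ties favor earlier index."""
    order = np.argsort(-np.asarray(fitnesses), kind="stable")
    return order[:p]


def crossover(
    parent_a: np.ndarray, parent_b: np.ndarray
) -> list[np.ndarray]:
    """Four children from a midpoint single-point crossover.

    Each parent is split at floor(N/2) into halves (A1, A2) and (B1, B2);
    the children are A1+B2, B1+A2, A1+B1, A2+B2, so each child inherits
    half of a parent's compounds.  For odd N the same-half children take
    the complementary-length prefix/suffix of the second parent so all
    four children have length N.  Children may contain duplicates and
    must be repaired.
    """
    n = len(parent_a)
    if len(parent_b) != n:
        raise ValueError("parents must have equal length")
    mid = n // 2
    a1, a2 = parent_a[:mid], parent_a[mid:]
    b1, b2 = parent_b[:mid], parent_b[mid:]
    return [
        np.concatenate([a1, b2]),
        np.concatenate([b1, a2]),
        np.concatenate([a1, parent_b[: n - mid]]),
        np.concatenate([a2, parent_b[n - mid :]]),
    ]


def _replace_excluding(
    pool_size: int, exclude: set[int], rng: np.random.Generator
) -> int:
    """A uniform draw from pool \\ exclude, by rejection sampling."""
    if len(exclude) >= pool_size:
        raise ValueError("pool too small to draw a replacement compound")
    while True:
        cand = int(rng.integers(pool_size))
        if cand not in exclude:
            return cand


def repair(
    child: np.ndarray, pool_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Replace duplicate entries (the later occurrence) by fresh pool draws."""
    child = child.copy()
    seen: set[int] = set()
    members = set(int(x) for x in child)
    for i, cid in enumerate(child):
        cid = int(cid)
        if cid in seen:
            new = _replace_excluding(pool_size, members, rng)
            child[i] = new
            members.add(new)
        else:
            seen.add(cid)
    return child


def mutate(
    child: np.ndarray, pool_size: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Resample floor(rate*N) positions from the pool, excluding current members."""
    n = len(child)
    k = int(rate * n)
    if k == 0:
        return child
    child = child.copy()
    positions = rng.choice(n, size=k, replace=False)
    members = set(int(x) for x in child)
    for pos in positions:
        new = _replace_excluding(pool_size, members, rng)
        members.discard(int(child[pos]))
        members.add(new)
        child[pos] = new
    return child


def evolve(
    pool_ids: list[str] | tuple[str, ...],
    context: FitnessContext,
    cfg: GAConfig,
) -> GAResult:
    """Run the evolution and return the fittest final individual.

    ``pool_ids`` is the PCC; all mutation/repair replacement draws come
    from it.  A single seeded generator drives initialization, pairing,
    repair, and mutation, so runs are reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    pool_rows = np.array([context.index[cid] for cid in pool_ids])
    pool_size = len(pool_rows)

    # individuals store positions into pool_rows so replacement draws are
    # uniform over the PCC regardless of the context's full pool
    population = init_population(pool_size, cfg, rng)
    p = parent_count(cfg.population_size, cfg.parent_fraction)

    records = []
    for generation in range(cfg.generations + 1):
        fitnesses = np.array(
            [context.score(pool_rows[ind]) for ind in population]
        )
        records.append(
            {
                "generation": generation,
                "best_fitness": float(fitnesses.max()),
                "mean_fitness": float(fitnesses.mean()),
            }
        )
        if generation == cfg.generations:
            break
        parents = population[select_parents(fitnesses, p)]
        n_children = cfg.population_size - p
        children: list[np.ndarray] = []
        while len(children) < n_children:
            order = rng.permutation(p)
            for i in range(0, p - 1, 2):
                for child in crossover(parents[order[i]], parents[order[i + 1]]):
                    children.append(repair(child, pool_size, rng))
                if len(children) >= n_children:
                    break
        children = [
            mutate(c, pool_size, cfg.mutation_rate, rng)
            for c in children[:n_children]
        ]
        population = np.vstack([parents, np.stack(children)])

    fitnesses = np.array([context.score(pool_rows[ind]) for ind in population])
    best = population[int(np.argmax(fitnesses))]
    return GAResult(
        best_ids=tuple(pool_ids[i] for i in best),
        best_fitness=float(fitnesses.max()),
        trajectory=pd.DataFrame.from_records(records),
        config=cfg,
    )


def baseline_library(
    filtered_pool_ids: list[str] | tuple[str, ...],
    context: FitnessContext,
    library_size: int,
    seed: int = 0,
    draws: int | None = None,
) -> tuple[tuple[str, ...], float, list[float]]:
    """The fittest of a few uniformly random N-subsets of the filtered pool.

    The pool here is the property-filtered set including dark-matter
    compounds; predictions play no role in the draw itself, only in
    scoring.  The number of draws defaults to max(1, floor(0.1 * N)).
    Returns ``(library_ids, fitness, all_draw_fitnesses)``.
    """
    if draws is None:
        draws = max(1, library_size // 10)
    if len(filtered_pool_ids) < library_size:
        raise ValueError("filtered pool smaller than the requested library")
    rng = np.random.default_rng(seed)
    pool_rows = np.array([context.index[cid] for cid in filtered_pool_ids])
    best_ids: tuple[str, ...] | None = None
    best_fit = -np.inf
    all_fits = []
    for _ in range(draws):
        pick = rng.choice(len(pool_rows), size=library_size, replace=False)
        fit = context.score(pool_rows[pick])
        all_fits.append(fit)
        if fit > best_fit:
            best_fit = fit
            best_ids = tuple(filtered_pool_ids[i] for i in pick)
    assert best_ids is not None
    return best_ids, float(best_fit), all_fits
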