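"""The library fitness function.

The fitness of an N-compound library rewards predicted activity on many,
novel, and diverse protein families.  Each family represented among the
library's predicted targets contributes the sum of a geometric
progression whose scale factor is the family's novelty score and whose
length is the family's count — the number of distinct library compounds
predicted to interact with at least one target of the family:

    contribution(family) = novelty * (1 - r**count) / (1 - r)

with common ratio r = 0.99.  Repeat representation of a family keeps
increasing the score (repeat predictions raise the chance of a true hit)
but with diminishing returns, which preserves the incentive to cover new
families.  The fitness is the sum of contributions over families divided
by N; it is therefore only comparable between libraries of equal size.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from screenlib.annotation import NoveltyTable
from screenlib.predict import PredictedTargetSet

COMMON_RATIO = 0.99


@dataclass(frozen=True)
class FitnessValue:
    """A fitness score together with the library size it was computed at."""

    score: float
    n: int
    r: float = COMMON_RATIO


def geometric_sum(scale: float, r: float, count: int) -> float:
    """Sum of the first ``count`` terms of a geometric progression."""
    if not 0 <= r < 1:
        raise ValueError(f"common ratio must be in [0, 1), got {r}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return scale * (1.0 - r**count) / (1.0 - r)


def family_counts(
    library: Sequence[str],
    predictions: Mapping[str, PredictedTargetSet],
    assignment: Mapping[str, frozenset[str]],
) -> Counter[str]:
    """Distinct-compound counts per family for one library.

    A compound predicted on two targets of one family counts once for
    that family; a target belonging to two families increments both.
    """
    counts: Counter[str] = Counter()
    for cid in library:
        if cid not in predictions:
            raise KeyError(f"no prediction record for library compound {cid!r}")
        families: set[str] = set()
        for tgt in predictions[cid].targets:
            families |= assignment[tgt]
        counts.update(families)
    return counts


def fitness(
    library: Sequence[str],
    counts: Mapping[str, int],
    novelty_table: NoveltyTable,
    r: float = COMMON_RATIO,
) -> FitnessValue:
    """Eq-style fitness: novelty-scaled geometric sums over families, / N."""
    n = len(library)
    if n == 0:
        raise ValueError("fitness is undefined for an empty library")
    total = sum(
        geometric_sum(novelty_table.score(fam), r, count)
        for fam, count in counts.items()
    )
    return FitnessValue(score=total / n, n=n, r=r)


class FitnessContext:
    """Vectorized fitness evaluation over a fixed candidate pool.

    Precomputes a boolean compound x family membership matrix (compound i
    is predicted to interact with >= 1 target of family j) and the
    novelty vector, so that scoring a library reduces to a row-gather,
    a column count, and a dot product.  Used by the genetic algorithm,
    which evaluates thousands of libraries per run.
    """

    def __init__(
        self,
        pool_ids: Sequence[str],
        predictions: Mapping[str, PredictedTargetSet],
        assignment: Mapping[str, frozenset[str]],
        novelty_table: NoveltyTable,
        r: float = COMMON_RATIO,
    ) -> None:
        if not 0 <= r < 1:
            raise ValueError(f"common ratio must be in [0, 1), got {r}")
        self.pool_ids = tuple(pool_ids)
        self.index = {cid: i for i, cid in enumerate(self.pool_ids)}
        if len(self.index) != len(self.pool_ids):
            raise ValueError("pool ids must be unique")
        self.r = r
        families = sorted(
            {f for tgt_fams in assignment.values() for f in tgt_fams}
        )
        fam_index = {f: j for j, f in enumerate(families)}
        self.families = tuple(families)
        self.membership = np.zeros((len(self.pool_ids), len(families)), dtype=bool)
        self.n_targets = np.zeros(len(self.pool_ids), dtype=np.int64)
        for i, cid in enumerate(self.pool_ids):
            pred = predictions.get(cid)
            if pred is None:
                continue
            self.n_targets[i] = len(pred.targets)
            for tgt in pred.targets:
                for fam in assignment[tgt]:
                    self.membership[i, fam_index[fam]] = True
        self.novelty = np.array([novelty_table.score(f) for f in families])

    def counts(self, member_indices: np.ndarray) -> np.ndarray:
        """Distinct-compound count per family for the given pool rows."""
        return self.membership[member_indices].sum(axis=0)

    def score(self, member_indices: np.ndarray) -> float:
        """Fitness of the library given by pool row indices."""
        n = len(member_indices)
        if n == 0:
            raise ValueError("fitness is undefined for an empty library")
        counts = self.counts(np.asarray(member_indices))
        total = float(self.novelty @ ((1.0 - self.r**counts) / (1.0 - self.r)))
        return total / n

    def score_ids(self, library: Sequence[str]) -> float:
        """Fitness of a library given by compound ids."""
        return self.score(np.array([self.index[cid] for cid in library]))
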