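"""Protein-family assignment and family novelty scoring.

Targets are grouped into protein families (Pfam-style identifiers read
from a mapping table produced upstream by HMM scanning).  Targets with no
family assignment are pooled into a single dummy family: while they are
known to differ from the classified targets, nothing is known about how
they relate to each other, so conservatively they are treated as one
family.

Each family receives a novelty score: the fraction of its dated
bioactivity records published in or after a cutoff year (2010 by
default).  The score ranges over [0, 1] and proxies how recent the
research interest in the family is.  Families with no dated records
receive the mean score of the directly scored families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

DUMMY_FAMILY = "PF_DUMMY"
NOVELTY_CUTOFF_YEAR = 2010


def assign_families(
    target_ids: Iterable[str], mapping_table: pd.DataFrame
) -> dict[str, frozenset[str]]:
    """Map each target to its set of families.

    ``mapping_table`` has columns ``target_id`` and ``family_id``, with
    repeated rows for multi-family targets.  Targets absent from the
    table map to exactly ``{PF_DUMMY}``.
    """
    for col in ("target_id", "family_id"):
        if col not in mapping_table.columns:
            raise ValueError(f"mapping table is missing column: {col!r}")
    known = mapping_table.groupby("target_id")["family_id"].agg(frozenset).to_dict()
    return {
        tid: known.get(tid, frozenset({DUMMY_FAMILY})) for tid in target_ids
    }


@dataclass(frozen=True)
class NoveltyTable:
    """Per-family novelty scores plus the fallback for unscorable families.

    ``counts`` maps family -> (n_after, n_before); families listed in
    ``fallback_families`` had no dated records and carry the fallback
    (mean-of-scored) score.
    """

    scores: dict[str, float]
    fallback_score: float
    counts: dict[str, tuple[int, int]]
    fallback_families: frozenset[str] = frozenset()

    def score(self, family_id: str) -> float:
        """Score of a family; unknown families get the fallback score."""
        return self.scores.get(family_id, self.fallback_score)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family_id": fam,
                "score": self.scores[fam],
                "n_after": self.counts.get(fam, (0, 0))[0],
                "n_before": self.counts.get(fam, (0, 0))[1],
                "is_fallback": fam in self.fallback_families,
            }
            for fam in sorted(self.scores)
        ]
        return pd.DataFrame(
            rows, columns=["family_id", "score", "n_after", "n_before", "is_fallback"]
        )


def novelty_score(n_after: int, n_before: int) -> float:
    """Fraction of dated records in or after the cutoff year."""
    if n_after < 0 or n_before < 0:
        raise ValueError("record counts must be non-negative")
    total = n_after + n_before
    if total == 0:
        raise ZeroDivisionError("no dated records; use the fallback score")
    return n_after / total


def compute_novelty(
    records: pd.DataFrame,
    assignment: Mapping[str, frozenset[str]],
    cutoff_year: int = NOVELTY_CUTOFF_YEAR,
) -> NoveltyTable:
    """Score every family appearing in ``assignment`` from dated records.

    ``records`` needs columns ``target_id`` and ``year`` (nullable); one
    row per bioactivity record (one per merged compound-target pair).
    Each record contributes, through its target, to every family of that
    target.  Records with a null year are excluded from the counts; a
    record dated exactly the cutoff year counts toward the numerator.
    Families with no dated record receive the arithmetic mean of the
    directly scored families' scores.
    """
    for col in ("target_id", "year"):
        if col not in records.columns:
            raise ValueError(f"records table is missing column: {col!r}")
    counts: dict[str, list[int]] = {}
    years = pd.to_numeric(records["year"], errors="coerce")
    for tid, year in zip(records["target_id"], years):
        if pd.isna(year):
            continue
        for fam in assignment.get(tid, frozenset({DUMMY_FAMILY})):
            after, before = counts.setdefault(fam, [0, 0])
            if year >= cutoff_year:
                counts[fam][0] = after + 1
            else:
                counts[fam][1] = before + 1

    all_families = set().union(*assignment.values()) if assignment else set()
    all_families |= set(counts)
    scored = {
        fam: novelty_score(after, before)
        for fam, (after, before) in counts.items()
        if after + before > 0
    }
    fallback = sum(scored.values()) / len(scored) if scored else 0.0
    scores = {fam: scored.get(fam, fallback) for fam in all_families}
    return NoveltyTable(
        scores=scores,
        fallback_score=fallback,
        counts={fam: (a, b) for fam, (a, b) in counts.items()},
        fallback_families=frozenset(all_families - set(scored)),
    )


def target_novelty(
    target_id: str,
    assignment: Mapping[str, frozenset[str]],
    table: NoveltyTable,
) -> float:
    """Novelty of a target: the mean score of its families."""
    families = assignment.get(target_id, frozenset({DUMMY_FAMILY}))
    return sum(table.score(f) for f in families) / len(families)
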