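"""Similarity-based target prediction.

A query compound inherits the active targets of every reference compound
whose 2D fingerprint Tanimoto similarity to the query is at least the
prediction threshold (0.5 by default, where the probability of a correct
prediction has been estimated at 60% or higher for this class of model).
Queries whose maximum similarity to the whole reference falls below the
threshold receive no prediction and are flagged as "dark chemical
matter"; the remaining queries form the pool of candidate compounds
(PCC) from which libraries are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from screenlib.fingerprints import FingerprintArena, tanimoto_matrix
from screenlib.reference import ReferenceSet

PREDICTION_THRESHOLD = 0.5


@dataclass(frozen=True)
class PredictedTargetSet:
    """Predicted targets of one query with supporting similarity evidence.

    ``evidence`` maps each predicted target to the best similarity among
    the reference compounds that contributed it.  An empty target set
    marks the query as dark chemical matter.
    """

    compound_id: str
    max_similarity: float
    targets: frozenset[str] = frozenset()
    evidence: dict[str, float] = field(default_factory=dict)

    @property
    def is_dark(self) -> bool:
        return not self.targets


def predict_targets(
    queries: FingerprintArena,
    reference: ReferenceSet,
    threshold: float = PREDICTION_THRESHOLD,
    block_size: int = 1024,
) -> list[PredictedTargetSet]:
    """Predict targets for every query in the arena.

    The union of active targets over all reference entries at similarity
    >= ``threshold`` is assigned; computation proceeds in query blocks to
    bound memory.
    """
    if len(reference) == 0:
        return [
            PredictedTargetSet(compound_id=cid, max_similarity=0.0)
            for cid in queries.ids
        ]
    results: list[PredictedTargetSet] = []
    for start in range(0, len(queries), block_size):
        block = queries.words[start : start + block_size]
        sims = tanimoto_matrix(block, reference.arena.words)
        for row in range(sims.shape[0]):
            cid = queries.ids[start + row]
            row_sims = sims[row]
            max_sim = float(row_sims.max(initial=0.0))
            hits = np.flatnonzero(row_sims >= threshold)
            evidence: dict[str, float] = {}
            for j in hits:
                s = float(row_sims[j])
                for tgt in reference.active_targets[j]:
                    if s > evidence.get(tgt, -1.0):
                        evidence[tgt] = s
            results.append(
                PredictedTargetSet(
                    compound_id=cid,
                    max_similarity=max_sim,
                    targets=frozenset(evidence),
                    evidence=evidence,
                )
            )
    return results


def predictions_to_frame(predictions: list[PredictedTargetSet]):
    """Tabulate predictions: compound_id, max_similarity, targets (';'-joined)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "compound_id": p.compound_id,
                "max_similarity": p.max_similarity,
                "targets": ";".join(sorted(p.targets)),
            }
            for p in predictions
        ],
        columns=["compound_id", "max_similarity", "targets"],
    )


def frame_to_predictions(frame) -> list[PredictedTargetSet]:
    """Inverse of :func:`predictions_to_frame` (evidence is not round-tripped)."""
    out = []
    for row in frame.itertuples(index=False):
        raw = "" if not isinstance(row.targets, str) else row.targets
        targets = frozenset(t for t in raw.split(";") if t)
        out.append(
            PredictedTargetSet(
                compound_id=str(row.compound_id),
                max_similarity=float(row.max_similarity),
                targets=targets,
                evidence={},
            )
        )
    return out


def build_pcc(
    predictions: list[PredictedTargetSet],
) -> tuple[list[str], list[str]]:
    """Split queries into the pool of candidate compounds and dark matter.

    Returns ``(pcc_ids, dark_ids)`` in input order.  A compound belongs
    to the PCC iff it has at least one predicted target; its bioactivity
    count is the number of unique predicted (compound, target) pairs,
    i.e. ``len(p.targets)``.
    """
    pcc = [p.compound_id for p in predictions if not p.is_dark]
    dark = [p.compound_id for p in predictions if p.is_dark]
    return pcc, dark
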