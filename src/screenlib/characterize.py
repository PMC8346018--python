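"""Library and pool characterization.

Computes the descriptors used to compare candidate pools and selected
libraries: unique Murcko scaffolds, Taylor-Butina clusters (exclusion
spheres at a fixed Tanimoto similarity threshold), predicted target /
family / bioactivity counts, the median novelty of predicted targets,
and summary statistics of drug-likeness properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from screenlib.annotation import NoveltyTable, target_novelty
from screenlib.fingerprints import FingerprintArena, tanimoto_matrix
from screenlib.predict import PredictedTargetSet

CLUSTER_THRESHOLD = 0.4


def murcko_scaffold(smiles: str) -> str:
    """Murcko scaffold SMILES: ring systems plus linkers, substituents removed.

    Acyclic molecules yield the empty string, which counts as one
    scaffold class.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


@dataclass(frozen=True)
class ClusterAssignment:
    """A Taylor-Butina partition of an arena.

    ``cluster_of`` maps compound id -> cluster id (dense from 0, in
    creation order); ``centroids`` maps cluster id -> centroid compound
    id; ``singletons`` lists ids of single-member clusters.
    """

    cluster_of: dict[str, int]
    centroids: dict[int, str]
    singletons: frozenset[str] = frozenset()

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound_id": cid,
                "cluster_id": cl,
                "is_centroid": self.centroids[cl] == cid,
            }
            for cid, cl in self.cluster_of.items()
        ]
        return pd.DataFrame(rows, columns=["compound_id", "cluster_id", "is_centroid"])


def taylor_butina(
    arena: FingerprintArena,
    threshold: float = CLUSTER_THRESHOLD,
    block_size: int = 1024,
) -> ClusterAssignment:
    """Leader-style exclusion-sphere clustering at a similarity threshold.

    Neighbors are pairs with Tanimoto similarity >= ``threshold``.  The
    unassigned compound with the most unassigned neighbors becomes the
    next centroid (ties broken by input order) and absorbs its
    unassigned neighbors.  Compounds whose neighbors are all already
    assigned ("false singletons") end up as singletons, as do compounds
    with no neighbors at all.
    """
    n = len(arena)
    if n == 0:
        raise ValueError("cannot cluster an empty arena")
    neighbors: list[np.ndarray] = []
    for start in range(0, n, block_size):
        sims = tanimoto_matrix(arena.words[start : start + block_size], arena.words)
        for row in range(sims.shape[0]):
            i = start + row
            hits = np.flatnonzero(sims[row] >= threshold)
            neighbors.append(hits[hits != i])

    unassigned = np.ones(n, dtype=bool)
    cluster_ids = np.full(n, -1, dtype=np.int64)
    centroids: dict[int, str] = {}
    singletons: list[str] = []
    next_cluster = 0
    while unassigned.any():
        counts = np.array(
            [
                unassigned[nbrs].sum() if unassigned[i] else -1
                for i, nbrs in enumerate(neighbors)
            ]
        )
        leader = int(np.argmax(counts))  # argmax is first-index on ties
        members = [leader] + [
            int(j) for j in neighbors[leader] if unassigned[j]
        ]
        cluster_ids[members] = next_cluster
        unassigned[members] = False
        centroids[next_cluster] = arena.ids[leader]
        if len(members) == 1:
            singletons.append(arena.ids[leader])
        next_cluster += 1

    return ClusterAssignment(
        cluster_of={arena.ids[i]: int(cluster_ids[i]) for i in range(n)},
        centroids=centroids,
        singletons=frozenset(singletons),
    )


@dataclass(frozen=True)
class LibraryReport:
    """The characterization row for one library (or a whole pool)."""

    n: int
    fitness: float | None
    n_scaffolds: int
    n_clusters_represented: int
    n_targets: int
    n_families: int
    n_bioactivities: int
    median_novelty: float
    property_summary: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "fitness": self.fitness,
            "n_scaffolds": self.n_scaffolds,
            "n_clusters_represented": self.n_clusters_represented,
            "n_targets": self.n_targets,
            "n_families": self.n_families,
            "n_bioactivities": self.n_bioactivities,
            "median_novelty": self.median_novelty,
        }
        out.update({f"property_{k}": v for k, v in self.property_summary.items()})
        return out


def library_report(
    library: Sequence[str],
    predictions: Mapping[str, PredictedTargetSet],
    assignment: Mapping[str, frozenset[str]],
    novelty_table: NoveltyTable,
    clusters: ClusterAssignment | None = None,
    smiles: Mapping[str, str] | None = None,
    fitness: float | None = None,
) -> LibraryReport:
    """Characterize one library.

    Counts are over the union of predicted targets; the bioactivity
    count is the total of per-compound predicted (compound, target)
    pairs; median novelty is taken over unique predicted targets.
    Scaffold and cluster counts require ``smiles`` / ``clusters`` and
    are reported as 0 when unavailable.
    """
    targets: set[str] = set()
    n_bioactivities = 0
    for cid in library:
        pred = predictions.get(cid)
        if pred is None:
            continue
        targets |= pred.targets
        n_bioactivities += len(pred.targets)
    families = set()
    for tgt in targets:
        families |= assignment[tgt]
    novelties = sorted(
        target_novelty(tgt, assignment, novelty_table) for tgt in targets
    )
    median = float(np.median(novelties)) if novelties else float("nan")

    n_scaffolds = 0
    if smiles is not None:
        n_scaffolds = len({murcko_scaffold(smiles[cid]) for cid in library})
    n_clusters = 0
    if clusters is not None:
        n_clusters = len({clusters.cluster_of[cid] for cid in library})

    return LibraryReport(
        n=len(library),
        fitness=fitness,
        n_scaffolds=n_scaffolds,
        n_clusters_represented=n_clusters,
        n_targets=len(targets),
        n_families=len(families),
        n_bioactivities=n_bioactivities,
        median_novelty=median,
    )


def property_summary(smiles_list: Sequence[str]) -> dict[str, float]:
    """Median QED and logP of a compound set (for report tables)."""
    from rdkit.Chem import Descriptors, QED

    qeds, logps = [], []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        qeds.append(QED.default(mol))
        logps.append(Descriptors.MolLogP(mol))
    return {
        "median_qed": float(np.median(qeds)) if qeds else float("nan"),
        "median_logp": float(np.median(logps)) if logps else float("nan"),
    }
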