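"""Murcko scaffolds, Taylor-Butina clustering, and library reports."""

import numpy as np
import pandas as pd
import pytest

from screenlib.annotation import assign_families, compute_novelty
from screenlib.characterize import (
    library_report,
    murcko_scaffold,
    taylor_butina,
)
from screenlib.fingerprints import FingerprintArena, unpack_bits
from screenlib.predict import PredictedTargetSet


class TestMurckoScaffold:
    def test_toluene_reduces_to_benzene(self):
        assert murcko_scaffold("Cc1ccccc1") == "c1ccccc1"

    def test_cresol_isomers_share_a_scaffold(self):
        assert murcko_scaffold("Cc1ccccc1O") == murcko_scaffold("Cc1ccc(O)cc1")

    def test_benzene_is_a_fixed_point(self):
        assert murcko_scaffold("c1ccccc1") == "c1ccccc1"

    def test_acyclic_molecule_gives_empty_scaffold(self):
        assert murcko_scaffold("CCO") == ""

    def test_linker_is_retained(self):
        scaffold = murcko_scaffold("COc1ccc(CCc2ccccc2)cc1")
        assert scaffold == murcko_scaffold("c1ccc(CCc2ccccc2)cc1")


def brute_force_butina(arena, threshold):
    """Independent leader-algorithm reference on explicit bit sets."""
    bits = unpack_bits(arena.words)
    sets = [set(np.flatnonzero(b)) for b in bits]
    n = len(sets)

    def sim(i, j):
        union = sets[i] | sets[j]
        return len(sets[i] & sets[j]) / len(union) if union else 0.0

    neighbors = {
        i: [j for j in range(n) if j != i and sim(i, j) >= threshold] for i in range(n)
    }
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best, best_count = None, -1
        for i in range(n):  # input order tie-break
            if i not in unassigned:
                continue
            count = sum(1 for j in neighbors[i] if j in unassigned)
            if count > best_count:
                best, best_count = i, count
        members = [best] + [j for j in neighbors[best] if j in unassigned]
        clusters.append(members)
        unassigned -= set(members)
    return clusters


class TestTaylorButina:
    def test_identical_pair_forms_one_cluster(self):
        arena = FingerprintArena.from_bitsets(
            [("a", {1, 2, 3}), ("b", {1, 2, 3})], n_bits=64
        )
        out = taylor_butina(arena, threshold=0.4)
        assert out.n_clusters == 1
        assert out.cluster_of["a"] == out.cluster_of["b"]
        assert not out.singletons

    def test_mutually_dissimilar_set_is_all_singletons(self):
        arena = FingerprintArena.from_bitsets(
            [("a", {0, 1}), ("b", {10, 11}), ("c", {20, 21})], n_bits=64
        )
        out = taylor_butina(arena, threshold=0.4)
        assert out.n_clusters == 3
        assert out.singletons == {"a", "b", "c"}

    def test_false_singleton_handling(self):
        # b neighbors a and c; a-c are not neighbors; a and c each have
        # one more neighbor. The leader (a, by input-order tie-break over
        # count 2) absorbs b and a2; then c leads c2; nobody is left with
        # unassigned neighbors.
        arena = FingerprintArena.from_bitsets(
            [
                ("a", set(range(0, 10))),
                ("b", set(range(5, 15))),
                ("c", set(range(10, 20))),
                ("a2", set(range(0, 11))),
                ("c2", set(range(10, 21))),
            ],
            n_bits=64,
        )
        out = taylor_butina(arena, threshold=0.3)
        oracle = brute_force_butina(arena, 0.3)
        ids = arena.ids
        got = sorted(sorted(ids[i] for i in c) for c in _clusters_of(out, ids))
        want = sorted(sorted(ids[i] for i in c) for c in oracle)
        assert got == want

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        arena = FingerprintArena.from_bitsets(
            [
                (f"m{i}", set(rng.choice(96, size=rng.integers(5, 40), replace=False)))
                for i in range(n)
            ],
            n_bits=128,
        )
        out = taylor_butina(arena, threshold=0.4)
        oracle = brute_force_butina(arena, 0.4)
        got = sorted(sorted(arena.ids[i] for i in c) for c in _clusters_of(out, arena.ids))
        want = sorted(sorted(arena.ids[i] for i in c) for c in oracle)
        assert got == want

    def test_partition_and_centroid_properties(self):
        rng = np.random.default_rng(77)
        arena = FingerprintArena.from_bitsets(
            [
                (f"m{i}", set(rng.choice(96, size=20, replace=False)))
                for i in range(30)
            ],
            n_bits=128,
        )
        out = taylor_butina(arena, threshold=0.3)
        # every compound is in exactly one cluster, ids dense from 0
        assert set(out.cluster_of) == set(arena.ids)
        assert set(out.cluster_of.values()) == set(range(out.n_clusters))
        # every non-singleton member is within threshold of its centroid
        from screenlib.fingerprints import tanimoto

        idx = {cid: i for i, cid in enumerate(arena.ids)}
        for cid, cl in out.cluster_of.items():
            centroid = out.centroids[cl]
            if cid != centroid and cid not in out.singletons:
                s = tanimoto(arena.words[idx[cid]], arena.words[idx[centroid]])
                assert s >= 0.3


def _clusters_of(assignment, ids):
    by_cluster = {}
    idx = {cid: i for i, cid in enumerate(ids)}
    for cid, cl in assignment.cluster_of.items():
        by_cluster.setdefault(cl, []).append(idx[cid])
    return list(by_cluster.values())


class TestLibraryReport:
    def _inputs(self):
        preds = {
            "a": PredictedTargetSet("a", 0.9, frozenset({"T1"})),
            "b": PredictedTargetSet("b", 0.8, frozenset({"T1", "T2"})),
            "c": PredictedTargetSet("c", 0.4),
        }
        fam = pd.DataFrame(
            [("T1", "F"), ("T2", "G")], columns=["target_id", "family_id"]
        )
        assignment = assign_families(["T1", "T2"], fam)
        records = pd.DataFrame(
            [("T1", 2015), ("T1", 2005), ("T2", 2012)], columns=["target_id", "year"]
        )
        novelty = compute_novelty(records, assignment)
        return preds, assignment, novelty

    def test_hand_counts(self):
        preds, assignment, novelty = self._inputs()
        report = library_report(["a", "b", "c"], preds, assignment, novelty)
        assert report.n_targets == 2
        assert report.n_bioactivities == 3
        assert report.n_families == 2
        assert report.median_novelty == pytest.approx((0.5 + 1.0) / 2)

    def test_empty_library(self):
        preds, assignment, novelty = self._inputs()
        report = library_report([], preds, assignment, novelty)
        assert report.n == 0
        assert report.n_targets == report.n_bioactivities == report.n_families == 0

    def test_order_invariance(self):
        preds, assignment, novelty = self._inputs()
        fwd = library_report(["a", "b", "c"], preds, assignment, novelty)
        rev = library_report(["c", "b", "a"], preds, assignment, novelty)
        assert fwd == rev

    def test_scaffold_and_cluster_counts(self):
        preds, assignment, novelty = self._inputs()
        smiles = {"a": "Cc1ccccc1", "b": "Cc1ccc(C)cc1", "c": "CCO"}
        arena = FingerprintArena.from_smiles([(k, v) for k, v in smiles.items()])
        clusters = taylor_butina(arena, threshold=0.4)
        report = library_report(
            ["a", "b", "c"], preds, assignment, novelty,
            clusters=clusters, smiles=smiles,
        )
        assert report.n_scaffolds == 2  # benzene + empty acyclic scaffold
        assert report.n_clusters_represented == clusters.n_clusters
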