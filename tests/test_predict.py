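"""Tanimoto similarity and similarity-based target prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screenlib.fingerprints import (
    FingerprintArena,
    morgan_fingerprint,
    pack_bits,
    tanimoto,
    tanimoto_matrix,
    unpack_bits,
)
from screenlib.predict import (
    PredictedTargetSet,
    build_pcc,
    frame_to_predictions,
    predict_targets,
    predictions_to_frame,
)
from screenlib.reference import ReferenceSet


def _fp(bits, n_bits=256):
    return FingerprintArena.from_bitsets([("x", bits)], n_bits=n_bits).words[0]


class TestTanimoto:
    def test_identical_nonzero(self):
        a = _fp(range(10))
        assert tanimoto(a, a) == 1.0

    def test_disjoint(self):
        assert tanimoto(_fp(range(10)), _fp(range(10, 20))) == 0.0

    def test_direct_bit_counting(self):
        a = _fp({0, 1, 2, 3, 4, 5, 6})  # |a|=7
        b = _fp({4, 5, 6, 7, 8, 9, 10, 11})  # |b|=8, inter=3, union=12
        assert tanimoto(a, b) == pytest.approx(0.25)

    def test_both_empty_defined_as_zero(self):
        assert tanimoto(_fp([]), _fp([])) == 0.0

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            tanimoto(_fp([1], n_bits=128), _fp([1], n_bits=256))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 255), max_size=60),
        b=st.sets(st.integers(0, 255), max_size=60),
    )
    def test_symmetry_and_bounds(self, a, b):
        fa, fb = _fp(a), _fp(b)
        s = tanimoto(fa, fb)
        assert s == tanimoto(fb, fa)
        assert 0.0 <= s <= 1.0
        expected = len(a & b) / len(a | b) if (a | b) else 0.0
        assert s == pytest.approx(expected)

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        A = rng.integers(0, 2, size=(7, 256)).astype(np.uint8)
        B = rng.integers(0, 2, size=(9, 256)).astype(np.uint8)
        pa, pb = pack_bits(A), pack_bits(B)
        M = tanimoto_matrix(pa, pb)
        for i in range(7):
            for j in range(9):
                assert M[i, j] == pytest.approx(tanimoto(pa[i], pb[j]))


def test_pack_unpack_round_trip():
    rng = np.random.default_rng(2)
    bits = rng.integers(0, 2, size=(5, 2048)).astype(np.uint8)
    assert (unpack_bits(pack_bits(bits)) == bits).all()


def test_morgan_fingerprint_is_deterministic_and_sized():
    a = morgan_fingerprint("COc1ccc(C(=O)Nc2ccccc2)cc1")
    b = morgan_fingerprint("COc1ccc(C(=O)Nc2ccccc2)cc1")
    assert (a == b).all() and a.size == 2048 // 64


def _synthetic_reference(rng, n_entries, n_bits=512, n_targets=20):
    items, targets = [], []
    for i in range(n_entries):
        items.append((f"R{i}", set(rng.choice(n_bits, size=rng.integers(20, 80), replace=False))))
        k = int(rng.integers(1, 4))
        targets.append(frozenset(f"T{t}" for t in rng.choice(n_targets, size=k, replace=False)))
    arena = FingerprintArena.from_bitsets(items, n_bits=n_bits)
    return ReferenceSet(arena=arena, active_targets=tuple(targets), pairs=pd.DataFrame())


def _brute_force(queries, reference, threshold):
    """Exhaustive all-pairs oracle, bit sets and a double loop."""
    out = []
    qbits = unpack_bits(queries.words)
    rbits = unpack_bits(reference.arena.words)
    for i, cid in enumerate(queries.ids):
        qa = set(np.flatnonzero(qbits[i]))
        best = 0.0
        targets = set()
        for j in range(len(reference)):
            rb = set(np.flatnonzero(rbits[j]))
            union = qa | rb
            sim = len(qa & rb) / len(union) if union else 0.0
            best = max(best, sim)
            if sim >= threshold:
                targets |= reference.active_targets[j]
        out.append((cid, best, frozenset(targets)))
    return out


class TestPredict:
    def test_identical_query_inherits_entry_targets(self, rng):
        ref = _synthetic_reference(rng, 5)
        queries = FingerprintArena.from_bitsets(
            [("q0", set(np.flatnonzero(unpack_bits(ref.arena.words)[2])))], n_bits=512
        )
        (pred,) = predict_targets(queries, ref)
        assert pred.max_similarity == 1.0
        assert pred.targets >= ref.active_targets[2]

    def test_boundary_0_49_is_dark_and_0_50_is_not(self):
        # |a|=74, |b|=75, inter 49, union 100 -> 0.49; adding one more
        # shared bit gives 50/100 = 0.50 exactly
        ref_bits = set(range(25, 100))
        ref = ReferenceSet(
            arena=FingerprintArena.from_bitsets([("r", ref_bits)], n_bits=256),
            active_targets=(frozenset({"T1"}),),
            pairs=pd.DataFrame(),
        )
        dark_q = FingerprintArena.from_bitsets([("q", set(range(74)))], n_bits=256)
        (pred,) = predict_targets(dark_q, ref)
        assert pred.max_similarity == pytest.approx(0.49)
        assert pred.is_dark

        lit_q = FingerprintArena.from_bitsets([("q", set(range(75)))], n_bits=256)
        (pred,) = predict_targets(lit_q, ref)
        assert pred.max_similarity == pytest.approx(0.50)
        assert pred.targets == {"T1"}

    def test_oracle_equivalence_on_synthetic_arena(self, rng):
        ref = _synthetic_reference(rng, 50)
        queries = FingerprintArena.from_bitsets(
            [
                (f"Q{i}", set(rng.choice(512, size=rng.integers(20, 80), replace=False)))
                for i in range(200)
            ],
            n_bits=512,
        )
        preds = predict_targets(queries, ref, threshold=0.5, block_size=64)
        oracle = _brute_force(queries, ref, threshold=0.5)
        assert len(preds) == len(oracle)
        for p, (cid, best, targets) in zip(preds, oracle):
            assert p.compound_id == cid
            assert p.max_similarity == pytest.approx(best)
            assert p.targets == targets

    def test_threshold_monotonicity(self, rng):
        ref = _synthetic_reference(rng, 30)
        queries = FingerprintArena.from_bitsets(
            [(f"Q{i}", set(rng.choice(512, size=50, replace=False))) for i in range(40)],
            n_bits=512,
        )
        prev = predict_targets(queries, ref, threshold=0.3)
        for thr in (0.4, 0.5, 0.6):
            cur = predict_targets(queries, ref, threshold=thr)
            for lo, hi in zip(cur, prev):
                assert lo.targets <= hi.targets
            prev = cur

    def test_evidence_is_at_least_threshold(self, rng):
        ref = _synthetic_reference(rng, 30)
        queries = FingerprintArena.from_bitsets(
            [(f"Q{i}", set(rng.choice(512, size=50, replace=False))) for i in range(20)],
            n_bits=512,
        )
        for p in predict_targets(queries, ref, threshold=0.4):
            assert all(v >= 0.4 for v in p.evidence.values())
            if p.targets:
                assert p.max_similarity >= 0.4

    def test_empty_reference_gives_empty_pool(self):
        ref = ReferenceSet(
            arena=FingerprintArena.from_bitsets([], n_bits=256),
            active_targets=(),
            pairs=pd.DataFrame(),
        )
        queries = FingerprintArena.from_bitsets([("q", {1, 2})], n_bits=256)
        preds = predict_targets(queries, ref)
        pcc, dark = build_pcc(preds)
        assert pcc == [] and dark == ["q"]


def test_build_pcc_counts():
    preds = [
        PredictedTargetSet("a", 0.9, frozenset({"T1", "T2"})),
        PredictedTargetSet("b", 0.4),
        PredictedTargetSet("c", 0.7, frozenset({"T1"})),
    ]
    pcc, dark = build_pcc(preds)
    assert pcc == ["a", "c"] and dark == ["b"]
    assert sum(len(p.targets) for p in preds) == 3  # pool bioactivity total


def test_predictions_frame_round_trip():
    preds = [
        PredictedTargetSet("a", 0.9, frozenset({"T1", "T2"}), {"T1": 0.9, "T2": 0.6}),
        PredictedTargetSet("b", 0.3),
    ]
    back = frame_to_predictions(predictions_to_frame(preds))
    assert [(p.compound_id, p.max_similarity, p.targets) for p in back] == [
        ("a", 0.9, frozenset({"T1", "T2"})),
        ("b", 0.3, frozenset()),
    ]
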