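"""Morgan fingerprints and fast Tanimoto similarity over packed bit arenas.

Fingerprints are hashed circular-substructure fingerprints (radius 2,
2048 bits by default).  An arena stores many fingerprints as rows of a
packed ``uint64`` matrix so that Tanimoto similarities can be computed
blockwise with vectorized popcounts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

DEFAULT_BITS = 2048
DEFAULT_RADIUS = 2

_GENERATORS: dict[tuple[int, int], object] = {}


def _generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _GENERATORS[key]


def morgan_fingerprint(
    smiles: str, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_BITS
) -> np.ndarray:
    """Fingerprint of one SMILES as a packed uint64 row (n_bits/64 words)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    fp = _generator(radius, n_bits).GetFingerprintAsNumPy(mol)
    return pack_bits(fp[None, :])[0]


def pack_bits(bits: np.ndarray) -> np.ndarray:
    """Pack an (n, n_bits) 0/1 array into (n, n_bits/64) uint64 words."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.ndim != 2 or bits.shape[1] % 64:
        raise ValueError("expected (n, n_bits) with n_bits a multiple of 64")
    packed8 = np.packbits(bits, axis=1, bitorder="little")
    return packed8.view(np.uint64)


def unpack_bits(words: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pack_bits`."""
    packed8 = np.ascontiguousarray(words).view(np.uint8)
    return np.unpackbits(packed8, axis=1, bitorder="little")


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity of two packed fingerprints.

    Defined as 0 when both fingerprints have no bits set.
    """
    a = np.asarray(a, dtype=np.uint64)
    b = np.asarray(b, dtype=np.uint64)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.bitwise_count(a & b).sum())
    union = int(np.bitwise_count(a | b).sum())
    return inter / union if union else 0.0


def tanimoto_matrix(queries: np.ndarray, references: np.ndarray) -> np.ndarray:
    """All-pairs Tanimoto matrix, shape (n_queries, n_references).

    Pairs where both fingerprints are empty score 0.
    """
    q = np.asarray(queries, dtype=np.uint64)
    r = np.asarray(references, dtype=np.uint64)
    if q.shape[1] != r.shape[1]:
        raise ValueError("fingerprint word-length mismatch")
    pop_q = np.bitwise_count(q).sum(axis=1).astype(np.int64)
    pop_r = np.bitwise_count(r).sum(axis=1).astype(np.int64)
    inter = np.zeros((q.shape[0], r.shape[0]), dtype=np.int64)
    for w in range(q.shape[1]):
        inter += np.bitwise_count(q[:, w, None] & r[None, :, w]).astype(np.int64)
    union = pop_q[:, None] + pop_r[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim


@dataclass(frozen=True)
class FingerprintArena:
    """Identifiers plus a packed fingerprint matrix, one row per compound."""

    ids: tuple[str, ...]
    words: np.ndarray  # (n, n_bits/64) uint64
    n_bits: int = DEFAULT_BITS

    def __post_init__(self) -> None:
        if self.words.shape != (len(self.ids), self.n_bits // 64):
            raise ValueError("arena shape inconsistent with ids/n_bits")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_smiles(
        cls,
        pairs: Iterable[tuple[str, str]],
        radius: int = DEFAULT_RADIUS,
        n_bits: int = DEFAULT_BITS,
    ) -> "FingerprintArena":
        """Build an arena from ``(id, smiles)`` pairs."""
        ids, rows = [], []
        gen = _generator(radius, n_bits)
        for cid, smi in pairs:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"unparseable SMILES for {cid!r}: {smi!r}")
            ids.append(cid)
            rows.append(gen.GetFingerprintAsNumPy(mol))
        words = (
            pack_bits(np.vstack(rows))
            if rows
            else np.empty((0, n_bits // 64), dtype=np.uint64)
        )
        return cls(ids=tuple(ids), words=words, n_bits=n_bits)

    @classmethod
    def from_bitsets(
        cls, items: Sequence[tuple[str, Iterable[int]]], n_bits: int = DEFAULT_BITS
    ) -> "FingerprintArena":
        """Build an arena from explicit on-bit index sets (synthetic arenas)."""
        bits = np.zeros((len(items), n_bits), dtype=np.uint8)
        ids = []
        for row, (cid, on_bits) in enumerate(items):
            ids.append(cid)
            idx = list(on_bits)
            if idx and (min(idx) < 0 or max(idx) >= n_bits):
                raise ValueError(f"bit index out of range for {cid!r}")
            bits[row, idx] = 1
        return cls(ids=tuple(ids), words=pack_bits(bits), n_bits=n_bits)

    def save(self, path) -> None:
        np.savez_compressed(path, ids=np.array(self.ids), words=self.words, n_bits=self.n_bits)

    @classmethod
    def load(cls, path) -> "FingerprintArena":
        data = np.load(path, allow_pickle=False)
        return cls(
            ids=tuple(str(x) for x in data["ids"]),
            words=data["words"].astype(np.uint64),
            n_bits=int(data["n_bits"]),
        )
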