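"""Curation of a bioactivity table into the "active" prediction reference.

The input is a flat table of compound-target activity measurements whose
column vocabulary mirrors the field names of large public bioactivity
databases (assay confidence score, validity comment, duplicate flag,
activity type/relation/comment, value, units, publication year).  The
curation keeps only trustworthy, quantitative measurements, converts
mass-concentration units to nM, merges replicate compound-target pairs by
their median value, and labels pairs with a merged potency of at most
10,000 nM as "active".  Active pairs, grouped per unique standardized
structure, form the reference set for similarity-based target prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from screenlib.fingerprints import DEFAULT_BITS, DEFAULT_RADIUS, FingerprintArena
from screenlib.standardize import RawStructure, standardize

ALLOWED_TYPES = frozenset({"Kd", "Potency", "AC50", "IC50", "Ki", "EC50"})
ALLOWED_UNITS = frozenset({"nM", "ug.mL^-1"})
ACTIVE_THRESHOLD_NM = 10_000.0

REQUIRED_COLUMNS = (
    "compound_id",
    "smiles",
    "target_id",
    "confidence_score",
    "data_validity_comment",
    "potential_duplicate",
    "standard_type",
    "activity_comment",
    "standard_relation",
    "standard_value",
    "standard_units",
    "year",
)


def _is_null(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or x is pd.NA or x == ""


def filter_records(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the record-level selection criteria.

    Returns ``(kept, excluded)`` where ``excluded`` carries a ``reason``
    column naming, for each dropped record, the first criterion it failed:

    - ``confidence``: assay confidence score not in {6, 7, 8, 9}
      (single protein or protein complex assays only);
    - ``validity``: data validity comment neither null nor
      "manually validated";
    - ``duplicate``: flagged as a potential duplicate;
    - ``type``: activity type outside {Kd, Potency, AC50, IC50, Ki, EC50};
    - ``inconclusive``: activity comment marks the measurement
      inconclusive/unspecified;
    - ``no_relation``: no relation recorded and the comment does not
      assert activity;
    - ``units``: units outside the supported vocabulary.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"bioactivity table is missing columns: {missing}")

    reasons = pd.Series("", index=records.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        mask = mask & (reasons == "")
        reasons[mask] = reason

    conf = pd.to_numeric(records["confidence_score"], errors="coerce")
    flag(~conf.isin([6, 7, 8, 9]), "confidence")

    validity = records["data_validity_comment"]
    flag(~(validity.map(_is_null) | (validity == "manually validated")), "validity")

    flag(pd.to_numeric(records["potential_duplicate"], errors="coerce") != 0, "duplicate")
    flag(~records["standard_type"].isin(ALLOWED_TYPES), "type")
    flag(
        records["activity_comment"].isin(["Inconclusive", "inconclusive", "unspecified"]),
        "inconclusive",
    )
    relation_null = records["standard_relation"].map(_is_null)
    comment_active = records["activity_comment"].isin(["Active", "active"])
    flag(relation_null & ~comment_active, "no_relation")
    flag(~records["standard_units"].isin(ALLOWED_UNITS), "units")

    kept = records[reasons == ""].copy()
    excluded = records[reasons != ""].copy()
    excluded["reason"] = reasons[reasons != ""]
    return kept, excluded


def ugml_to_nM(value: float, mw: float) -> float:
    """Convert a µg/mL concentration to nM given the molecular weight in Da."""
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    return value * 1e6 / mw


def nM_to_ugml(value: float, mw: float) -> float:
    """Inverse of :func:`ugml_to_nM`."""
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    return value * mw / 1e6


def _standardize_column(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``smiles_std`` (and drop structures that fail standardization)."""
    cache: dict[str, str | None] = {}
    out = []
    for smi in records["smiles"]:
        if smi not in cache:
            rec = standardize(RawStructure(id="", smiles=smi))
            cache[smi] = None if not hasattr(rec, "smiles_std") else rec.smiles_std
        out.append(cache[smi])
    records = records.assign(smiles_std=out)
    return records[records["smiles_std"].notna()]


def normalize_units(records: pd.DataFrame) -> pd.DataFrame:
    """Return records with ``value_nM`` populated for every row.

    µg/mL values are converted with the monoisotopic molecular weight of
    the standardized structure.
    """
    if "smiles_std" not in records.columns:
        records = _standardize_column(records)
    values = pd.to_numeric(records["standard_value"], errors="coerce").to_numpy(float)
    out = values.copy()
    mask = (records["standard_units"] == "ug.mL^-1").to_numpy()
    if mask.any():
        mws = np.array(
            [
                Descriptors.ExactMolWt(Chem.MolFromSmiles(s))
                for s in records.loc[mask, "smiles_std"]
            ]
        )
        out[mask] = values[mask] * 1e6 / mws
    return records.assign(value_nM=out)


def merge_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Merge replicate measurements of one (structure, target) pair.

    The merged activity is the median of the replicate values (mean of
    the two middle values for even counts).  The merged year is the
    earliest recorded year among dated replicates (the first report of
    the bioactivity); pairs with no dated replicate keep a null year.
    """
    if "smiles_std" not in records.columns:
        records = _standardize_column(records)
    if "value_nM" not in records.columns:
        records = normalize_units(records)
    years = pd.to_numeric(records.get("year"), errors="coerce")
    merged = (
        records.assign(_year=years)
        .groupby(["smiles_std", "target_id"], as_index=False, sort=True)
        .agg(value_nM=("value_nM", "median"), year=("_year", "min"))
    )
    return merged


@dataclass(frozen=True)
class ReferenceSet:
    """The prediction reference: active pairs plus a fingerprint arena.

    ``arena`` holds one fingerprint per unique active structure;
    ``active_targets[i]`` is the set of targets on which structure ``i``
    is active.  ``pairs`` retains the merged (structure, target,
    value_nM, year) table for novelty scoring.
    """

    arena: FingerprintArena
    active_targets: tuple[frozenset[str], ...]
    pairs: pd.DataFrame

    def __len__(self) -> int:
        return len(self.arena)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset().union(*self.active_targets) if self.active_targets else frozenset()


def build_reference(
    merged: pd.DataFrame,
    threshold_nM: float = ACTIVE_THRESHOLD_NM,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_BITS,
) -> ReferenceSet:
    """Label merged pairs at or below ``threshold_nM`` active and build the reference.

    Structures with no active target are omitted entirely.
    """
    active = merged[merged["value_nM"] <= threshold_nM]
    grouped = active.groupby("smiles_std", sort=True)["target_id"].agg(set)
    arena = FingerprintArena.from_smiles(
        [(smi, smi) for smi in grouped.index], radius=radius, n_bits=n_bits
    )
    return ReferenceSet(
        arena=arena,
        active_targets=tuple(frozenset(t) for t in grouped.to_list()),
        pairs=active.reset_index(drop=True),
    )
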