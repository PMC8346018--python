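"""Synthetic fixtures emulating the statistical shape of real inputs.

Two independent tiers:

* the **annotation tier** fabricates a candidate pool with predicted
  targets, a target-to-family map, and dated bioactivity records — no
  chemistry backend involved.  It reproduces the skewed statistics seen
  in large curated bioactivity extracts: a minority of promiscuous
  compounds, heavy-tailed family sizes, a fraction of compounds with no
  predictable target ("dark chemical matter"), and family novelty scores
  concentrated around 0.7 via Beta-distributed publication-year mixes;

* the **chemistry tier** enumerates substituted heteroaromatic
  structures from a small scaffold/substituent grammar whose members are
  guaranteed to pass the drug-likeness filters, plus deliberate
  violators each designed to break exactly one filter rule.

All outputs are deterministic functions of the configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from screenlib.annotation import (
    DUMMY_FAMILY,
    NoveltyTable,
    assign_families,
    compute_novelty,
)
from screenlib.predict import PredictedTargetSet


@dataclass(frozen=True)
class FixtureConfig:
    """Shape parameters of the annotation-tier fixture.

    ``promiscuity`` is the mean number of predicted targets per
    non-dark compound; ``dark_fraction`` the share of compounds with no
    prediction; ``novelty_shape`` the Beta parameters of per-family
    recency (mean a/(a+b) = 0.7 at the defaults, matching the typical
    center of family novelty distributions); ``year_range`` bounds the
    publication years of the synthetic bioactivity records.
    """

    n_compounds: int = 10_000
    n_targets: int = 300
    n_families: int = 120
    seed: int = 0
    promiscuity: float = 3.0
    dark_fraction: float = 0.3
    novelty_shape: tuple[float, float] = (3.5, 1.5)
    year_range: tuple[int, int] = (1995, 2020)
    multi_family_fraction: float = 0.08
    unmapped_fraction: float = 0.02
    undated_fraction: float = 0.03

    def __post_init__(self) -> None:
        for frac in (
            self.dark_fraction,
            self.multi_family_fraction,
            self.unmapped_fraction,
            self.undated_fraction,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_compounds, self.n_targets, self.n_families) < 1:
            raise ValueError("counts must be positive")
        if self.promiscuity < 1:
            raise ValueError("promiscuity must be >= 1")


@dataclass(frozen=True)
class AnnotationFixture:
    """Everything the fitness/GA/novelty stages need, fully synthetic."""

    pool_ids: tuple[str, ...]
    predictions: dict[str, PredictedTargetSet]
    family_map: pd.DataFrame  # target_id, family_id
    records: pd.DataFrame  # target_id, year (nullable)
    assignment: Mapping[str, frozenset[str]]
    novelty: NoveltyTable

    @property
    def pcc_ids(self) -> tuple[str, ...]:
        return tuple(
            cid for cid in self.pool_ids if not self.predictions[cid].is_dark
        )


def _zipf_weights(n: int, exponent: float = 1.0) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def synth_annotation_pool(cfg: FixtureConfig) -> AnnotationFixture:
    """Generate the annotation-tier fixture.

    Per-compound predicted-target counts follow a zero-truncated
    geometric law with the configured mean; targets are drawn with
    Zipf-skewed popularity, so a few targets dominate the predictions.
    Each target belongs to one Zipf-drawn family (a small fraction get a
    second family; another small fraction are left unmapped and fall
    into the dummy family).  Per-family record years are Bernoulli
    splits around the family's Beta-drawn recency, so realized novelty
    scores follow the configured Beta law.
    """
    rng = np.random.default_rng(cfg.seed)
    pool_ids = tuple(f"C{i:06d}" for i in range(cfg.n_compounds))
    target_ids = [f"T{i:04d}" for i in range(cfg.n_targets)]
    family_ids = [f"FAM{i:04d}" for i in range(cfg.n_families)]

    # target -> families (Zipf-skewed family sizes)
    fam_weights = _zipf_weights(cfg.n_families)
    rows = []
    n_unmapped = int(round(cfg.unmapped_fraction * cfg.n_targets))
    for i, tid in enumerate(target_ids):
        if i < n_unmapped:
            continue  # left out of the map -> dummy family
        fams = {family_ids[int(rng.choice(cfg.n_families, p=fam_weights))]}
        if rng.random() < cfg.multi_family_fraction:
            fams.add(family_ids[int(rng.choice(cfg.n_families, p=fam_weights))])
        rows.extend({"target_id": tid, "family_id": f} for f in sorted(fams))
    family_map = pd.DataFrame(rows, columns=["target_id", "family_id"])

    # predictions: dark compounds empty, the rest zero-truncated geometric
    target_weights = _zipf_weights(cfg.n_targets, exponent=0.8)
    dark = rng.random(cfg.n_compounds) < cfg.dark_fraction
    # zero-truncated geometric with mean m has success prob 1/m
    p_geom = 1.0 / cfg.promiscuity
    predictions: dict[str, PredictedTargetSet] = {}
    for i, cid in enumerate(pool_ids):
        if dark[i]:
            predictions[cid] = PredictedTargetSet(
                compound_id=cid, max_similarity=float(rng.uniform(0.0, 0.5))
            )
            continue
        k = min(int(rng.geometric(p_geom)), cfg.n_targets)
        picks = rng.choice(cfg.n_targets, size=k, replace=False, p=target_weights)
        targets = frozenset(target_ids[j] for j in picks)
        sims = {t: float(rng.uniform(0.5, 1.0)) for t in sorted(targets)}
        predictions[cid] = PredictedTargetSet(
            compound_id=cid,
            max_similarity=max(sims.values()),
            targets=targets,
            evidence=sims,
        )

    # dated bioactivity records per target, with Beta-law family recency
    a, b = cfg.novelty_shape
    fam_recency = {f: float(rng.beta(a, b)) for f in family_ids}
    fam_recency[DUMMY_FAMILY] = float(rng.beta(a, b))
    assignment = assign_families(target_ids, family_map)
    lo, hi = cfg.year_range
    rec_rows = []
    for tid in target_ids:
        fams = assignment[tid]
        recency = float(np.mean([fam_recency[f] for f in fams]))
        n_rec = 1 + int(rng.geometric(0.15))
        for _ in range(n_rec):
            if rng.random() < cfg.undated_fraction:
                year = None
            elif rng.random() < recency:
                year = int(rng.integers(2010, hi + 1))
            else:
                year = int(rng.integers(lo, 2010))
            rec_rows.append({"target_id": tid, "year": year})
    records = pd.DataFrame(rec_rows, columns=["target_id", "year"])

    novelty = compute_novelty(records, assignment)
    return AnnotationFixture(
        pool_ids=pool_ids,
        predictions=predictions,
        family_map=family_map,
        records=records,
        assignment=assignment,
        novelty=novelty,
    )


# --------------------------------------------------------------------------
# chemistry tier
# --------------------------------------------------------------------------

#: Scaffold cores of the compliant grammar; {R} is the substitution point.
#: Every (core, substituent) combination passes all property filters.
GRAMMAR_CORES = (
    "COc1ccc(C(=O)Nc2ccc({R})cc2)cc1",
    "Cc1ccc(S(=O)(=O)N2CCC({R})CC2)cc1",
    "O=C(Nc1ccc({R})cc1)c1ccc2c(c1)OCO2",
    "Fc1ccc(-c2nc(Cc3ccc({R})cc3)no2)cc1",
    "O=C(c1ccc(-c2ccccc2)o1)N1CCN({R})CC1",
    "Clc1ccc(Oc2ccc({R})cn2)cc1",
)

#: Substituents; ring-closure digits are remapped per core to avoid clashes.
GRAMMAR_SUBSTITUENTS = (
    "CCN2CCOCC2",
    "CN2CCCC2",
    "N2CCN(C)CC2",
    "CC(C)O",
    "C(=O)N(C)C",
    "CNC(C)=O",
    "OCC(C)C",
    "CCc2ccccc2",
    "Cc2ccncc2",
    "C2CCNCC2",
)

#: One deliberate violator per filter rule.  Each molecule breaks exactly
#: its designed rule and satisfies every other bound.  The exclusion_smarts
#: violator carries an aldehyde and is flagged only when the aldehyde
#: pattern (see :data:`EXCLUSION_SMARTS_FIXTURE`) is supplied.
VIOLATOR_SUITE: tuple[tuple[str, str], ...] = (
    ("mw_range", "CN(C)c1ccc(CCCc2ccccc2)cc1"),
    ("element_whitelist", "C[Si](C)(C)c1ccc(C(=O)Nc2ccc(OC)cc2)cc1"),
    ("heavy_atoms", "COc1ccc(C(=O)Nc2ccc(-c3ccc(C(=O)Nc4ccc(OC)cc4)cc3)cc2)cc1"),
    ("ring_count", "C1CN(Cc2ccc3ccccc3c2)CCN1Cc1ccc2ccccc2c1"),
    ("fused_rings", "CN(C)Cc1cc2ccc3cccc4ccc(c1)c2c34"),
    ("rotatable_bonds", "CCCCCCCCOc1ccc(C(=O)Nc2ccccc2)cc1"),
    ("hbd", "OCC(O)C(O)C(O)COc1ccc(-c2ccccc2)cc1"),
    ("hba", "COc1cc(OC)c(-c2nc(N3CCOCC3)nc(N)n2)c(OC)c1"),
    ("charged_carbon", "COc1ccc([C+](c2ccccc2)c2ccccc2)cc1"),
    ("no_N_or_O", "Cc1ccc(C2(c3ccc(C)cc3)CCCCC2)cc1"),
    ("exclusion_smarts", "O=Cc1ccc(C(=O)Nc2ccc(CCN3CCOCC3)cc2)cc1"),
    ("tosyl", "CC(C)(C)c1ccc(COS(=O)(=O)c2ccc(C)cc2)cc1"),
)

#: A fully compliant control molecule.
COMPLIANT_CONTROL = "COc1ccc(C(=O)Nc2ccc(CCN3CCOCC3)cc2)cc1"

#: Exclusion patterns to pair with the violator suite (name, SMARTS).
EXCLUSION_SMARTS_FIXTURE: tuple[tuple[str, str], ...] = (
    ("aldehyde", "[CX3H1](=O)[#6]"),
)

#: A string that is not valid SMILES, for unparseable-input paths.
UNPARSEABLE_SMILES = "C1CC(not-a-smiles"


def filter_violation_suite() -> list[tuple[str, str, str | None]]:
    """The 13-molecule filter fixture: 12 single-rule violators + control.

    Returns ``(id, smiles, designed_rule)`` triples; the control carries
    ``None`` as its designed rule.
    """
    suite = [
        (f"VIOL_{rule}", smiles, rule) for rule, smiles in VIOLATOR_SUITE
    ]
    suite.append(("CONTROL", COMPLIANT_CONTROL, None))
    return suite


def _enumerate_grammar() -> list[str]:
    out = []
    for core in GRAMMAR_CORES:
        for sub in GRAMMAR_SUBSTITUENTS:
            # remap ring-closure digits in the substituent above those of the core
            out.append(core.format(R=sub.replace("2", "9")))
    return out


def synth_chemistry_pool(
    n: int, seed: int = 0, violator_fraction: float = 0.2
) -> pd.DataFrame:
    """A pool of ``n`` structures: grammar compounds plus designed violators.

    Returns a DataFrame with columns ``id``, ``smiles``,
    ``designed_rule`` (null for the compliant grammar compounds).
    Compliant entries are drawn from the scaffold grammar with random
    methyl/fluoro ring decorations to diversify; violators are sampled
    from the fixed single-rule suite.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    grammar = _enumerate_grammar()
    n_viol = int(n * violator_fraction)
    rows = []
    for i in range(n - n_viol):
        base = grammar[int(rng.integers(len(grammar)))]
        # optional single aromatic methyl decoration keeps all bounds safe
        if rng.random() < 0.5 and base.count("cc1)") == 1:
            base = base.replace("cc1)", "c(C)c1)", 1)
        rows.append({"id": f"SYN{i:06d}", "smiles": base, "designed_rule": None})
    violators = VIOLATOR_SUITE
    for j in range(n_viol):
        rule, smi = violators[int(rng.integers(len(violators)))]
        rows.append(
            {"id": f"SYN{n - n_viol + j:06d}", "smiles": smi, "designed_rule": rule}
        )
    return pd.DataFrame(rows, columns=["id", "smiles", "designed_rule"])


def synth_bioactivity_table(
    n_records: int = 400,
    n_targets: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """A curated-extract-shaped bioactivity table over grammar chemistry.

    Reference compounds come from the first four scaffold cores of the
    chemistry grammar, so query compounds built on those cores find
    similar neighbors while queries on the remaining cores fall below
    the prediction threshold and surface as dark chemical matter
    (mirroring the large dark fraction of real purchasable pools).  Mixed in
    are records designed to be excluded by each curation criterion
    (duplicates, inconclusive comments, low-confidence assays, foreign
    units, missing relations), plus a share of µg/mL records and
    missing years.
    """
    rng = np.random.default_rng(seed)
    grammar = [
        core.format(R=sub.replace("2", "9"))
        for core in GRAMMAR_CORES[:4]
        for sub in GRAMMAR_SUBSTITUENTS
    ]
    types = ["IC50", "Ki", "Kd", "EC50", "AC50", "Potency"]
    rows = []
    for i in range(n_records):
        smi = grammar[int(rng.integers(len(grammar)))]
        row = {
            "compound_id": f"REF{i:05d}",
            "smiles": smi,
            "target_id": f"T{int(rng.integers(n_targets)):04d}",
            "confidence_score": 9,
            "data_validity_comment": None,
            "potential_duplicate": 0,
            "standard_type": types[int(rng.integers(len(types)))],
            "activity_comment": None,
            "standard_relation": "=",
            "standard_value": float(np.round(rng.lognormal(np.log(800), 1.5), 3)),
            "standard_units": "nM",
            "year": int(rng.integers(1998, 2021)),
            "source": "synthetic",
        }
        u = rng.random()
        if u < 0.04:
            row["potential_duplicate"] = 1
        elif u < 0.08:
            row["activity_comment"] = "inconclusive"
        elif u < 0.12:
            row["confidence_score"] = int(rng.integers(1, 6))
        elif u < 0.16:
            row["standard_type"] = "Inhibition"
        elif u < 0.20:
            row["standard_relation"] = None  # excluded unless comment says Active
        elif u < 0.25:
            row["standard_units"] = "ug.mL^-1"
            row["standard_value"] = float(np.round(rng.lognormal(0.0, 1.0), 4))
        if rng.random() < 0.04:
            row["year"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def synth_family_table(
    target_ids: list[str], n_families: int = 8, seed: int = 0
) -> pd.DataFrame:
    """A target -> family map over the given targets with skewed sizes."""
    rng = np.random.default_rng(seed)
    weights = _zipf_weights(n_families)
    rows = []
    for tid in target_ids:
        if rng.random() < 0.05:
            continue  # unmapped -> dummy family downstream
        fam = int(rng.choice(n_families, p=weights))
        rows.append({"target_id": tid, "family_id": f"FAM{fam:04d}"})
        if rng.random() < 0.08:
            fam2 = int(rng.choice(n_families, p=weights))
            if fam2 != fam:
                rows.append({"target_id": tid, "family_id": f"FAM{fam2:04d}"})
    return pd.DataFrame(rows, columns=["target_id", "family_id"])
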