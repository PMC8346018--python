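"""Structure standardization, eligibility checks, and drug-likeness filters.

Candidate structures arrive as SMILES and are normalized to a canonical,
salt-stripped, neutralized, tautomer-canonical, non-stereospecific form so
that duplicates can be merged on constitution alone.  Standardized
compounds are then screened with a fixed battery of physicochemical
property rules intended to remove structures that behave poorly in
biochemical and cell-based assays: size bounds, element whitelist, ring
and flexibility limits, hydrogen-bonding limits, charged carbons, and
structural-alert SMARTS patterns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, Lipinski, QED, rdMolDescriptors, rdmolops
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Elements allowed in an eligible compound (hydrogen included implicitly).
ELEMENT_WHITELIST = frozenset({"C", "H", "O", "N", "P", "S", "F", "Cl", "Br", "I"})

#: Fixed vocabulary of filter rule names.
RULE_VOCABULARY = (
    "mw_range",
    "element_whitelist",
    "heavy_atoms",
    "ring_count",
    "fused_rings",
    "rotatable_bonds",
    "hbd",
    "hba",
    "charged_carbon",
    "no_N_or_O",
    "exclusion_smarts",
    "tosyl",
    "unparseable",
)

#: Built-in structural alert: tosyl / sulfonate ester group.
TOSYL_SMARTS = "S(=O)(=O)O"


@dataclass(frozen=True)
class RawStructure:
    """An input structure exactly as read: an opaque id and a SMILES."""

    id: str
    smiles: str


@dataclass(frozen=True)
class CompoundRecord:
    """A standardized structure.

    ``smiles_std`` is salt/solvent-stripped, neutralized, tautomer-canonical
    and non-stereospecific; it is the identity key used for deduplication.
    """

    id: str
    smiles_std: str
    mw: float
    elements: frozenset[str]


@dataclass(frozen=True)
class PropertyProfile:
    """All quantities the drug-likeness filters look at, for one compound."""

    heavy_atoms: int
    rings: int
    max_fused_system_rings: int
    rotatable_bonds: int
    hbd: int
    hba: int
    logp: float
    qed: float
    has_charged_carbon: bool
    has_N_or_O: bool
    matched_exclusion_patterns: tuple[str, ...] = ()


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of filtering one compound: every violated rule is listed."""

    id: str
    violated_rules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.violated_rules) - set(RULE_VOCABULARY)
        if unknown:
            raise ValueError(f"unknown filter rule names: {sorted(unknown)}")

    @property
    def passed(self) -> bool:
        return not self.violated_rules


@dataclass(frozen=True)
class FilterConfig:
    """Bounds for the property filters.

    Defaults encode the standard rule set: 250-900 Da, 18-30 heavy atoms,
    1-4 rings, at most 3 fused rings per ring system, at most 8 rotatable
    bonds, at most 3 H-bond donors, at most 7 acceptors.
    """

    mw_min: float = 250.0
    mw_max: float = 900.0
    heavy_min: int = 18
    heavy_max: int = 30
    rings_min: int = 1
    rings_max: int = 4
    fused_max: int = 3
    rotatable_max: int = 8
    hbd_max: int = 3
    hba_max: int = 7
    elements: frozenset[str] = ELEMENT_WHITELIST


class ExclusionPatterns:
    """A named set of structural-alert SMARTS patterns.

    The tosyl pattern is always present under the reserved name ``tosyl``;
    additional patterns (e.g. "remove" / "extreme caution" alert lists) are
    supplied by the user as ``name<whitespace>SMARTS`` lines.
    """

    def __init__(self, patterns: Iterable[tuple[str, str]] = ()) -> None:
        self._patterns: list[tuple[str, Chem.Mol]] = []
        seen = set()
        for name, smarts in itertools.chain([("tosyl", TOSYL_SMARTS)], patterns):
            if name in seen:
                raise ValueError(f"duplicate exclusion pattern name: {name!r}")
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise ValueError(f"invalid SMARTS for pattern {name!r}: {smarts!r}")
            self._patterns.append((name, query))
            seen.add(name)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExclusionPatterns":
        pairs = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'name SMARTS', got {line!r}")
            pairs.append((parts[0], parts[1]))
        return cls(pairs)

    def matches(self, mol: Chem.Mol) -> tuple[str, ...]:
        return tuple(name for name, q in self._patterns if mol.HasSubstructMatch(q))

    def __len__(self) -> int:
        return len(self._patterns)


_TAUTOMER_ENUMERATOR: rdMolStandardize.TautomerEnumerator | None = None
_UNCHARGER: rdMolStandardize.Uncharger | None = None


def _tools() -> tuple[rdMolStandardize.TautomerEnumerator, rdMolStandardize.Uncharger]:
    # constructing the tautomer enumerator is not free; reuse one instance
    global _TAUTOMER_ENUMERATOR, _UNCHARGER
    if _TAUTOMER_ENUMERATOR is None:
        _TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator()
        _UNCHARGER = rdMolStandardize.Uncharger()
    return _TAUTOMER_ENUMERATOR, _UNCHARGER


def standardize(raw: RawStructure) -> CompoundRecord | FilterVerdict:
    """Standardize one structure; return a rejection verdict if unparseable.

    Pipeline: sanitize -> keep the largest organic fragment (strips salts
    and solvents) -> neutralize charges where chemically possible ->
    canonical tautomer -> strip stereochemistry -> canonical SMILES.
    The result is idempotent: re-standardizing the output SMILES yields
    the same string.
    """
    mol = Chem.MolFromSmiles(raw.smiles)
    if mol is None:
        return FilterVerdict(id=raw.id, violated_rules=("unparseable",))
    taut, uncharger = _tools()
    try:
        mol = rdMolStandardize.Cleanup(mol)
        mol = rdMolStandardize.FragmentParent(mol)
        mol = uncharger.uncharge(mol)
        mol = taut.Canonicalize(mol)
    except Exception:
        return FilterVerdict(id=raw.id, violated_rules=("unparseable",))
    rdmolops.RemoveStereochemistry(mol)
    smiles_std = Chem.MolToSmiles(mol)
    return CompoundRecord(
        id=raw.id,
        smiles_std=smiles_std,
        mw=Descriptors.MolWt(mol),
        elements=frozenset(a.GetSymbol() for a in mol.GetAtoms()) | {"H"},
    )


def eligibility_check(rec: CompoundRecord, cfg: FilterConfig = FilterConfig()) -> FilterVerdict:
    """Check the two eligibility rules: molecular-weight window and element whitelist."""
    violated = []
    if not (cfg.mw_min <= rec.mw <= cfg.mw_max):
        violated.append("mw_range")
    if rec.elements - cfg.elements:
        violated.append("element_whitelist")
    return FilterVerdict(id=rec.id, violated_rules=tuple(violated))


def ring_systems(mol: Chem.Mol) -> list[tuple[frozenset[int], int]]:
    """Group SSSR rings into ring systems by shared atoms.

    Returns one ``(atom_index_set, ring_count)`` pair per system.  Rings
    sharing at least one atom belong to one system, which covers both
    fused and spiro junctions.
    """
    rings = [frozenset(r) for r in mol.GetRingInfo().AtomRings()]
    n = len(rings)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if rings[i] & rings[j]:
            parent[find(i)] = find(j)

    groups: dict[int, list[frozenset[int]]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(rings[i])
    return [
        (frozenset().union(*members), len(members)) for members in groups.values()
    ]


def property_profile(
    rec: CompoundRecord, patterns: ExclusionPatterns | None = None
) -> PropertyProfile:
    """Compute every quantity the drug-likeness filters inspect."""
    mol = Chem.MolFromSmiles(rec.smiles_std)
    if mol is None:  # pragma: no cover - smiles_std is produced by standardize
        raise ValueError(f"standardized SMILES failed to parse: {rec.smiles_std!r}")
    systems = ring_systems(mol)
    if patterns is None:
        patterns = ExclusionPatterns()
    return PropertyProfile(
        heavy_atoms=Lipinski.HeavyAtomCount(mol),
        rings=rdMolDescriptors.CalcNumRings(mol),
        max_fused_system_rings=max((count for _, count in systems), default=0),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        logp=Descriptors.MolLogP(mol),
        qed=QED.default(mol),
        has_charged_carbon=any(
            a.GetSymbol() == "C" and a.GetFormalCharge() != 0 for a in mol.GetAtoms()
        ),
        has_N_or_O=any(a.GetSymbol() in ("N", "O") for a in mol.GetAtoms()),
        matched_exclusion_patterns=patterns.matches(mol),
    )


def apply_filters(
    profile: PropertyProfile, id: str = "", cfg: FilterConfig = FilterConfig()
) -> FilterVerdict:
    """Apply the property rules to a complete profile; report all violations."""
    violated = []
    if not (cfg.heavy_min <= profile.heavy_atoms <= cfg.heavy_max):
        violated.append("heavy_atoms")
    if not (cfg.rings_min <= profile.rings <= cfg.rings_max):
        violated.append("ring_count")
    if profile.max_fused_system_rings > cfg.fused_max:
        violated.append("fused_rings")
    if profile.rotatable_bonds > cfg.rotatable_max:
        violated.append("rotatable_bonds")
    if profile.hbd > cfg.hbd_max:
        violated.append("hbd")
    if profile.hba > cfg.hba_max:
        violated.append("hba")
    if profile.has_charged_carbon:
        violated.append("charged_carbon")
    if not profile.has_N_or_O:
        violated.append("no_N_or_O")
    non_tosyl = [p for p in profile.matched_exclusion_patterns if p != "tosyl"]
    if non_tosyl:
        violated.append("exclusion_smarts")
    if "tosyl" in profile.matched_exclusion_patterns:
        violated.append("tosyl")
    return FilterVerdict(id=id, violated_rules=tuple(violated))


def classify(
    raw: RawStructure,
    cfg: FilterConfig = FilterConfig(),
    patterns: ExclusionPatterns | None = None,
) -> tuple[CompoundRecord | None, FilterVerdict]:
    """Run the full standardize -> eligibility -> property-filter pipeline.

    Returns the standardized record (``None`` when unparseable) together
    with a single verdict combining all violated rules.
    """
    rec = standardize(raw)
    if isinstance(rec, FilterVerdict):
        return None, rec
    elig = eligibility_check(rec, cfg)
    prop = apply_filters(property_profile(rec, patterns), id=raw.id, cfg=cfg)
    return rec, FilterVerdict(
        id=raw.id, violated_rules=elig.violated_rules + prop.violated_rules
    )


def dedupe(records: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """Merge records with identical standardized SMILES.

    The kept id is the lexicographically smallest among the merged ids, so
    the result is independent of input order.  Output is sorted by kept id.
    """
    best: dict[str, CompoundRecord] = {}
    for rec in records:
        cur = best.get(rec.smiles_std)
        if cur is None or rec.id < cur.id:
            best[rec.smiles_std] = rec
    return sorted(best.values(), key=lambda r: r.id)
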