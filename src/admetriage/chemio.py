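"""Chemical table I/O and structure standardisation.

Screened chemicals arrive as CSV (or SDF) rows carrying a raw SMILES —
often a salt form — together with the assay outcome and the exposure/ADME
annotations that drive triage.  Before any descriptor or fingerprint is
computed, structures are "washed": counter-ions stripped, standard
ionisable groups neutralised, and the survivor emitted as a canonical
SMILES.  Washing is deterministic and idempotent.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem, RDLogger

from .errors import IntegrityError, SchemaError, StructureParseError, WashError

RDLogger.DisableLog("rdApp.*")


class AssayOutcome(str, enum.Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    UNTESTED = "untested"


class ExposureCategory(enum.Enum):
    """Exposure potential: 1 widespread, 2 occupational/special-case,
    3 unknown, 4 low/no likelihood.  UNANNOTATED means no literature call."""

    WIDESPREAD = 1
    LIMITED = 2
    UNKNOWN = 3
    NEGLIGIBLE = 4
    UNANNOTATED = 0

    @classmethod
    def parse(cls, text: str) -> "ExposureCategory":
        text = text.strip()
        if text in {"", "unannotated"}:
            return cls.UNANNOTATED
        try:
            return cls(int(text))
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"bad exposure category {text!r}") from exc


class MetabolismCode(str, enum.Enum):
    """Qualitative fate of the chemical under metabolism."""

    ACTIVATING = "+"
    DETOXIFYING = "-"
    MIXED = "+/-"
    SAME_TOXICITY = "="
    EXCRETED_UNCHANGED = "NA"
    UNKNOWN = "U"
    UNANNOTATED = ""

    @classmethod
    def parse(cls, text: str) -> "MetabolismCode":
        text = text.strip()
        aliases = {"±": "+/-", "–": "-", "−": "-"}
        text = aliases.get(text, text)
        try:
            return cls(text)
        except ValueError as exc:
            raise SchemaError(f"bad metabolism code {text!r}") from exc


class AbsorptionClass(str, enum.Enum):
    YES = "Yes"
    LIMITED = "Limited"
    NEGLIGIBLE = "Negligible"
    NA = "NA"


class DistributionClass(str, enum.Enum):
    YES = "Yes"
    NO = "No"
    NA = "NA"


def _parse_optional_enum(text: str, cls):
    text = text.strip()
    if not text:
        return None
    try:
        return cls(text)
    except ValueError as exc:
        raise SchemaError(f"bad {cls.__name__} value {text!r}") from exc


def _parse_optional_bool(text: str):
    text = text.strip().lower()
    if not text:
        return None
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise SchemaError(f"bad boolean value {text!r}")


@dataclass
class ChemicalRecord:
    """One screened chemical and everything triage knows about it."""

    id: str
    name: str = ""
    smiles: str | None = None
    assay_outcome: AssayOutcome = AssayOutcome.UNTESTED
    ac50_uM: float | None = None
    exposure_category: ExposureCategory = ExposureCategory.UNANNOTATED
    metabolism_code: MetabolismCode = MetabolismCode.UNANNOTATED
    parent_id: str | None = None
    absorption_annotation: AbsorptionClass | None = None
    distribution_annotation: DistributionClass | None = None
    promiscuity_override: bool | None = None
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.id:
            raise IntegrityError("record id must be non-empty")
        if self.ac50_uM is not None and not self.ac50_uM > 0:
            raise IntegrityError(f"record {self.id}: ac50_uM must be > 0")


@dataclass(frozen=True)
class StructureRecord:
    """A washed structure: the retained fragment of one chemical."""

    source_id: str
    washed_smiles: str
    n_fragments_removed: int = 0
    is_organic: bool = True
    wash_notes: tuple[str, ...] = ()


def parse_structure(smiles: str, record_id: str | None = None) -> Chem.Mol:
    """Parse a SMILES into a valence-checked molecule or raise
    :class:`StructureParseError` naming the offending record."""
    if not smiles or not smiles.strip():
        raise StructureParseError(smiles, record_id, "empty string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(smiles, record_id)
    return mol


# Fixed neutralisation table: (pattern, fix).  Protonated amines lose a
# proton; common anions (carboxylate, phenolate/alkoxide, thiolate,
# sulfonate/phosphate oxygens) gain one.  Nitro/N-oxide oxygens and
# quaternary ammoniums carry non-removable charges and are left alone.
_NEUTRALISE_TABLE = [
    ("[n+;H]", "n"),
    ("[N+;!H0]", "N"),
    ("[$([O-]);!$([O-][#7])]", "O"),
    ("[S-;X1]", "S"),
    ("[$([N-;X2]S(=O)=O)]", "N"),
    ("[$([N-;X2][C,N]=C)]", "N"),
    ("[n-]", "[nH]"),
    ("[$([N-]C=O)]", "N"),
]
_NEUTRALISE_PATTERNS = [
    (Chem.MolFromSmarts(pat), Chem.MolFromSmiles(fix, sanitize=False))
    for pat, fix in _NEUTRALISE_TABLE
]


def _neutralise(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    changed = False
    for pattern, replacement in _NEUTRALISE_PATTERNS:
        while mol.HasSubstructMatch(pattern):
            changed = True
            mol = Chem.ReplaceSubstructs(mol, pattern, replacement)[0]
    if changed:
        Chem.SanitizeMol(mol)
    return mol, changed


def wash_structure(mol: Chem.Mol, source_id: str = "") -> StructureRecord:
    """Standardise a parsed structure.

    Keeps the largest fragment by heavy-atom count (ties broken by
    molecular weight, then canonical-SMILES order), neutralises standard
    acid/base groups, and emits the canonical SMILES.  Inorganic
    survivors (no carbon) are retained and flagged rather than rejected.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        raise WashError(f"empty molecule for record {source_id!r}")
    notes: list[str] = []

    def _key(frag: Chem.Mol):
        from rdkit.Chem import Descriptors

        return (
            frag.GetNumHeavyAtoms(),
            Descriptors.MolWt(frag),
            # lexicographically *smallest* canonical SMILES wins the tie,
            # so negate by sorting on the reversed criterion below
        )

    best = max(
        frags,
        key=lambda f: (_key(f), _InvertedStr(Chem.MolToSmiles(f))),
    )
    n_removed = len(frags) - 1
    if n_removed:
        notes.append(f"stripped_{n_removed}_fragments")

    best = Chem.Mol(best)
    Chem.SanitizeMol(best)
    best, neutralised = _neutralise(best)
    if neutralised:
        notes.append("neutralised")

    organic = any(atom.GetAtomicNum() == 6 for atom in best.GetAtoms())
    if not organic:
        notes.append("inorganic")

    smiles = Chem.MolToSmiles(best)
    if not smiles:
        raise WashError(f"washing produced an empty structure for {source_id!r}")
    return StructureRecord(
        source_id=source_id,
        washed_smiles=smiles,
        n_fragments_removed=n_removed,
        is_organic=organic,
        wash_notes=tuple(notes),
    )


class _InvertedStr(str):
    """String with reversed ordering, for use inside a max() key."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


def wash_smiles(smiles: str, source_id: str = "") -> StructureRecord:
    """Parse + wash in one step."""
    return wash_structure(parse_structure(smiles, source_id), source_id)


_MANDATORY_COLUMNS = ("id", "smiles", "assay_outcome")
_KNOWN_COLUMNS = {
    "id",
    "name",
    "smiles",
    "assay_outcome",
    "ac50_uM",
    "exposure_category",
    "metabolism_code",
    "parent_id",
    "absorption_annotation",
    "distribution_annotation",
    "promiscuity_override",
}


def _record_from_mapping(row: dict[str, str]) -> ChemicalRecord:
    outcome = row.get("assay_outcome", "").strip() or "untested"
    try:
        outcome = AssayOutcome(outcome)
    except ValueError as exc:
        raise SchemaError(f"bad assay_outcome {outcome!r}") from exc
    ac50_text = row.get("ac50_uM", "").strip()
    extras = {k: v for k, v in row.items() if k not in _KNOWN_COLUMNS and k is not None}
    return ChemicalRecord(
        id=row["id"].strip(),
        name=row.get("name", "").strip(),
        smiles=row.get("smiles", "").strip() or None,
        assay_outcome=outcome,
        ac50_uM=float(ac50_text) if ac50_text else None,
        exposure_category=ExposureCategory.parse(row.get("exposure_category", "")),
        metabolism_code=MetabolismCode.parse(row.get("metabolism_code", "")),
        parent_id=row.get("parent_id", "").strip() or None,
        absorption_annotation=_parse_optional_enum(
            row.get("absorption_annotation", ""), AbsorptionClass
        ),
        distribution_annotation=_parse_optional_enum(
            row.get("distribution_annotation", ""), DistributionClass
        ),
        promiscuity_override=_parse_optional_bool(row.get("promiscuity_override", "")),
        extras=extras,
    )


def read_chemical_table(path: str | Path, format: str = "csv") -> list[ChemicalRecord]:
    """Read a chemical table (CSV or SDF V2000) into records.

    Raises :class:`SchemaError` for a missing mandatory column and
    :class:`IntegrityError` for duplicated ids.
    """
    path = Path(path)
    if format == "csv":
        records = _read_csv(path)
    elif format == "sdf":
        records = _read_sdf(path)
    else:
        raise SchemaError(f"unknown table format {format!r}")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise IntegrityError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
    return records


def _read_csv(path: Path) -> list[ChemicalRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        missing = [c for c in _MANDATORY_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns {missing}")
        return [_record_from_mapping(row) for row in reader]


def _read_sdf(path: Path) -> list[ChemicalRecord]:
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise StructureParseError(f"<SDF block {i}>", str(path))
        props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        props.setdefault("id", props.get("_Name", mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf-{i}"))
        props.setdefault("smiles", Chem.MolToSmiles(mol))
        if "id" not in props or not props["id"]:
            raise SchemaError(f"{path}: SDF record {i} has no id")
        records.append(_record_from_mapping(props))
    return records


def validate_dataset(records: list[ChemicalRecord], require_exposure: bool = True) -> None:
    """Enforce dataset-level invariants.

    Ids unique; parent links resolve; every active that will be gated
    carries an exposure category (triage cannot demote on absent
    evidence, so an unannotated active is an input error).
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IntegrityError(f"duplicate ids: {dupes}")
    id_set = set(ids)
    for rec in records:
        if rec.parent_id is not None and rec.parent_id not in id_set:
            raise IntegrityError(
                f"record {rec.id}: parent_id {rec.parent_id!r} does not resolve"
            )
        if (
            require_exposure
            and rec.assay_outcome is AssayOutcome.ACTIVE
            and rec.exposure_category is ExposureCategory.UNANNOTATED
        ):
            from .errors import AnnotationRequiredError

            raise AnnotationRequiredError(
                f"active record {rec.id} has no exposure category"
            )


def write_records_csv(records: list[ChemicalRecord], path: str | Path) -> None:
    """Write records back to CSV; a read of the output reproduces them."""
    columns = [
        "id",
        "name",
        "smiles",
        "assay_outcome",
        "ac50_uM",
        "exposure_category",
        "metabolism_code",
        "parent_id",
        "absorption_annotation",
        "distribution_annotation",
        "promiscuity_override",
    ]
    extra_cols = sorted({k for r in records for k in r.extras})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns + extra_cols)
        for r in records:
            row = [
                r.id,
                r.name,
                r.smiles or "",
                r.assay_outcome.value,
                "" if r.ac50_uM is None else repr(r.ac50_uM),
                "" if r.exposure_category is ExposureCategory.UNANNOTATED
                else str(r.exposure_category.value),
                r.metabolism_code.value,
                r.parent_id or "",
                "" if r.absorption_annotation is None else r.absorption_annotation.value,
                "" if r.distribution_annotation is None else r.distribution_annotation.value,
                "" if r.promiscuity_override is None else str(r.promiscuity_override).lower(),
            ]
            writer.writerow(row + [r.extras.get(k, "") for k in extra_cols])


def write_report(report, path: str | Path, format: str = "csv") -> None:
    """Serialise a :class:`~admetriage.triage.TriageReport`.

    CSV carries one row per priority call (reasons and notes
    pipe-separated); JSON carries the full report including hits and the
    summary block.  Both round-trip every call and reason code.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2, ensure_ascii=False)
            fh.write("\n")
        return
    if format != "csv":
        raise SchemaError(f"unknown report format {format!r}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["chemical_id", "name", "priority", "reasons", "rank_notes"])
        names = getattr(report, "names", {})
        for call in report.calls:
            writer.writerow(
                [
                    call.chemical_id,
                    names.get(call.chemical_id, ""),
                    call.priority,
                    "|".join(call.reasons),
                    "|".join(call.rank_notes),
                ]
            )


def read_report_csv(path: str | Path) -> list[dict[str, object]]:
    """Read back a CSV triage report as plain dicts (round-trip check)."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    for row in rows:
        row["reasons"] = [r for r in row["reasons"].split("|") if r]
        row["rank_notes"] = [r for r in row["rank_notes"].split("|") if r]
    return rows
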