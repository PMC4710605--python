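"""Physicochemical descriptors and the absorption / distribution gates.

Absorption potential is screened with the Rule-of-5 extended by the
rotatable-bond and polar-surface-area criteria; a chemical free of
violations is classed "Yes", otherwise "Limited".  Distribution to brain
tissue is screened with a configurable rule set over the same
descriptors (CNS-permeant chemicals are small, moderately lipophilic,
low-polarity and not anionic).  All thresholds are strict inequalities:
a value exactly at a limit is not a violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .chemio import AbsorptionClass, DistributionClass, StructureRecord


@dataclass(frozen=True)
class DescriptorSet:
    """2D descriptors of one washed structure.

    mw in g/mol; logp is the Crippen atom-contribution estimate of
    log K_ow; tpsa in Å²; counts are plain integers.  ``low_confidence``
    marks inorganic/organometallic structures whose atom-contribution
    estimates are unreliable.
    """

    mw: float
    logp: float
    hbd: int
    hba: int
    rotatable_bonds: int
    tpsa: float
    net_formal_charge: int
    low_confidence: bool = False


@dataclass(frozen=True)
class AbsorptionCall:
    cls: AbsorptionClass
    violations: tuple[str, ...] = ()
    source: str = "predicted"  # "annotation" | "predicted"


@dataclass(frozen=True)
class DistributionCall:
    bbb_permeable: DistributionClass
    source: str = "predicted"
    failed_rules: tuple[str, ...] = ()


def compute_descriptors(structure: StructureRecord) -> DescriptorSet:
    """Compute the descriptor set from the washed fragment.

    Never raises: inorganic structures get best-effort values with the
    ``low_confidence`` flag set (mass is exact; logP and TPSA fall back
    to the default atom contributions).
    """
    mol = Chem.MolFromSmiles(structure.washed_smiles)
    if mol is None:  # washed_smiles is guaranteed to parse; belt and braces
        return DescriptorSet(0.0, 0.0, 0, 0, 0, 0.0, 0, low_confidence=True)
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        rotatable_bonds=Lipinski.NumRotatableBonds(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        net_formal_charge=Chem.GetFormalCharge(mol),
        low_confidence=not structure.is_organic,
    )


@dataclass(frozen=True)
class Ro5Thresholds:
    """Upper limits for the extended Rule-of-5 absorption screen."""

    mw: float = 500.0
    logp: float = 5.0
    hbd: int = 5
    hba: int = 10
    rotatable_bonds: int = 10
    tpsa: float = 140.0

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def classify_absorption(
    d: DescriptorSet, thresholds: Ro5Thresholds = Ro5Thresholds()
) -> AbsorptionCall:
    """Rule-of-5 absorption class: "Yes" iff no threshold is exceeded,
    otherwise "Limited".  ("Negligible" is reserved for annotations.)"""
    t = thresholds
    checks = [
        ("mw", d.mw, t.mw),
        ("logp", d.logp, t.logp),
        ("hbd", d.hbd, t.hbd),
        ("hba", d.hba, t.hba),
        ("rotbonds", d.rotatable_bonds, t.rotatable_bonds),
        ("tpsa", d.tpsa, t.tpsa),
    ]
    violations = tuple(
        f"{name}_gt_{limit:g}" for name, value, limit in checks if value > limit
    )
    cls = AbsorptionClass.YES if not violations else AbsorptionClass.LIMITED
    return AbsorptionCall(cls=cls, violations=violations, source="predicted")


@dataclass(frozen=True)
class BBBRules:
    """Rule set for blood–brain-barrier permeability.

    Every enabled rule must pass for a "Yes".  A rule is disabled by
    setting its bound to None.  Defaults: TPSA ≤ 90 Å², MW ≤ 450,
    1 ≤ logP ≤ 4, H-bond donors ≤ 3, net formal charge ≥ 0.
    """

    tpsa_max: float | None = 90.0
    mw_max: float | None = 450.0
    logp_min: float | None = 1.0
    logp_max: float | None = 4.0
    hbd_max: int | None = 3
    charge_min: int | None = 0

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def classify_bbb(d: DescriptorSet, rules: BBBRules = BBBRules()) -> DistributionCall:
    """Distribution call: "Yes" iff every enabled rule passes."""
    failed = []
    if rules.tpsa_max is not None and d.tpsa > rules.tpsa_max:
        failed.append(f"tpsa_gt_{rules.tpsa_max:g}")
    if rules.mw_max is not None and d.mw > rules.mw_max:
        failed.append(f"mw_gt_{rules.mw_max:g}")
    if rules.logp_min is not None and d.logp < rules.logp_min:
        failed.append(f"logp_lt_{rules.logp_min:g}")
    if rules.logp_max is not None and d.logp > rules.logp_max:
        failed.append(f"logp_gt_{rules.logp_max:g}")
    if rules.hbd_max is not None and d.hbd > rules.hbd_max:
        failed.append(f"hbd_gt_{rules.hbd_max:g}")
    if rules.charge_min is not None and d.net_formal_charge < rules.charge_min:
        failed.append(f"charge_lt_{rules.charge_min:g}")
    cls = DistributionClass.YES if not failed else DistributionClass.NO
    return DistributionCall(bbb_permeable=cls, source="predicted", failed_rules=tuple(failed))
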