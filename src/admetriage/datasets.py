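"""Packaged case-study fixtures and synthetic screening libraries.

The case study ships as two CSVs: the 30 assay-active
acetylcholinesterase inhibitors with their printed exposure/ADME
annotations, and the discussion set of assay-inactive organophosphates,
carbamates and drugs used to demonstrate false-negative detection.
Structures come from standard registry entries for the named chemicals
(each row cites its CAS number); failed pharmaceuticals with undisclosed
structures carry no SMILES and triage on annotations alone.

The synthetic generators build screening libraries with known ground
truth: analog series guaranteed (by rejection sampling against the
package's own fingerprints) to sit at or above a similarity threshold to
their scaffold, decoys guaranteed below it, and a full factorial grid of
gate annotations for exercising the decision logic.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from importlib import resources

from rdkit import Chem

from .chemio import (
    AbsorptionClass,
    AssayOutcome,
    ChemicalRecord,
    DistributionClass,
    ExposureCategory,
    read_chemical_table,
    validate_dataset,
    wash_smiles,
)
from .errors import AdmetriageError
from .fingerprints import compute_maccs, tanimoto


def _data_path(name: str):
    return resources.files("admetriage.data").joinpath(name)


@dataclass
class FixtureSet:
    """The packaged case study: active table plus discussion inactives."""

    table1_actives: list[ChemicalRecord]
    discussion_inactives: list[ChemicalRecord]

    @property
    def all_records(self) -> list[ChemicalRecord]:
        return self.table1_actives + self.discussion_inactives


def load_table1_fixture() -> FixtureSet:
    """Load and validate the packaged case-study fixture."""
    with resources.as_file(_data_path("table1_actives.csv")) as p:
        actives = read_chemical_table(p, "csv")
    with resources.as_file(_data_path("discussion_inactives.csv")) as p:
        inactives = read_chemical_table(p, "csv")
    fixture = FixtureSet(actives, inactives)
    validate_dataset(fixture.all_records, require_exposure=False)
    if len(actives) != 30:
        raise AdmetriageError(f"fixture must have 30 actives, found {len(actives)}")
    ac50s = [r.ac50_uM for r in actives]
    if any(a is None for a in ac50s) or any(
        a >= b for a, b in zip(ac50s, ac50s[1:])
    ):
        raise AdmetriageError("fixture AC50 values must be strictly increasing")
    return fixture


def load_decoy_pool() -> list[tuple[str, str]]:
    """Packaged pool of structurally diverse molecules: (smiles, name)."""
    pool = []
    text = _data_path("decoy_pool.smi").read_text(encoding="utf-8")
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, name = line.split(None, 1)
        pool.append((smiles, name.strip()))
    return pool


# Edit vocabulary for analog generation.
_HALOGENS = (9, 17, 35)  # F, Cl, Br


def _random_edit(mol: Chem.Mol, rng: random.Random) -> Chem.Mol | None:
    """Apply one randomly chosen structure edit; None if inapplicable."""
    edit = rng.choice(("halogen_swap", "methyl_add", "chalcogen_swap", "chain_extend"))
    rw = Chem.RWMol(mol)
    atoms = list(rw.GetAtoms())
    if edit == "halogen_swap":
        candidates = [a for a in atoms if a.GetAtomicNum() in _HALOGENS]
        if not candidates:
            return None
        atom = rng.choice(candidates)
        choices = [z for z in _HALOGENS if z != atom.GetAtomicNum()]
        atom.SetAtomicNum(rng.choice(choices))
    elif edit == "methyl_add":
        candidates = [
            a for a in atoms if a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0
        ]
        if not candidates:
            return None
        atom = rng.choice(candidates)
        new_idx = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(atom.GetIdx(), new_idx, Chem.BondType.SINGLE)
    elif edit == "chalcogen_swap":
        candidates = [
            a
            for a in atoms
            if a.GetAtomicNum() in (8, 16) and not a.GetIsAromatic()
        ]
        if not candidates:
            return None
        atom = rng.choice(candidates)
        atom.SetAtomicNum(24 - atom.GetAtomicNum())  # 8 <-> 16
    else:  # chain_extend: grow a terminal methyl by one carbon
        candidates = [
            a
            for a in atoms
            if a.GetAtomicNum() == 6 and a.GetDegree() == 1 and not a.GetIsAromatic()
        ]
        if not candidates:
            return None
        atom = rng.choice(candidates)
        new_idx = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(atom.GetIdx(), new_idx, Chem.BondType.SINGLE)
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def generate_analog_series(
    scaffold_smiles: str,
    n_analogs: int,
    max_edits: int = 2,
    threshold: float = 0.75,
    seed: int = 0,
) -> list[ChemicalRecord]:
    """Derive analogs of a scaffold by 1..max_edits random edits,
    keeping only those whose MACCS Tanimoto to the scaffold reaches the
    threshold (rejection sampling, deterministic per seed).

    Emits a partial series with a warning if the attempt budget runs out
    before ``n_analogs`` distinct analogs are found.
    """
    if n_analogs < 0:
        raise AdmetriageError("n_analogs must be >= 0")
    rng = random.Random(seed)
    scaffold_struct = wash_smiles(scaffold_smiles, "scaffold")
    scaffold_fp = compute_maccs(scaffold_struct)
    scaffold_mol = Chem.MolFromSmiles(scaffold_struct.washed_smiles)

    records: list[ChemicalRecord] = []
    seen: set[str] = {scaffold_struct.washed_smiles}
    budget = max(50, 60 * n_analogs)
    attempts = 0
    while len(records) < n_analogs and attempts < budget:
        attempts += 1
        mol = scaffold_mol
        for _ in range(rng.randint(1, max_edits)):
            edited = _random_edit(mol, rng)
            if edited is not None:
                mol = edited
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen:
            continue
        analog_fp = compute_maccs(wash_smiles(smiles, "analog"))
        if tanimoto(analog_fp, scaffold_fp) < threshold:
            continue
        seen.add(smiles)
        records.append(
            ChemicalRecord(
                id=f"analog-{seed}-{len(records)}",
                name=f"analog {len(records)} of scaffold",
                smiles=smiles,
                assay_outcome=AssayOutcome.INACTIVE,
            )
        )
    if len(records) < n_analogs:
        warnings.warn(
            f"analog generation exhausted budget: {len(records)}/{n_analogs} "
            f"analogs reached threshold {threshold}",
            stacklevel=2,
        )
    return records


def generate_decoys(
    n: int,
    scaffolds: list[str],
    threshold: float = 0.75,
    seed: int = 0,
) -> list[ChemicalRecord]:
    """Sample structurally unrelated molecules from the packaged pool,
    keeping only those below the threshold against every scaffold."""
    if n < 0:
        raise AdmetriageError("n must be >= 0")
    rng = random.Random(seed)
    scaffold_fps = [compute_maccs(wash_smiles(s, "scaffold")) for s in scaffolds]
    pool = load_decoy_pool()
    rng.shuffle(pool)
    records: list[ChemicalRecord] = []
    for smiles, name in pool:
        if len(records) >= n:
            break
        fp = compute_maccs(wash_smiles(smiles, name))
        if any(tanimoto(fp, sf) >= threshold for sf in scaffold_fps):
            continue
        records.append(
            ChemicalRecord(
                id=f"decoy-{seed}-{len(records)}",
                name=name,
                smiles=smiles,
                assay_outcome=AssayOutcome.INACTIVE,
            )
        )
    if len(records) < n:
        warnings.warn(
            f"decoy pool exhausted: {len(records)}/{n} decoys below threshold",
            stacklevel=2,
        )
    return records


_EXPOSURE_TOKENS = {
    ExposureCategory.WIDESPREAD: "1",
    ExposureCategory.LIMITED: "2",
    ExposureCategory.UNKNOWN: "3",
    ExposureCategory.NEGLIGIBLE: "4",
    ExposureCategory.UNANNOTATED: "u",
}


def generate_triage_grid() -> list[ChemicalRecord]:
    """One active record per gate-annotation combination: 5 exposure
    categories x 4 absorption classes x 3 distribution classes = 60."""
    records = []
    for exposure, etok in _EXPOSURE_TOKENS.items():
        for absorption in (*AbsorptionClass, None):
            if absorption is None:
                continue
            for distribution in DistributionClass:
                records.append(
                    ChemicalRecord(
                        id=f"grid-e{etok}-a{absorption.value}-d{distribution.value}",
                        name=f"grid {etok}/{absorption.value}/{distribution.value}",
                        assay_outcome=AssayOutcome.ACTIVE,
                        exposure_category=exposure,
                        absorption_annotation=absorption,
                        distribution_annotation=distribution,
                    )
                )
    return records


# Scaffold pool for synthetic libraries: carbamate and organophosphate
# cores typical of the chemistry the case-study assay responds to.
LIBRARY_SCAFFOLDS: tuple[str, ...] = (
    "CNC(=O)Oc1ccccc1",            # aryl methylcarbamate
    "CCOP(=S)(OCC)Oc1ccccc1",      # diethyl aryl phosphorothioate
    "COP(=O)(OC)OC=C",             # dimethyl vinyl phosphate
    "CNC(=O)ON=C(C)SC",            # oxime carbamate
    "CCOP(=O)(OCC)SCC",            # phosphorodithioate-like ester
    "CNC(=O)Oc1cccc2c1OCC2",       # fused benzofuranyl carbamate
)


@dataclass
class SyntheticLibrary:
    """A generated screening library with known ground truth."""

    actives: list[ChemicalRecord]
    planted_analogs: list[ChemicalRecord]
    decoys: list[ChemicalRecord]
    seed: int
    threshold: float

    @property
    def inactives(self) -> list[ChemicalRecord]:
        return self.planted_analogs + self.decoys

    @property
    def all_records(self) -> list[ChemicalRecord]:
        return self.actives + self.inactives


def generate_library(
    seed: int,
    n_scaffolds: int = 4,
    n_analogs_per_scaffold: int = 2,
    n_decoys: int = 25,
    threshold: float = 0.75,
) -> SyntheticLibrary:
    """Build a library of active scaffolds, planted high-similarity
    analogs, unrelated decoys, and randomized gate annotations."""
    if not 1 <= n_scaffolds <= len(LIBRARY_SCAFFOLDS):
        raise AdmetriageError(
            f"n_scaffolds must lie in 1..{len(LIBRARY_SCAFFOLDS)}"
        )
    rng = random.Random(seed)
    scaffolds = list(LIBRARY_SCAFFOLDS[:n_scaffolds])
    actives = []
    for i, smiles in enumerate(scaffolds):
        actives.append(
            ChemicalRecord(
                id=f"scaffold-{i}",
                name=f"scaffold {i}",
                smiles=smiles,
                assay_outcome=AssayOutcome.ACTIVE,
                ac50_uM=round(rng.uniform(0.1, 25.0), 3),
                exposure_category=rng.choice(
                    (
                        ExposureCategory.WIDESPREAD,
                        ExposureCategory.LIMITED,
                        ExposureCategory.UNKNOWN,
                        ExposureCategory.NEGLIGIBLE,
                    )
                ),
                absorption_annotation=rng.choice(
                    (AbsorptionClass.YES, AbsorptionClass.LIMITED)
                ),
                distribution_annotation=rng.choice(
                    (DistributionClass.YES, DistributionClass.NO)
                ),
            )
        )
    analogs: list[ChemicalRecord] = []
    for i, smiles in enumerate(scaffolds):
        series = generate_analog_series(
            smiles,
            n_analogs_per_scaffold,
            threshold=threshold,
            seed=rng.randrange(2**31),
        )
        for j, rec in enumerate(series):
            analogs.append(
                ChemicalRecord(
                    id=f"analog-s{i}-{j}",
                    name=f"analog {j} of scaffold {i}",
                    smiles=rec.smiles,
                    assay_outcome=AssayOutcome.INACTIVE,
                    extras={"true_scaffold": f"scaffold-{i}"},
                )
            )
    decoys = generate_decoys(n_decoys, scaffolds, threshold, seed=rng.randrange(2**31))
    return SyntheticLibrary(
        actives=actives,
        planted_analogs=analogs,
        decoys=decoys,
        seed=seed,
        threshold=threshold,
    )
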