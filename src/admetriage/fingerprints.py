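"""MACCS-166 structural fingerprints, Tanimoto similarity and
nearest-active-neighbor screening.

The fingerprint is the presence/absence vector of the 166 public MDL
MACCS substructure keys.  Similarity between two fingerprints is the
Tanimoto coefficient |A∩B| / |A∪B| over set bits.  An inactive chemical
whose nearest active neighbor reaches the similarity threshold
(inclusive, default 0.75) is flagged as a possible in vitro false
negative: a close structural analog of a chemical that does hit the
molecular target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from .chemio import AssayOutcome, ChemicalRecord, StructureRecord, wash_smiles
from .errors import AdmetriageError, StructureParseError, WashError

N_KEYS = 166


@dataclass(frozen=True)
class Fingerprint:
    """Ordered 166-bit MACCS key vector (key k at index k-1)."""

    bits: tuple[bool, ...]

    def __post_init__(self):
        if len(self.bits) != N_KEYS:
            raise ValueError(f"fingerprint must have {N_KEYS} bits, got {len(self.bits)}")

    @property
    def popcount(self) -> int:
        return sum(self.bits)

    @property
    def on_keys(self) -> tuple[int, ...]:
        """1-based MACCS key numbers that are set."""
        return tuple(i + 1 for i, b in enumerate(self.bits) if b)

    @classmethod
    def from_on_keys(cls, keys) -> "Fingerprint":
        keyset = set(keys)
        if keyset and (min(keyset) < 1 or max(keyset) > N_KEYS):
            raise ValueError("MACCS key numbers must lie in 1..166")
        return cls(tuple(i + 1 in keyset for i in range(N_KEYS)))

    @classmethod
    def from_mol(cls, mol: Chem.Mol) -> "Fingerprint":
        # RDKit emits 167 bits with bit 0 permanently unset; drop it so the
        # public vector is exactly the 166 keys.
        bv = MACCSkeys.GenMACCSKeys(mol)
        return cls(tuple(bool(bv.GetBit(i)) for i in range(1, N_KEYS + 1)))


def compute_maccs(structure: StructureRecord) -> Fingerprint:
    """Fingerprint a washed structure; an all-zero result (nothing
    matchable, e.g. a bare metal salt) is returned with a warning."""
    mol = Chem.MolFromSmiles(structure.washed_smiles)
    if mol is None:
        raise StructureParseError(structure.washed_smiles, structure.source_id)
    fp = Fingerprint.from_mol(mol)
    if fp.popcount == 0:
        warnings.warn(
            f"structure {structure.source_id or structure.washed_smiles!r} sets no "
            "MACCS keys; similarity to it is undefined and reported as 0",
            stacklevel=2,
        )
    return fp


def _intersection_union(a: Fingerprint, b: Fingerprint) -> tuple[int, int]:
    if len(a.bits) != len(b.bits):  # defensive: lengths are enforced at build
        raise ValueError("fingerprint length mismatch")
    inter = sum(1 for x, y in zip(a.bits, b.bits) if x and y)
    union = a.popcount + b.popcount - inter
    return inter, union


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B|/|A∪B|; 0.0 when both vectors are empty
    (no structural evidence supports a similarity claim)."""
    inter, union = _intersection_union(a, b)
    if union == 0:
        warnings.warn("tanimoto of two empty fingerprints defined as 0.0", stacklevel=2)
        return 0.0
    return inter / union


@dataclass(frozen=True)
class SimilarityHit:
    """An inactive query paired with its most similar active."""

    query_id: str
    neighbor_id: str
    tanimoto: float
    flagged: bool
    inherited_priority: str | None = None  # "low" once propagated
    ties: tuple[str, ...] = ()


@dataclass(frozen=True)
class ActiveFingerprint:
    """Indexed entry of the active set: id, fingerprint, potency."""

    id: str
    fingerprint: Fingerprint
    ac50_uM: float | None = None


def nearest_active_neighbor(
    query: Fingerprint,
    actives: list[ActiveFingerprint],
    *,
    query_id: str = "",
    threshold: float = 0.75,
) -> SimilarityHit:
    """Exhaustive nearest-neighbor search over the active set.

    Similarities are compared as exact rationals (cross-multiplied
    integer counts), so ties are detected without floating-point
    artefacts.  Ties are broken by lowest AC50 (most potent active)
    then lexicographic id; all tied ids are reported.
    """
    if not actives:
        raise AdmetriageError("nearest_active_neighbor requires a non-empty active set")
    best: list[ActiveFingerprint] = []
    best_i, best_u = 0, 1  # current maximum as a fraction best_i/best_u
    for entry in actives:
        i, u = _intersection_union(query, entry.fingerprint)
        if u == 0:
            i, u = 0, 1
        # compare i/u vs best_i/best_u exactly
        lhs, rhs = i * best_u, best_i * u
        if not best or lhs > rhs:
            best, best_i, best_u = [entry], i, u
        elif lhs == rhs:
            best.append(entry)
    winner = min(
        best,
        key=lambda e: (e.ac50_uM if e.ac50_uM is not None else float("inf"), e.id),
    )
    value = best_i / best_u if best_u else 0.0
    return SimilarityHit(
        query_id=query_id,
        neighbor_id=winner.id,
        tanimoto=value,
        flagged=value >= threshold,
        ties=tuple(sorted(e.id for e in best)) if len(best) > 1 else (),
    )


@dataclass
class ScreenResult:
    hits: list[SimilarityHit]
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)


def index_actives(records: list[ChemicalRecord]) -> tuple[list[ActiveFingerprint], list[tuple[str, str]]]:
    """Wash + fingerprint the active records; structureless records are
    skipped with a note rather than aborting the batch."""
    indexed, skipped = [], []
    for rec in records:
        if not rec.smiles:
            skipped.append((rec.id, "no structure available"))
            continue
        try:
            fp = compute_maccs(wash_smiles(rec.smiles, rec.id))
        except (StructureParseError, WashError) as exc:
            skipped.append((rec.id, str(exc)))
            continue
        indexed.append(ActiveFingerprint(rec.id, fp, rec.ac50_uM))
    return indexed, skipped


def screen_inactives(
    inactives: list[ChemicalRecord],
    actives: list[ChemicalRecord],
    threshold: float = 0.75,
) -> ScreenResult:
    """One nearest-active hit per inactive, sorted by descending
    similarity (ties by query id); the flagged subset is the
    possible-false-negative candidate list."""
    if not (0.0 < threshold <= 1.0):
        raise AdmetriageError(f"threshold must lie in (0, 1], got {threshold}")
    if not inactives or not actives:
        raise AdmetriageError("screen_inactives needs non-empty query and active sets")
    index, skipped = index_actives(actives)
    if not index:
        raise AdmetriageError("no active structure could be fingerprinted")
    hits = []
    for rec in inactives:
        if not rec.smiles:
            skipped.append((rec.id, "no structure available"))
            continue
        try:
            fp = compute_maccs(wash_smiles(rec.smiles, rec.id))
        except (StructureParseError, WashError) as exc:
            skipped.append((rec.id, str(exc)))
            continue
        hits.append(
            nearest_active_neighbor(fp, index, query_id=rec.id, threshold=threshold)
        )
    hits.sort(key=lambda h: (-h.tanimoto, h.query_id))
    return ScreenResult(hits=hits, skipped=skipped)


def pairwise_matrix(records: list[ChemicalRecord]) -> tuple[list[str], np.ndarray]:
    """Full symmetric Tanimoto matrix over records with structures."""
    indexed, _ = index_actives(records)
    ids = [e.id for e in indexed]
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            t = tanimoto(indexed[i].fingerprint, indexed[j].fingerprint)
            mat[i, j] = mat[j, i] = t
    return ids, mat
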