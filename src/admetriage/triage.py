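"""Priority triage: the parent and metabolite decision trees, priority
propagation to flagged inactives, and promiscuity flagging.

An active chemical passes through up to three gates, in order:

1. exposure — category 4 (low/no likelihood of exposure) demotes
   immediately; categories 1–3 pass (unknown exposure is retained:
   insufficient evidence never demotes);
2. absorption — only an explicit "Negligible" call demotes; "Limited"
   keeps the chemical but records a ranking note;
3. distribution — a "No" blood–brain-barrier call demotes, because a
   chemical that cannot reach brain acetylcholinesterase cannot trigger
   the molecular initiating event.

A chemical is "low priority" iff at least one gate demoted it.  A known
metabolite with no environmental exposure of its own is judged through
its parent: the parent must be encountered and absorbed before the
metabolite can exist in vivo, after which only the metabolite's own
distribution matters.

Annotated gate calls always take precedence over predicted ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .chemio import (
    AbsorptionClass,
    AssayOutcome,
    ChemicalRecord,
    DistributionClass,
    ExposureCategory,
    MetabolismCode,
    validate_dataset,
    wash_smiles,
)
from .descriptors import (
    AbsorptionCall,
    DistributionCall,
    classify_absorption,
    classify_bbb,
    compute_descriptors,
)
from .errors import AdmetriageError, ConfigError, StructureParseError, WashError
from .fingerprints import ScreenResult, SimilarityHit, screen_inactives

# reason codes (demote) and rank notes (annotate only)
NO_EXPOSURE = "no_exposure"
NEGLIGIBLE_ABSORPTION = "negligible_absorption"
NO_BBB_DISTRIBUTION = "no_bbb_distribution"
INHERITED_LOW = "inherited_from_low_priority_neighbor"
PROMISCUITY_SUSPECT = "promiscuity_suspect"

LIMITED_ABSORPTION = "limited_absorption"
METABOLISM_ACTIVATING = "metabolism_activating"
METABOLISM_DETOXIFYING = "metabolism_detoxifying"


@dataclass(frozen=True)
class GateStep:
    """One evaluated gate: what went in, what came out, and whether the
    input was an annotation or a prediction."""

    gate: str
    input: str
    outcome: str  # "pass" | "demote" | "insufficient"
    source: str = "annotation"  # "annotation" | "predicted" | "absent"


@dataclass
class PriorityCall:
    chemical_id: str
    priority: str  # "high" | "low"
    reasons: list[str] = field(default_factory=list)
    rank_notes: list[str] = field(default_factory=list)
    gate_trace: list[GateStep] = field(default_factory=list)

    def __post_init__(self):
        if (self.priority == "low") != bool(self.reasons):
            raise AdmetriageError(
                f"{self.chemical_id}: priority {self.priority!r} inconsistent with "
                f"reasons {self.reasons}"
            )


def _metabolism_notes(code: MetabolismCode) -> list[str]:
    notes = []
    if code in (MetabolismCode.ACTIVATING, MetabolismCode.MIXED):
        notes.append(METABOLISM_ACTIVATING)
    if code in (MetabolismCode.DETOXIFYING, MetabolismCode.MIXED):
        notes.append(METABOLISM_DETOXIFYING)
    return notes


def _effective_absorption(
    rec: ChemicalRecord, predicted: AbsorptionCall | None
) -> tuple[AbsorptionClass | None, str]:
    if rec.absorption_annotation is not None:
        return rec.absorption_annotation, "annotation"
    if predicted is not None:
        return predicted.cls, "predicted"
    return None, "absent"


def _effective_distribution(
    rec: ChemicalRecord, predicted: DistributionCall | None
) -> tuple[DistributionClass | None, str]:
    if rec.distribution_annotation is not None:
        return rec.distribution_annotation, "annotation"
    if predicted is not None:
        return predicted.bbb_permeable, "predicted"
    return None, "absent"


def assign_priority_parent(
    rec: ChemicalRecord,
    absorption: AbsorptionCall | None = None,
    distribution: DistributionCall | None = None,
) -> PriorityCall:
    """Figure the parent-compound decision path for one active chemical.

    ``absorption``/``distribution`` are predicted calls used only when
    the record carries no annotation for that gate.  Gates are evaluated
    in order exposure → absorption → distribution and stop at the first
    demotion.  Unknown or absent gate values never demote.
    """
    reasons: list[str] = []
    trace: list[GateStep] = []
    notes = _metabolism_notes(rec.metabolism_code)

    # gate 1: exposure
    cat = rec.exposure_category
    if cat is ExposureCategory.NEGLIGIBLE:
        trace.append(GateStep("exposure", "4", "demote"))
        return PriorityCall(rec.id, "low", [NO_EXPOSURE], notes, trace)
    if cat is ExposureCategory.UNANNOTATED:
        trace.append(GateStep("exposure", "unannotated", "insufficient", "absent"))
    else:
        trace.append(GateStep("exposure", str(cat.value), "pass"))

    # gate 2: absorption
    abs_cls, abs_src = _effective_absorption(rec, absorption)
    if abs_cls is AbsorptionClass.NEGLIGIBLE:
        trace.append(GateStep("absorption", abs_cls.value, "demote", abs_src))
        return PriorityCall(rec.id, "low", [NEGLIGIBLE_ABSORPTION], notes, trace)
    if abs_cls is AbsorptionClass.LIMITED:
        notes.insert(0, LIMITED_ABSORPTION)
        trace.append(GateStep("absorption", abs_cls.value, "pass", abs_src))
    elif abs_cls is AbsorptionClass.YES:
        trace.append(GateStep("absorption", abs_cls.value, "pass", abs_src))
    else:  # NA annotation or nothing known
        trace.append(
            GateStep("absorption", abs_cls.value if abs_cls else "unknown",
                     "insufficient", abs_src)
        )

    # gate 3: distribution (blood-brain barrier)
    dist_cls, dist_src = _effective_distribution(rec, distribution)
    if dist_cls is DistributionClass.NO:
        trace.append(GateStep("distribution", dist_cls.value, "demote", dist_src))
        reasons.append(NO_BBB_DISTRIBUTION)
    elif dist_cls is DistributionClass.YES:
        trace.append(GateStep("distribution", dist_cls.value, "pass", dist_src))
    else:
        trace.append(
            GateStep("distribution", dist_cls.value if dist_cls else "unknown",
                     "insufficient", dist_src)
        )

    priority = "low" if reasons else "high"
    return PriorityCall(rec.id, priority, reasons, notes, trace)


def assign_priority_metabolite(
    met: ChemicalRecord,
    parent: ChemicalRecord,
    parent_absorption: AbsorptionCall | None = None,
    met_distribution: DistributionCall | None = None,
) -> PriorityCall:
    """Figure the metabolite decision path.

    A metabolite with environmental exposure of its own (category 1–3)
    is judged exactly like a parent compound.  Otherwise it can only be
    formed in vivo, so the parent's exposure and absorption gates apply,
    followed by the metabolite's own distribution gate.
    """
    if met.parent_id != parent.id:
        raise AdmetriageError(
            f"metabolite {met.id}: parent_id {met.parent_id!r} does not match "
            f"supplied parent {parent.id!r}"
        )
    if met.exposure_category in (
        ExposureCategory.WIDESPREAD,
        ExposureCategory.LIMITED,
        ExposureCategory.UNKNOWN,
    ):
        return assign_priority_parent(met, None, met_distribution)

    notes = _metabolism_notes(met.metabolism_code)
    trace: list[GateStep] = []

    if parent.exposure_category is ExposureCategory.NEGLIGIBLE:
        trace.append(GateStep("parent_exposure", "4", "demote"))
        return PriorityCall(met.id, "low", [NO_EXPOSURE], notes, trace)
    trace.append(
        GateStep(
            "parent_exposure",
            "unannotated"
            if parent.exposure_category is ExposureCategory.UNANNOTATED
            else str(parent.exposure_category.value),
            "insufficient"
            if parent.exposure_category is ExposureCategory.UNANNOTATED
            else "pass",
        )
    )

    abs_cls, abs_src = _effective_absorption(parent, parent_absorption)
    if abs_cls is AbsorptionClass.NEGLIGIBLE:
        trace.append(GateStep("parent_absorption", abs_cls.value, "demote", abs_src))
        return PriorityCall(met.id, "low", [NEGLIGIBLE_ABSORPTION], notes, trace)
    trace.append(
        GateStep(
            "parent_absorption",
            abs_cls.value if abs_cls else "unknown",
            "pass" if abs_cls in (AbsorptionClass.YES, AbsorptionClass.LIMITED) else "insufficient",
            abs_src,
        )
    )

    dist_cls, dist_src = _effective_distribution(met, met_distribution)
    if dist_cls is DistributionClass.NO:
        trace.append(GateStep("distribution", dist_cls.value, "demote", dist_src))
        return PriorityCall(met.id, "low", [NO_BBB_DISTRIBUTION], notes, trace)
    trace.append(
        GateStep(
            "distribution",
            dist_cls.value if dist_cls else "unknown",
            "pass" if dist_cls is DistributionClass.YES else "insufficient",
            dist_src,
        )
    )
    return PriorityCall(met.id, "high", [], notes, trace)


def propagate_neighbor_priority(
    hits: list[SimilarityHit], calls: dict[str, PriorityCall]
) -> list[SimilarityHit]:
    """Flagged inactives inherit "low" from a low-priority nearest
    neighbor; the remaining flagged hits are the possible in vitro false
    negatives.  Unflagged hits pass through untouched."""
    out = []
    for hit in hits:
        if not hit.flagged:
            out.append(hit)
            continue
        if hit.neighbor_id not in calls:
            raise AdmetriageError(
                f"flagged hit {hit.query_id}: neighbor {hit.neighbor_id} has no "
                "priority call"
            )
        neighbor = calls[hit.neighbor_id]
        out.append(
            replace(hit, inherited_priority="low" if neighbor.priority == "low" else None)
        )
    return out


# Default structural alerts for assay promiscuity: dye chromophores and
# reactive/interfering motifs known to light up optical assays without
# genuine target binding.
DEFAULT_ALERTS: tuple[tuple[str, str], ...] = (
    ("triarylmethane_dye", "[#6](=[#6]1[#6]=[#6][#6](=[N+])[#6]=[#6]1)([a])[a]"),
    ("benzyl_azinium", "c[CH2][n+]"),
    ("azo_dye", "cN=Nc"),
    ("quinone", "O=C1C=CC(=O)C=C1"),
    ("rhodanine", "S=C1SC(=O)N1"),
)


def compile_alerts(alert_set=DEFAULT_ALERTS):
    from rdkit import Chem

    compiled = []
    for name, smarts in alert_set:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ConfigError(f"alert {name!r}: malformed SMARTS {smarts!r}")
        compiled.append((name, patt))
    return compiled


def flag_promiscuity(
    records: list[ChemicalRecord],
    alert_set=DEFAULT_ALERTS,
) -> dict[str, tuple[bool, tuple[str, ...]]]:
    """Per-record promiscuity flag with matched alert names.

    An explicit ``promiscuity_override`` on the record wins in both
    directions; otherwise the flag is "any alert substructure matches".
    Records without structures are flagged only by override.
    """
    from rdkit import Chem

    compiled = compile_alerts(alert_set)
    result: dict[str, tuple[bool, tuple[str, ...]]] = {}
    for rec in records:
        matched: tuple[str, ...] = ()
        if rec.smiles:
            try:
                mol = Chem.MolFromSmiles(wash_smiles(rec.smiles, rec.id).washed_smiles)
            except (StructureParseError, WashError):
                mol = None
            if mol is not None:
                matched = tuple(n for n, p in compiled if mol.HasSubstructMatch(p))
        if rec.promiscuity_override is not None:
            result[rec.id] = (rec.promiscuity_override, matched)
        else:
            result[rec.id] = (bool(matched), matched)
    return result


@dataclass
class TriageSummary:
    n_active: int = 0
    n_low: int = 0
    n_low_by_exposure: int = 0
    n_low_by_absorption: int = 0
    n_low_by_bbb: int = 0
    n_high: int = 0
    n_high_non_promiscuous: int = 0
    n_flagged_inactives: int = 0
    n_flagged_low_inherited: int = 0
    n_possible_false_negatives: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TriageReport:
    calls: list[PriorityCall]
    hits: list[SimilarityHit]
    summary: TriageSummary
    config_echo: dict
    skipped: list[tuple[str, str]] = field(default_factory=list)
    names: dict[str, str] = field(default_factory=dict)

    def call_for(self, chemical_id: str) -> PriorityCall:
        for call in self.calls:
            if call.chemical_id == chemical_id:
                return call
        raise KeyError(chemical_id)

    def to_dict(self) -> dict:
        return {
            "calls": [
                {
                    "chemical_id": c.chemical_id,
                    "priority": c.priority,
                    "reasons": list(c.reasons),
                    "rank_notes": list(c.rank_notes),
                    "gate_trace": [
                        {"gate": g.gate, "input": g.input, "outcome": g.outcome,
                         "source": g.source}
                        for g in c.gate_trace
                    ],
                }
                for c in self.calls
            ],
            "hits": [
                {
                    "query_id": h.query_id,
                    "neighbor_id": h.neighbor_id,
                    "tanimoto": round(h.tanimoto, 4),
                    "flagged": h.flagged,
                    "inherited_priority": h.inherited_priority,
                    "ties": list(h.ties),
                }
                for h in self.hits
            ],
            "summary": self.summary.to_dict(),
            "config_echo": self.config_echo,
            "skipped": [list(s) for s in self.skipped],
        }


def run_workflow(
    records: list[ChemicalRecord], config=None, *, require_exposure: bool = True
) -> TriageReport:
    """End-to-end triage of a screened dataset.

    Actives are washed, descriptors computed where a gate lacks an
    annotation, and gated through the parent or metabolite decision
    path.  Inactives are screened against the actives by MACCS/Tanimoto
    nearest neighbor; flagged hits inherit low priority from
    low-priority neighbors, and the rest form the possible
    false-negative list.  Promiscuity alerts annotate (and, only if
    configured, demote) high-priority actives.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    validate_dataset(records, require_exposure=require_exposure)
    by_id = {r.id: r for r in records}
    actives = [r for r in records if r.assay_outcome is AssayOutcome.ACTIVE]
    inactives = [r for r in records if r.assay_outcome is AssayOutcome.INACTIVE]

    calls: list[PriorityCall] = []
    skipped: list[tuple[str, str]] = []
    for rec in actives:
        predicted_abs = predicted_dist = None
        needs_prediction = (
            rec.absorption_annotation is None or rec.distribution_annotation is None
        )
        if needs_prediction and rec.smiles:
            try:
                d = compute_descriptors(wash_smiles(rec.smiles, rec.id))
                predicted_abs = classify_absorption(d, cfg.ro5)
                predicted_dist = classify_bbb(d, cfg.bbb_rules)
            except (StructureParseError, WashError) as exc:
                skipped.append((rec.id, f"descriptor prediction failed: {exc}"))
        parent = by_id.get(rec.parent_id) if rec.parent_id else None
        if parent is not None:
            call = assign_priority_metabolite(rec, parent, None, predicted_dist)
        else:
            call = assign_priority_parent(rec, predicted_abs, predicted_dist)
        calls.append(call)

    call_map = {c.chemical_id: c for c in calls}

    hits: list[SimilarityHit] = []
    if inactives and any(r.smiles for r in actives) and any(r.smiles for r in inactives):
        screen = screen_inactives(inactives, actives, cfg.threshold)
        hits = propagate_neighbor_priority(screen.hits, call_map)
        skipped.extend(screen.skipped)

    promiscuity = flag_promiscuity(actives, cfg.alerts)
    for call in calls:
        flagged, _ = promiscuity.get(call.chemical_id, (False, ()))
        if flagged:
            call.rank_notes.append(PROMISCUITY_SUSPECT)
            if cfg.demote_promiscuous and call.priority == "high":
                call.priority = "low"
                call.reasons.append(PROMISCUITY_SUSPECT)

    summary = TriageSummary(
        n_active=len(actives),
        n_low=sum(c.priority == "low" for c in calls),
        n_low_by_exposure=sum(c.reasons == [NO_EXPOSURE] for c in calls),
        n_low_by_absorption=sum(NEGLIGIBLE_ABSORPTION in c.reasons for c in calls),
        n_low_by_bbb=sum(NO_BBB_DISTRIBUTION in c.reasons for c in calls),
        n_high=sum(c.priority == "high" for c in calls),
        n_flagged_inactives=sum(h.flagged for h in hits),
        n_flagged_low_inherited=sum(h.inherited_priority == "low" for h in hits),
    )
    summary.n_high_non_promiscuous = sum(
        c.priority == "high" and PROMISCUITY_SUSPECT not in c.rank_notes for c in calls
    )
    summary.n_possible_false_negatives = (
        summary.n_flagged_inactives - summary.n_flagged_low_inherited
    )
    return TriageReport(
        calls=calls,
        hits=hits,
        summary=summary,
        config_echo=cfg.to_dict(),
        skipped=skipped,
        names={r.id: r.name for r in records},
    )
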