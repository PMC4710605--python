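"""Decision-tree logic, priority propagation, promiscuity flagging."""

import pytest

from admetriage import (
    AbsorptionClass,
    AssayOutcome,
    ChemicalRecord,
    DistributionClass,
    ExposureCategory,
    RunConfig,
    SimilarityHit,
    assign_priority_metabolite,
    assign_priority_parent,
    flag_promiscuity,
    generate_triage_grid,
    propagate_neighbor_priority,
    run_workflow,
)
from admetriage.errors import AdmetriageError
from admetriage.triage import (
    INHERITED_LOW,
    NEGLIGIBLE_ABSORPTION,
    NO_BBB_DISTRIBUTION,
    NO_EXPOSURE,
    LIMITED_ABSORPTION,
    PriorityCall,
)


def oracle_parent_priority(exposure, absorption, distribution):
    """Independent statement of the parent decision tree: demote on
    no-exposure (category 4), on negligible absorption, or on a BBB
    "No"; everything else - including every unknown - stays high."""
    if exposure == 4:
        return "low", ["no_exposure"]
    if absorption == "Negligible":
        return "low", ["negligible_absorption"]
    if distribution == "No":
        return "low", ["no_bbb_distribution"]
    return "high", []


def _grid_tokens(rec):
    exposure = rec.exposure_category.value if rec.exposure_category.value else "u"
    return exposure, rec.absorption_annotation.value, rec.distribution_annotation.value


class TestParentDecisionTree:
    def test_truth_table_matches_oracle_on_all_60_combinations(self):
        grid = generate_triage_grid()
        assert len(grid) == 60
        for rec in grid:
            call = assign_priority_parent(rec)
            expected_priority, expected_reasons = oracle_parent_priority(*_grid_tokens(rec))
            assert call.priority == expected_priority, rec.id
            assert call.reasons == expected_reasons, rec.id

    def test_exposure_gate_short_circuits(self):
        rec = ChemicalRecord(
            id="x",
            assay_outcome=AssayOutcome.ACTIVE,
            exposure_category=ExposureCategory.NEGLIGIBLE,
        )
        call = assign_priority_parent(rec)
        assert call.priority == "low"
        assert call.reasons == [NO_EXPOSURE]
        assert len(call.gate_trace) == 1
        assert call.gate_trace[0].gate == "exposure"

    def test_negligible_absorption_stops_before_distribution(self):
        rec = ChemicalRecord(
            id="x",
            assay_outcome=AssayOutcome.ACTIVE,
            exposure_category=ExposureCategory.WIDESPREAD,
            absorption_annotation=AbsorptionClass.NEGLIGIBLE,
            distribution_annotation=DistributionClass.NO,
        )
        call = assign_priority_parent(rec)
        assert call.reasons == [NEGLIGIBLE_ABSORPTION]
        assert [g.gate for g in call.gate_trace] == ["exposure", "absorption"]

    def test_limited_absorption_keeps_high_with_rank_note(self):
        rec = ChemicalRecord(
            id="x",
            assay_outcome=AssayOutcome.ACTIVE,
            exposure_category=ExposureCategory.WIDESPREAD,
            absorption_annotation=AbsorptionClass.LIMITED,
            distribution_annotation=DistributionClass.YES,
        )
        call = assign_priority_parent(rec)
        assert call.priority == "high"
        assert LIMITED_ABSORPTION in call.rank_notes

    def test_annotation_precedence_over_prediction(self):
        """A provided annotation must be used verbatim; the predicted
        call must not even appear in the trace source."""
        from admetriage import classify_bbb, compute_descriptors, wash_smiles

        rec = ChemicalRecord(
            id="anthralin",
            smiles="O=C1c2cccc(O)c2Cc2cccc(O)c21",
            assay_outcome=AssayOutcome.ACTIVE,
            exposure_category=ExposureCategory.LIMITED,
            absorption_annotation=AbsorptionClass.YES,
            distribution_annotation=DistributionClass.NO,
        )
        predicted = classify_bbb(compute_descriptors(wash_smiles(rec.smiles)))
        # the prediction disagrees with the annotation here - the
        # reference BBB model was proprietary and opaque
        assert predicted.bbb_permeable is DistributionClass.YES
        call = assign_priority_parent(rec, None, predicted)
        assert call.priority == "low"
        assert call.reasons == [NO_BBB_DISTRIBUTION]
        dist_step = next(g for g in call.gate_trace if g.gate == "distribution")
        assert dist_step.source == "annotation"

    def test_unknown_gates_never_demote(self):
        rec = ChemicalRecord(
            id="x",
            assay_outcome=AssayOutcome.ACTIVE,
            exposure_category=ExposureCategory.UNKNOWN,
        )
        call = assign_priority_parent(rec)
        assert call.priority == "high"
        assert all(g.outcome != "demote" for g in call.gate_trace)

    def test_call_consistency_enforced(self):
        with pytest.raises(AdmetriageError):
            PriorityCall("x", "low", reasons=[])


class TestMetaboliteDecisionTree:
    def _parent(self, exposure, absorption=AbsorptionClass.YES):
        return ChemicalRecord(
            id="parent",
            assay_outcome=AssayOutcome.INACTIVE,
            exposure_category=exposure,
            absorption_annotation=absorption,
        )

    def test_own_exposure_routes_through_parent_path(self):
        met = ChemicalRecord(
            id="met",
            parent_id="parent",
            assay_outcome=AssayOutcome.ACTIVE,
            exposure_category=ExposureCategory.WIDESPREAD,
            absorption_annotation=AbsorptionClass.YES,
            distribution_annotation=DistributionClass.YES,
        )
        call = assign_priority_metabolite(met, self._parent(ExposureCategory.NEGLIGIBLE))
        assert call.priority == "high"
        assert call.gate_trace[0].gate == "exposure"  # not parent_exposure

    def test_no_own_exposure_parent_unexposed_demotes(self):
        met = ChemicalRecord(
            id="met",
            parent_id="parent",
            assay_outcome=AssayOutcome.ACTIVE,
            exposure_category=ExposureCategory.NEGLIGIBLE,
            distribution_annotation=DistributionClass.YES,
        )
        call = assign_priority_metabolite(met, self._parent(ExposureCategory.NEGLIGIBLE))
        assert call.priority == "low"
        assert call.reasons == [NO_EXPOSURE]
        assert call.gate_trace[0].gate == "parent_exposure"

    def test_no_own_exposure_parent_unabsorbed_demotes(self):
        met = ChemicalRecord(
            id="met",
            parent_id="parent",
            assay_outcome=AssayOutcome.ACTIVE,
            exposure_category=ExposureCategory.NEGLIGIBLE,
        )
        parent = self._parent(ExposureCategory.WIDESPREAD, AbsorptionClass.NEGLIGIBLE)
        call = assign_priority_metabolite(met, parent)
        assert call.reasons == [NEGLIGIBLE_ABSORPTION]

    def test_surviving_parent_gates_leaves_distribution_decision(self):
        met = ChemicalRecord(
            id="met",
            parent_id="parent",
            assay_outcome=AssayOutcome.ACTIVE,
            exposure_category=ExposureCategory.NEGLIGIBLE,
            distribution_annotation=DistributionClass.NO,
        )
        call = assign_priority_metabolite(met, self._parent(ExposureCategory.WIDESPREAD))
        assert call.reasons == [NO_BBB_DISTRIBUTION]

    def test_mismatched_parent_link_rejected(self):
        met = ChemicalRecord(
            id="met", parent_id="other", assay_outcome=AssayOutcome.ACTIVE
        )
        with pytest.raises(AdmetriageError, match="parent_id"):
            assign_priority_metabolite(met, self._parent(ExposureCategory.WIDESPREAD))


class TestPropagation:
    def _call(self, cid, priority):
        reasons = [NO_EXPOSURE] if priority == "low" else []
        return PriorityCall(cid, priority, reasons)

    def test_flagged_inherits_low_from_low_neighbor(self):
        hits = [SimilarityHit("zamifenacin", "raloxifene", 0.76, flagged=True)]
        calls = {"raloxifene": self._call("raloxifene", "low")}
        (out,) = propagate_neighbor_priority(hits, calls)
        assert out.inherited_priority == "low"

    def test_flagged_with_high_neighbor_stays_false_negative(self):
        hits = [SimilarityHit("aldicarb", "methomyl", 0.88, flagged=True)]
        calls = {"methomyl": self._call("methomyl", "high")}
        (out,) = propagate_neighbor_priority(hits, calls)
        assert out.inherited_priority is None

    def test_unflagged_hit_untouched(self):
        hit = SimilarityHit("malaoxon", "mevinphos", 0.57, flagged=False)
        (out,) = propagate_neighbor_priority([hit], {})
        assert out == hit

    def test_flagged_without_neighbor_call_is_an_error(self):
        hits = [SimilarityHit("q", "missing", 0.9, flagged=True)]
        with pytest.raises(AdmetriageError, match="missing"):
            propagate_neighbor_priority(hits, {})


class TestPromiscuity:
    def test_override_true_flags(self):
        rec = ChemicalRecord(id="gv", smiles="CCO", promiscuity_override=True)
        flags = flag_promiscuity([rec])
        assert flags["gv"][0] is True

    def test_override_false_beats_matching_alert(self):
        quinone = ChemicalRecord(
            id="q", smiles="O=C1C=CC(=O)C=C1", promiscuity_override=False
        )
        flagged, matched = flag_promiscuity([quinone])["q"]
        assert matched  # the alert does match
        assert flagged is False  # but the override wins

    def test_default_alerts_catch_fixture_dyes_without_override(self, fixture_set):
        by_id = {r.id: r for r in fixture_set.table1_actives}
        import dataclasses

        no_override = [
            dataclasses.replace(by_id[i], promiscuity_override=None)
            for i in ("gentian-violet", "1-benzylquinolinium-chloride")
        ]
        flags = flag_promiscuity(no_override)
        assert all(f for f, _ in flags.values())

    def test_ethanol_clean(self):
        assert flag_promiscuity([ChemicalRecord(id="e", smiles="CCO")])["e"] == (
            False,
            (),
        )

    def test_malformed_alert_rejected_at_load(self):
        from admetriage.errors import ConfigError

        with pytest.raises(ConfigError, match="broken"):
            flag_promiscuity(
                [ChemicalRecord(id="e", smiles="CCO")],
                alert_set=(("broken", "[[["),),
            )


class TestRunWorkflow:
    def test_empty_dataset_empty_report(self):
        report = run_workflow([], RunConfig())
        assert report.calls == [] and report.hits == []
        assert report.summary.n_active == 0

    def test_grid_dataset_matches_oracle_end_to_end(self):
        # the grid deliberately includes exposure-unannotated actives
        report = run_workflow(
            generate_triage_grid(), RunConfig(), require_exposure=False
        )
        for call in report.calls:
            rec_id = call.chemical_id  # grid-e{e}-a{a}-d{d}
            _, e, a, d = rec_id.split("-")
            exposure = int(e[1:]) if e[1:] != "u" else "u"
            expected, _ = oracle_parent_priority(exposure, a[1:], d[1:])
            assert call.priority == expected, rec_id

    def test_summary_count_identities(self, table1_report):
        s = table1_report.summary
        assert s.n_low + s.n_high == s.n_active
        assert s.n_low_by_exposure + s.n_low_by_absorption + s.n_low_by_bbb == s.n_low
        assert (
            s.n_possible_false_negatives
            == s.n_flagged_inactives - s.n_flagged_low_inherited
        )

    def test_demote_promiscuous_switch(self, fixture_set):
        report = run_workflow(
            fixture_set.all_records, RunConfig(demote_promiscuous=True)
        )
        assert report.summary.n_high == 18
        assert report.summary.n_low == 12

    def test_inheritance_at_relaxed_threshold(self, fixture_set):
        """At a 0.60 flag threshold the muscarinic antagonist in the
        discussion set is flagged against the demoted raloxifene and
        inherits its low priority."""
        report = run_workflow(fixture_set.all_records, RunConfig(threshold=0.60))
        hit = next(h for h in report.hits if h.query_id == "zamifenacin")
        assert hit.flagged
        assert hit.neighbor_id == "raloxifene-hydrochloride"
        assert hit.inherited_priority == "low"
        malaoxon = next(h for h in report.hits if h.query_id == "malaoxon")
        assert not malaoxon.flagged
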