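"""The three derivation steps: classify, formalize, compose."""

import pytest

from pathforge import hl7_io
from pathforge.derivation import (
    AttributeSchemaSet,
    IdAllocator,
    MarkupRecord,
    PhasePlan,
    PhaseSpec,
    add_local_activity,
    classify_recommendation,
    compose,
    formalize,
    formalize_parameter,
    schema_for,
)
from pathforge.errors import (
    CompositionError,
    ConfigurationError,
    EnumerationError,
    KindMismatchError,
)
from pathforge.metamodel import (
    ActivityKind,
    CodedConcept,
    ControlFlowEdge,
    Guideline,
    ModelRepository,
    ParameterCategory,
    RecommendationKind,
)

DEXA = ("Patients with early invasive breast cancer should have a baseline dual "
        "energy X-ray absorptiometry (DEXA) scan to assess bone mineral density")


@pytest.fixture
def repo():
    r = ModelRepository()
    r.add_guideline(Guideline(id="gl", title="test guideline"))
    return r


@pytest.fixture
def schemas():
    return AttributeSchemaSet.default()


class TestClassify:
    def test_dexa_excerpt_becomes_observation(self, repo):
        rec = classify_recommendation(
            MarkupRecord(guideline_id="gl", excerpt=DEXA,
                         kind=RecommendationKind.observation),
            repo, IdAllocator())
        assert rec.kind is RecommendationKind.observation
        assert rec.text == DEXA
        assert rec.id in repo.recommendations
        assert rec.id in repo.guidelines["gl"].recommendations

    def test_empty_excerpt_rejected(self, repo):
        with pytest.raises(ValueError):
            MarkupRecord(guideline_id="gl", excerpt="",
                         kind=RecommendationKind.observation)
        record = MarkupRecord(guideline_id="gl", excerpt="x",
                              kind=RecommendationKind.observation)
        record = record.model_copy(update={"excerpt": "   "})
        with pytest.raises(EnumerationError):
            classify_recommendation(record, repo, IdAllocator())

    def test_additional_information_class_is_echoed(self, repo):
        rec = classify_recommendation(
            MarkupRecord(guideline_id="gl", excerpt="risk factor: obesity",
                         kind=RecommendationKind.additional_information),
            repo, IdAllocator())
        assert rec.kind is RecommendationKind.additional_information

    def test_unknown_kind_in_markup_file(self, tmp_path):
        f = tmp_path / "markup.tsv"
        f.write_text("gl\tsurgery-robot\tannot\t\t\tdo something\n")
        with pytest.raises(EnumerationError):
            from pathforge.derivation import load_markup
            load_markup(f)


class TestSchemas:
    def test_procedure_requires_name_and_ops_code(self, schemas):
        s = schema_for("procedure", schemas)
        assert {"name", "ops_code"} <= set(s.required)

    def test_medication_schema_contains_dosage(self, schemas):
        assert "dosage" in schema_for(ActivityKind.medication, schemas).all_attributes

    def test_unknown_kind_is_configuration_error(self, schemas):
        with pytest.raises(ConfigurationError):
            schema_for("surgery-robot", schemas)

    def test_required_and_optional_must_be_disjoint(self):
        with pytest.raises(ValueError):
            AttributeSchemaSet.from_mapping(
                {"procedure": {"required": ["name", "x"], "optional": ["x"]}})


class TestFormalize:
    def test_dexa_formalization_is_complete_with_evidence(self, repo, schemas):
        ids = IdAllocator()
        rec = classify_recommendation(
            MarkupRecord(guideline_id="gl", excerpt=DEXA,
                         kind=RecommendationKind.observation), repo, ids)
        result = formalize(rec, {"name": "dual energy X-ray absorptiometry",
                                 "target": "bone mineral density"}, schemas, ids)
        assert result.complete
        assert result.activity.kind is ActivityKind.observation
        assert result.activity.evidence_link == rec.id
        assert not result.activity.local_origin

    def test_nothing_supplied_lists_required_attributes(self, repo, schemas):
        ids = IdAllocator()
        rec = classify_recommendation(
            MarkupRecord(guideline_id="gl", excerpt="operate",
                         kind=RecommendationKind.procedure), repo, ids)
        result = formalize(rec, {}, schemas, ids)
        assert not result.complete
        assert {"name", "ops_code"} <= set(result.missing)

    def test_repeat_formalization_identical_except_fresh_id(self, repo, schemas):
        ids = IdAllocator()
        rec = classify_recommendation(
            MarkupRecord(guideline_id="gl", excerpt=DEXA,
                         kind=RecommendationKind.observation), repo, ids)
        values = {"name": "DEXA", "target": "bone mineral density"}
        a = formalize(rec, values, schemas, ids).activity
        b = formalize(rec, values, schemas, ids).activity
        assert a.id != b.id
        assert a.model_dump(exclude={"id"}) == b.model_dump(exclude={"id"})

    def test_extra_values_kept_with_warning_not_error(self, repo, schemas):
        ids = IdAllocator()
        rec = classify_recommendation(
            MarkupRecord(guideline_id="gl", excerpt=DEXA,
                         kind=RecommendationKind.observation), repo, ids)
        result = formalize(rec, {"name": "DEXA", "target": "bone",
                                 "color": "grey"}, schemas, ids)
        assert result.complete
        assert result.extras == {"color": "grey"}
        assert any("color" in w for w in result.warnings)

    def test_additional_information_is_rejected(self, repo, schemas):
        ids = IdAllocator()
        rec = classify_recommendation(
            MarkupRecord(guideline_id="gl", excerpt="risk factor: obesity",
                         kind=RecommendationKind.additional_information), repo, ids)
        with pytest.raises(KindMismatchError):
            formalize(rec, {}, schemas, ids)


class TestParametersAndLocalActivities:
    def test_risk_factor_parameter_at_pathway_scope(self, repo):
        ids = IdAllocator()
        rec = classify_recommendation(
            MarkupRecord(guideline_id="gl", excerpt="risk factor: obesity",
                         kind=RecommendationKind.additional_information), repo, ids)
        p = formalize_parameter(rec, ParameterCategory.risk_factor, "pw-1", ids)
        assert p.category is ParameterCategory.risk_factor
        assert p.value == "risk factor: obesity"
        assert p.scope == "pw-1"

    def test_complication_parameter_attached_to_activity(self, repo):
        ids = IdAllocator()
        rec = classify_recommendation(
            MarkupRecord(guideline_id="gl", excerpt="watch for seroma",
                         kind=RecommendationKind.additional_information), repo, ids)
        p = formalize_parameter(rec, "complication", "act-X", ids)
        assert p.scope == "act-X"

    def test_activity_kind_recommendation_is_kind_mismatch(self, repo):
        ids = IdAllocator()
        rec = classify_recommendation(
            MarkupRecord(guideline_id="gl", excerpt=DEXA,
                         kind=RecommendationKind.observation), repo, ids)
        with pytest.raises(KindMismatchError):
            formalize_parameter(rec, "risk_factor", "pw", ids)

    def test_nursing_activity_has_local_origin_no_evidence(self, schemas):
        result = add_local_activity(
            "procedure", {"name": "wound dressing change"}, schemas, IdAllocator())
        assert result.activity.local_origin
        assert result.activity.evidence_link is None

    def test_admission_encounter_is_complete(self, schemas):
        result = add_local_activity(
            ActivityKind.encounter,
            {"name": "patient admission", "encounter_type": "admission"},
            schemas, IdAllocator())
        assert result.complete

    def test_empty_values_give_incomplete_draft(self, schemas):
        assert not add_local_activity("encounter", {}, schemas, IdAllocator()).complete

    def test_unknown_local_kind_rejected(self, schemas):
        with pytest.raises(EnumerationError):
            add_local_activity("surgery-robot", {"name": "x"}, schemas, IdAllocator())


class TestCompose:
    def _three_results(self, schemas):
        ids = IdAllocator()
        return [add_local_activity(
            "encounter", {"name": f"visit {i}", "encounter_type": "admission"},
            schemas, ids) for i in range(3)]

    def test_three_named_phases_in_order(self, schemas):
        results = self._three_results(schemas)
        names = ["preoperative day", "day of surgery", "postoperative day"]
        plan = PhasePlan(phases=[
            PhaseSpec(id=f"ph{i}", name=n, anchor_offset=i,
                      activity_ids=[results[i].activity.id])
            for i, n in enumerate(names)])
        pw = compose(results, plan, pathway_id="pw", name="test")
        assert [p.name for p in pw.phases] == names

    def test_single_complete_activity_composes(self, schemas):
        r = self._three_results(schemas)[:1]
        pw = compose(r, PhasePlan(phases=[PhaseSpec(
            id="ph", name="day", activity_ids=[r[0].activity.id])]),
            pathway_id="pw", name="one")
        assert len(pw.phases) == 1

    def test_cyclic_edges_rejected_matching_brute_force(self, schemas):
        from test_metamodel import brute_force_has_cycle
        results = self._three_results(schemas)
        ids = [r.activity.id for r in results]
        edges = [ControlFlowEdge(from_activity=ids[0], to_activity=ids[1]),
                 ControlFlowEdge(from_activity=ids[1], to_activity=ids[2]),
                 ControlFlowEdge(from_activity=ids[2], to_activity=ids[0])]
        assert brute_force_has_cycle(ids, edges)
        plan = PhasePlan(phases=[PhaseSpec(id="ph", name="day",
                                           activity_ids=ids, edges=edges)])
        with pytest.raises(CompositionError, match="cycle"):
            compose(results, plan, pathway_id="pw", name="cyclic")

    def test_incomplete_activity_blocks_composition_listing_missing(self, schemas):
        draft = add_local_activity("procedure", {"name": "x"}, schemas, IdAllocator())
        plan = PhasePlan(phases=[PhaseSpec(id="ph", name="day",
                                           activity_ids=[draft.activity.id])])
        with pytest.raises(CompositionError, match="ops_code"):
            compose([draft], plan, pathway_id="pw", name="draft")

    def test_unassigned_activity_rejected(self, schemas):
        results = self._three_results(schemas)
        plan = PhasePlan(phases=[PhaseSpec(
            id="ph", name="day", activity_ids=[results[0].activity.id])])
        with pytest.raises(CompositionError, match="not assigned"):
            compose(results, plan, pathway_id="pw", name="partial")

    def test_provenance_conservation(self, bundle):
        """Every non-local activity traces to a recommendation to a guideline."""
        for _, act in bundle.full_pathway.iter_activities():
            if act.local_origin:
                continue
            rec = bundle.repository.recommendations[act.evidence_link]
            assert rec.guideline_id in bundle.repository.guidelines
            assert rec.guideline_id in bundle.full_pathway.guideline_ids

    def test_composition_is_deterministic(self, bundle):
        from pathforge.fixtures import breast_carcinoma_bundle
        other = breast_carcinoma_bundle()
        a = hl7_io.write_xml(bundle.full_pathway, repository=bundle.repository)
        b = hl7_io.write_xml(other.full_pathway, repository=other.repository)
        assert a == b
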