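"""Deployment plans, choice resolution and dialect rendering."""

import random
import sqlite3

import pytest
from lxml import etree

from pathforge.deployment import (
    ChoiceConfig,
    TemplateSet,
    plan_deployment,
    render_relational,
    render_target_xml,
    resolve,
)
from pathforge.errors import (
    CoverageError,
    DialectGapError,
    InvalidChoiceError,
    UnresolvedChoiceError,
)
from pathforge.fixtures import docpath_mapping, docpath_profile, random_document
from pathforge.metamodel import ClinicalPathway, TreatmentPhase
from pathforge.ontology import (
    ComponentMapping,
    build_instance_model,
    merge_reasoning_model,
    query_counterparts,
)


def load_and_count_units(sql_script: str) -> int:
    """Independent oracle: load the insert script and count emitted units."""
    con = sqlite3.connect(":memory:")
    con.executescript(sql_script)
    n_el = con.execute("SELECT count(*) FROM element").fetchone()[0]
    n_at = con.execute("SELECT count(*) FROM attachment").fetchone()[0]
    return n_el + n_at


def parse_and_count_units(xml_payload: str) -> int:
    root = etree.fromstring(xml_payload.encode("utf-8"))
    return len(root.xpath("//*[@element]"))


class TestPlanning:
    def test_toy_plan_diagnosis_auto_phase_pending(self, toy_model):
        plan = plan_deployment(toy_model)
        concepts = toy_model.instance.element_nodes
        auto_concepts = {concepts[n] for n in plan.auto}
        assert "meta:InclusionDiagnosis" in auto_concepts
        (phase_node,) = [n for n in plan.pending]
        assert concepts[phase_node] == "meta:TreatmentPhase"
        assert len(plan.pending[phase_node]) == 2
        assert plan.unmapped == []

    def test_empty_instance_gives_empty_plan(self):
        pw = ClinicalPathway(id="p", name="x",
                             phases=[TreatmentPhase(id="ph", name="day")])
        inst = build_instance_model(pw)
        model = merge_reasoning_model(inst, docpath_profile(), ComponentMapping([]))
        plan = plan_deployment(model)
        assert not plan.auto and not plan.pending
        assert plan.unmapped == ["inst:ph"]

    @pytest.mark.parametrize("seed", range(6))
    def test_partition_matches_option_count_oracle(self, seed):
        doc = random_document(random.Random(31 + seed), index=seed)
        pw = doc.pathways[0]
        inst = build_instance_model(pw, doc.repository())
        model = merge_reasoning_model(inst, docpath_profile(), docpath_mapping())
        plan = plan_deployment(model)
        for node in inst.order:
            n_options = len(query_counterparts(model, node))
            if n_options == 0:
                assert node in plan.unmapped
            elif n_options == 1:
                assert node in plan.auto
            else:
                assert node in plan.pending and len(plan.pending[node]) == n_options
        assert sorted(list(plan.auto) + list(plan.pending) + plan.unmapped) == \
            sorted(inst.order)

    def test_plan_json_round_trip(self, toy_model, tmp_path):
        from pathforge.deployment import DeploymentPlan
        plan = plan_deployment(toy_model)
        path = tmp_path / "plan.json"
        plan.to_json(path)
        again = DeploymentPlan.from_json(path)
        assert again.auto == plan.auto and again.pending == plan.pending
        assert again.order == plan.order


class TestResolve:
    def test_phase_choice_dimension_is_honoured(self, toy_model):
        plan = plan_deployment(toy_model)
        (phase_node,) = plan.pending
        choices = ChoiceConfig(selections={phase_node: "docpath:PhaseDimension"})
        resolved = resolve(plan, choices)
        assert resolved.assignments[phase_node].target_concept == "docpath:PhaseDimension"

    def test_empty_pending_resolves_to_auto(self, toy_model):
        plan = plan_deployment(toy_model)
        plan.pending.clear()
        plan.order = [n for n in plan.order if n in plan.auto]
        resolved = resolve(plan, ChoiceConfig())
        assert resolved.assignments == plan.auto

    def test_concept_level_default_covers_all_phases(self, full_model, bundle):
        plan = plan_deployment(full_model)
        resolved = resolve(plan, bundle.choices)
        assert len(resolved.assignments) == len(full_model.instance.order)

    def test_element_selection_beats_concept_default(self, full_model, bundle):
        plan = plan_deployment(full_model)
        phase_nodes = [n for n in plan.pending
                       if plan.concepts[n] == "meta:TreatmentPhase"]
        choices = bundle.choices.model_copy(deep=True)
        choices.selections[phase_nodes[0]] = "docpath:OptionalElement"
        resolved = resolve(plan, choices)
        assert resolved.assignments[phase_nodes[0]].target_concept == \
            "docpath:OptionalElement"
        assert resolved.assignments[phase_nodes[1]].target_concept == \
            "docpath:PhaseDimension"

    def test_unoffered_option_is_invalid_choice(self, toy_model):
        plan = plan_deployment(toy_model)
        (phase_node,) = plan.pending
        with pytest.raises(InvalidChoiceError, match="hologram"):
            resolve(plan, ChoiceConfig(selections={phase_node: "hologram"}))

    def test_strict_mode_uncovered_pending_lists_elements(self, toy_model):
        plan = plan_deployment(toy_model)
        (phase_node,) = plan.pending
        with pytest.raises(UnresolvedChoiceError) as exc:
            resolve(plan, ChoiceConfig())
        assert phase_node in str(exc.value)

    def test_unmapped_elements_block_deployment(self, bundle):
        inst = build_instance_model(bundle.toy_pathway, bundle.repository)
        no_encounter = ComponentMapping(
            [e for e in bundle.mapping.entries
             if e.metamodel_concept != "meta:Encounter"])
        plan = plan_deployment(merge_reasoning_model(inst, bundle.profile, no_encounter))
        with pytest.raises(CoverageError):
            resolve(plan, bundle.choices)
        resolved = resolve(plan, bundle.choices, allow_unmapped=True)
        assert len(resolved.assignments) == 2  # encounter dropped, logged separately

    def test_interactive_choices_are_recorded_for_replay(self, toy_model):
        plan = plan_deployment(toy_model)
        choices = ChoiceConfig(user="tester")
        resolved = resolve(plan, choices, mode="interactive",
                           chooser=lambda node, options: options[1])
        (phase_node,) = [n for n in resolved.assignments
                         if plan.concepts[n] == "meta:TreatmentPhase"]
        assert choices.selections[phase_node] == "docpath:OptionalElement"
        # the saved config now replays strictly
        replay = resolve(plan_deployment(toy_model), choices, mode="strict")
        assert replay.assignments[phase_node].target_concept == "docpath:OptionalElement"


@pytest.fixture
def resolved_full(full_model, bundle):
    return resolve(plan_deployment(full_model), bundle.choices)


class TestRendering:
    def test_relational_script_structure(self, resolved_full, bundle):
        art = render_relational(resolved_full, bundle.full_pathway)
        assert "INSERT INTO pathway " in art.payload
        assert art.payload.count("INSERT INTO phase_day") == 3
        con = sqlite3.connect(":memory:")
        con.executescript(art.payload)
        dims = dict(con.execute("SELECT id, label FROM dimension").fetchall())
        assert dims["phase"] == "Phase"
        phase_rows = con.execute(
            "SELECT count(*) FROM element WHERE dimension_id='phase'").fetchone()[0]
        assert phase_rows == 3

    def test_relational_conservation_load_and_count(self, resolved_full, bundle):
        art = render_relational(resolved_full, bundle.full_pathway)
        assert load_and_count_units(art.payload) == len(resolved_full.assignments)
        assert sorted(art.manifest.values()) == list(range(len(art.manifest)))
        assert set(art.manifest) == set(resolved_full.assignments)

    def test_empty_resolved_plan_gives_ddl_only_script(self):
        pw = ClinicalPathway(id="p", name="bare",
                             phases=[TreatmentPhase(id="ph", name="day")])
        inst = build_instance_model(pw)
        model = merge_reasoning_model(inst, docpath_profile(), ComponentMapping([]))
        resolved = resolve(plan_deployment(model), allow_unmapped=True)
        art = render_relational(resolved, pw)
        assert load_and_count_units(art.payload) == 0
        assert "CREATE TABLE element" in art.payload

    def test_target_xml_conservation_parse_and_count(self, resolved_full, bundle):
        art = render_target_xml(resolved_full, bundle.full_pathway)
        assert parse_and_count_units(art.payload) == len(resolved_full.assignments)

    def test_phase_sits_under_dimension_container(self, resolved_full, bundle):
        art = render_target_xml(resolved_full, bundle.full_pathway)
        root = etree.fromstring(art.payload.encode("utf-8"))
        entries = root.xpath("//dimension[@id='phase']/entry")
        assert len(entries) == 3
        assert all(e.get("kind") == "phase" for e in entries)

    def test_rendering_is_byte_deterministic(self, resolved_full, bundle):
        a = render_target_xml(resolved_full, bundle.full_pathway)
        b = render_target_xml(resolved_full, bundle.full_pathway)
        assert a.payload == b.payload
        assert render_relational(resolved_full, bundle.full_pathway).payload == \
            render_relational(resolved_full, bundle.full_pathway).payload

    def test_missing_template_is_dialect_gap(self, resolved_full, bundle):
        crippled = TemplateSet.default()
        crippled.options = {k: v for k, v in crippled.options.items()
                            if k != "docpath:Prescription"}
        with pytest.raises(DialectGapError, match="docpath:Prescription"):
            render_relational(resolved_full, bundle.full_pathway, crippled)

    def test_choice_locality_single_perturbation(self, full_model, bundle):
        """Changing one element's choice changes only that element's unit."""
        plan = plan_deployment(full_model)
        phase_node = [n for n in plan.pending
                      if plan.concepts[n] == "meta:TreatmentPhase"][1]
        base = resolve(plan, bundle.choices)
        perturbed_choices = bundle.choices.model_copy(deep=True)
        perturbed_choices.selections[phase_node] = "docpath:OptionalElement"
        pert = resolve(plan_deployment(full_model), perturbed_choices)

        for render in (render_relational, render_target_xml):
            a = render(base, bundle.full_pathway)
            b = render(pert, bundle.full_pathway)
            a_lines = [l for l in a.payload.splitlines() if "inst:" in l]
            b_lines = [l for l in b.payload.splitlines() if "inst:" in l]
            assert len(a_lines) == len(b_lines)
            only_a = [l for l in a_lines if l not in b_lines]
            only_b = [l for l in b_lines if l not in a_lines]
            assert only_a and only_b
            assert all(phase_node in l for l in only_a + only_b)
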