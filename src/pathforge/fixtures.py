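"""Fixture generator: the worked breast-carcinoma example, end to end.

Real guideline corpora cannot ship with the toolkit, so this module builds
a small, faithful stand-in from the worked example the approach is usually
demonstrated on: a guideline with classified recommendations (including
the DEXA bone-density observation), a simplified breast-carcinoma pathway
(inclusion diagnosis "malignant neoplasm of lower-inner quadrant of
breast", a preoperative-day phase, the patient's admission encounter), a
DOC.Path-like target-system profile, the component mapping (diagnosis has
one counterpart, treatment phase two, medication one, parameter
information three) and a default choice configuration.

A randomized generator for valid pathway documents is included for
property tests (round-trip identity, instance-model counts).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import hl7_io
from .derivation import (
    AttributeSchemaSet,
    FormalizationResult,
    IdAllocator,
    MarkupRecord,
    PhasePlan,
    PhaseSpec,
    add_local_activity,
    classify_recommendation,
    compose,
    formalize,
    formalize_parameter,
)
from .deployment import ChoiceConfig, TemplateSet
from .metamodel import (
    Activity,
    ActivityKind,
    ClinicalPathway,
    CodedConcept,
    ControlFlowEdge,
    EpisodeOfCare,
    Guideline,
    ModelRepository,
    Parameter,
    ParameterCategory,
    PathwaySystem,
    Recommendation,
    RecommendationKind,
    TimeSpec,
    TreatmentPhase,
)
from .ontology import ComponentMapping, MappingEntry, TargetSystemProfile, metamodel_ontology

__all__ = ["FixtureBundle", "breast_carcinoma_bundle", "docpath_profile",
           "docpath_mapping", "generate_fixtures", "random_document"]


@dataclass
class FixtureBundle:
    repository: ModelRepository
    guideline: Guideline
    recommendations: dict[str, Recommendation]
    schemas: AttributeSchemaSet
    markup: list[MarkupRecord]
    values: dict[str, dict[str, str]]  # recommendation id -> form values
    toy_pathway: ClinicalPathway
    full_pathway: ClinicalPathway
    toy_plan: PhasePlan
    full_plan: PhasePlan
    profile: TargetSystemProfile
    mapping: ComponentMapping
    choices: ChoiceConfig
    drafts: list[FormalizationResult] = field(default_factory=list)


def docpath_profile() -> TargetSystemProfile:
    """The DOC.Path-like reference target: calendric view plus dimensions."""
    p = TargetSystemProfile("docpath")
    p.declare("docpath:InclusionDiagnosis", "Inclusion diagnosis entry", "calendric-view")
    p.declare("docpath:PhaseDimension", "Dimension: phase", "calendric-view", "dimension")
    p.declare("docpath:OptionalElement", "Optional element")
    p.declare("docpath:Prescription", "Prescription", "dimension")
    p.declare("docpath:Order", "Order", "dimension")
    p.declare("docpath:AdmissionEntry", "Admission entry", "dimension")
    p.declare("docpath:InformationDimension", "Dimension: information", "dimension")
    p.declare("docpath:TextualDescription", "Textual description")
    p.declare("docpath:DocumentLink", "Document or URL attachment")
    return p


def docpath_mapping() -> ComponentMapping:
    """Component mapping meta-model -> DOC.Path.

    Diagnosis, medication, observation, procedure and encounter map
    uniquely (the encounter mapping is a fixture decision, not reference
    ground truth); the treatment phase has two alternatives and parameter
    information three, all passive.
    """
    return ComponentMapping([
        MappingEntry("meta:InclusionDiagnosis", "docpath:InclusionDiagnosis", "active"),
        MappingEntry("meta:TreatmentPhase", "docpath:PhaseDimension", "active"),
        MappingEntry("meta:TreatmentPhase", "docpath:OptionalElement", "active"),
        MappingEntry("meta:Medication", "docpath:Prescription", "active"),
        MappingEntry("meta:Observation", "docpath:Order", "active",
                     "an observation leads to a concrete order"),
        MappingEntry("meta:Procedure", "docpath:Order", "active"),
        MappingEntry("meta:Encounter", "docpath:AdmissionEntry", "active",
                     "fixture decision: encounters map uniquely"),
        MappingEntry("meta:Parameter", "docpath:InformationDimension", "passive"),
        MappingEntry("meta:Parameter", "docpath:TextualDescription", "passive"),
        MappingEntry("meta:Parameter", "docpath:DocumentLink", "passive"),
    ])


_DEXA_TEXT = ("Patients with early invasive breast cancer should have a baseline "
              "dual energy X-ray absorptiometry (DEXA) scan to assess bone "
              "mineral density")


def breast_carcinoma_bundle() -> FixtureBundle:
    """Build the complete worked example in memory (deterministic)."""
    repo = ModelRepository()
    ids = IdAllocator()
    schemas = AttributeSchemaSet.default()

    guideline = repo.add_guideline(Guideline(
        id="gl-breast-ca",
        title="Interdisciplinary guideline for the diagnosis and treatment of breast cancer",
        version="2012", citation="national guideline programme, long version"))

    markup = [
        MarkupRecord(guideline_id=guideline.id, excerpt=_DEXA_TEXT,
                     kind=RecommendationKind.observation, annotator="path-team",
                     evidence_grade="1+", recommendation_grade="A"),
        MarkupRecord(guideline_id=guideline.id,
                     excerpt=("Patients with unifocal early-stage tumours should be "
                              "offered breast-conserving surgery (partial mastectomy)."),
                     kind=RecommendationKind.procedure, annotator="path-team",
                     evidence_grade="1++", recommendation_grade="A"),
        MarkupRecord(guideline_id=guideline.id,
                     excerpt=("Postmenopausal patients with hormone-receptor-positive "
                              "tumours should receive adjuvant endocrine therapy "
                              "with tamoxifen."),
                     kind=RecommendationKind.medication, annotator="path-team",
                     evidence_grade="1+", recommendation_grade="A"),
        MarkupRecord(guideline_id=guideline.id,
                     excerpt="Risk factor: obesity increases the risk of recurrence.",
                     kind=RecommendationKind.additional_information,
                     annotator="path-team"),
    ]
    recs = {r.kind.value: classify_recommendation(r, repo, ids) for r in markup}

    values = {
        recs["observation"].id: {
            "name": "dual energy X-ray absorptiometry",
            "target": "bone mineral density", "method": "DEXA scan"},
        recs["procedure"].id: {
            "name": "partial mastectomy", "ops_code": "5-870"},
        recs["medication"].id: {
            "name": "tamoxifen", "substance": "tamoxifen",
            "dosage": "20 mg daily", "route": "oral"},
    }

    dexa = formalize(recs["observation"], values[recs["observation"].id], schemas, ids)
    surgery = formalize(recs["procedure"], values[recs["procedure"].id], schemas, ids)
    tamoxifen = formalize(recs["medication"], values[recs["medication"].id], schemas, ids)
    admission = add_local_activity(
        ActivityKind.encounter,
        {"name": "patient admission", "encounter_type": "admission"}, schemas, ids)
    # a nursing activity stays a draft: it has no OPS code yet
    wound_care = add_local_activity(
        ActivityKind.procedure, {"name": "wound dressing change"}, schemas, ids)

    diagnosis = CodedConcept(system="ICD-10", value="C50.3",
                             display="malignant neoplasm of lower-inner quadrant of breast")

    # --- simplified (toy) pathway: diagnosis + one phase + admission -------
    toy_admission = add_local_activity(
        ActivityKind.encounter,
        {"name": "patient admission", "encounter_type": "admission"}, schemas, ids)
    toy_plan = PhasePlan(phases=[PhaseSpec(
        id="ph-preop", name="preoperative day", anchor_offset=0, duration="P1D",
        activity_ids=[toy_admission.activity.id])])
    toy = compose([toy_admission], toy_plan,
                  pathway_id="pw-breast-toy",
                  name="Breast carcinoma pathway (simplified)",
                  inclusion_diagnoses=[diagnosis],
                  repository=repo)
    repo.add_pathway(toy)

    # --- full pathway: three phases, evidence-linked activities -----------
    risk = formalize_parameter(recs["additional_information"],
                               ParameterCategory.risk_factor,
                               scope="pw-breast-full", ids=ids)
    full_plan = PhasePlan(
        phases=[
            PhaseSpec(id="ph-full-preop", name="preoperative day", anchor_offset=0,
                      duration="P1D",
                      activity_ids=[admission.activity.id, dexa.activity.id],
                      edges=[ControlFlowEdge(from_activity=admission.activity.id,
                                             to_activity=dexa.activity.id)]),
            PhaseSpec(id="ph-full-op", name="day of surgery", anchor_offset=1,
                      duration="P1D", activity_ids=[surgery.activity.id]),
            PhaseSpec(id="ph-full-postop", name="postoperative day", anchor_offset=2,
                      duration="P1D", activity_ids=[tamoxifen.activity.id]),
        ],
        responsibilities={dexa.activity.id: "radiology",
                          surgery.activity.id: "senology"},
        times={dexa.activity.id: TimeSpec(offset="PT8H", duration="PT1H")},
        costs={surgery.activity.id: "2450.00"},
    )
    full = compose([admission, dexa, surgery, tamoxifen], full_plan,
                   pathway_id="pw-breast-full",
                   name="Breast carcinoma pathway",
                   inclusion_diagnoses=[diagnosis],
                   episode_id="ep-acute",
                   parameters=[risk],
                   repository=repo)
    repo.add_pathway(full)
    repo.add_system(PathwaySystem(id="sys-breast", episodes=[
        EpisodeOfCare(id="ep-acute", name="therapeutics",
                      pathway_ids=["pw-breast-full", "pw-breast-toy"]),
        EpisodeOfCare(id="ep-followup", name="follow-up"),
    ]))

    choices = ChoiceConfig(user="fixture-default", selections={
        "meta:TreatmentPhase": "docpath:PhaseDimension",
        "meta:Parameter": "docpath:InformationDimension",
    })

    return FixtureBundle(
        repository=repo, guideline=guideline,
        recommendations={r.id: r for r in repo.recommendations.values()},
        schemas=schemas, markup=markup, values=values,
        toy_pathway=toy, full_pathway=full,
        toy_plan=toy_plan, full_plan=full_plan,
        profile=docpath_profile(), mapping=docpath_mapping(),
        choices=choices, drafts=[wound_care])


def generate_fixtures(seed: int, destination: str | Path) -> FixtureBundle:
    """Write the fixture bundle to disk in the toolkit's file formats.

    Deterministic: the same seed yields byte-identical files.  (The worked
    example itself is fixed; the seed feeds only the file-format round-trip
    of the randomized sanity models and future randomized bundles.)
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    bundle = breast_carcinoma_bundle()

    lines = ["# guideline_id\tkind\tannotator\tevidence_grade\trecommendation_grade\texcerpt"]
    for m in bundle.markup:
        lines.append("\t".join([m.guideline_id, m.kind.value, m.annotator,
                                m.evidence_grade, m.recommendation_grade, m.excerpt]))
    (dest / "markup.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    (dest / "guideline.yaml").write_text(yaml.safe_dump({
        "id": bundle.guideline.id, "title": bundle.guideline.title,
        "version": bundle.guideline.version,
        "citation": bundle.guideline.citation}, sort_keys=True), encoding="utf-8")

    vdir = dest / "values"
    vdir.mkdir(exist_ok=True)
    for rec_id, vals in sorted(bundle.values.items()):
        (vdir / f"{rec_id}.yaml").write_text(
            yaml.safe_dump(vals, sort_keys=True), encoding="utf-8")

    for pw, stem in ((bundle.toy_pathway, "toy_pathway"),
                     (bundle.full_pathway, "full_pathway")):
        hl7_io.write_xml(pw, dest / f"{stem}.xml", repository=bundle.repository)
    for pw, plan, stem in ((bundle.toy_pathway, bundle.toy_plan, "toy_composition"),
                           (bundle.full_pathway, bundle.full_plan, "full_composition")):
        comp = {
            "pathway_id": pw.id,
            "name": pw.name,
            "episode_id": pw.episode_id,
            "inclusion_diagnoses": [d.model_dump(mode="json")
                                    for d in pw.inclusion_diagnoses],
            "parameters": [p.model_dump(mode="json") for p in pw.parameters],
            "phase_plan": plan.model_dump(mode="json"),
        }
        (dest / f"{stem}.yaml").write_text(
            yaml.safe_dump(comp, sort_keys=True), encoding="utf-8")

    metamodel_ontology().to_json(dest / "metamodel_ontology.json")
    bundle.profile.to_json(dest / "docpath_profile.json")
    bundle.mapping.to_json(dest / "docpath_mapping.json")
    bundle.choices.to_yaml(dest / "choices.yaml")
    TemplateSet.default()  # ensure the packaged template set is loadable

    # seed-derived sanity models exercising the full XML vocabulary
    rng = random.Random(seed)
    doc = random_document(rng, index=0)
    hl7_io.write_xml(doc, dest / "random_models.xml")
    return bundle


# ---------------------------------------------------------------------------
# randomized valid models (for property tests)

_WORDS = ["anamnesis", "staging", "sonography", "consultation", "biopsy",
          "mobilisation", "laboratory", "mammography", "histology", "drainage"]
_ROLES = ["nursing", "radiology", "surgery", "internal medicine", "physiotherapy"]


def _random_activity(rng: random.Random, ids: IdAllocator,
                     recs_by_kind: dict[str, list[Recommendation]]) -> Activity:
    kind = rng.choice(list(ActivityKind))
    name = f"{rng.choice(_WORDS)} {rng.randrange(100)}"
    attrs: dict[str, str] = {}
    if kind is ActivityKind.procedure:
        attrs["ops_code"] = f"5-{rng.randrange(100, 999)}"
    elif kind is ActivityKind.medication:
        attrs.update(substance=rng.choice(_WORDS),
                     dosage=f"{rng.randrange(1, 50)} mg", route="oral")
    elif kind is ActivityKind.encounter:
        attrs["encounter_type"] = rng.choice(["admission", "discharge", "transfer"])
    else:
        attrs["target"] = rng.choice(_WORDS)
    evidence = None
    if recs_by_kind.get(kind.value) and rng.random() < 0.5:
        evidence = rng.choice(recs_by_kind[kind.value]).id
    code = None
    if "ops_code" in attrs:
        code = CodedConcept(system="OPS", value=attrs["ops_code"], display=name)
    return Activity(
        id=ids.next("ract"), kind=kind, name=name, code=code,
        responsibility=rng.choice(_ROLES) if rng.random() < 0.5 else "",
        resources=[rng.choice(_WORDS)] if rng.random() < 0.3 else [],
        time=TimeSpec(offset=f"PT{rng.randrange(12)}H", duration=f"PT{rng.randrange(1, 4)}H")
        if rng.random() < 0.5 else None,
        evidence_link=evidence, local_origin=evidence is None,
        attributes=attrs)


def random_document(rng: random.Random, index: int = 0) -> hl7_io.PathwayDocument:
    """One random, valid pathway document exercising the whole vocabulary."""
    ids = IdAllocator(start=1 + index * 1000)
    guideline = Guideline(id=ids.next("rgl"), title=f"random guideline {index}",
                          version=str(rng.randrange(2005, 2020)))
    recs = []
    recs_by_kind: dict[str, list[Recommendation]] = {}
    for _ in range(rng.randrange(1, 4)):
        kind = rng.choice([k for k in RecommendationKind
                           if k is not RecommendationKind.additional_information])
        r = Recommendation(id=ids.next("rrec"), guideline_id=guideline.id,
                           text=f"{rng.choice(_WORDS)} should be performed",
                           kind=kind, evidence_grade=rng.choice(["1+", "2-", ""]))
        recs.append(r)
        recs_by_kind.setdefault(kind.value, []).append(r)

    pw_id = ids.next("rpw")
    phases = []
    for p in range(rng.randrange(1, 4)):
        acts = [_random_activity(rng, ids, recs_by_kind)
                for _ in range(rng.randrange(0, 4))]
        edges = []
        for i in range(len(acts)):
            for j in range(i + 1, len(acts)):  # forward edges only: a DAG by construction
                if rng.random() < 0.3:
                    rel = rng.choice(list("spc"))
                    edges.append(ControlFlowEdge(
                        from_activity=acts[i].id, to_activity=acts[j].id,
                        relation={"s": "sequence", "p": "parallel", "c": "conditional"}[rel],
                        guard="finding positive" if rel == "c" else ""))
        phases.append(TreatmentPhase(
            id=ids.next("rph"), name=f"day {p}", anchor_offset=p,
            duration="P1D", activities=acts, edges=edges))

    scope_pool = [pw_id] + [ph.id for ph in phases] + \
        [a.id for ph in phases for a in ph.activities]
    params = [Parameter(id=ids.next("rpar"), key=rng.choice(_WORDS),
                        value=f"{rng.choice(_WORDS)} noted",
                        category=rng.choice(list(ParameterCategory)),
                        scope=rng.choice(scope_pool))
              for _ in range(rng.randrange(0, 3))]

    linked_guidelines = sorted({r.guideline_id for r in recs
                                if any(a.evidence_link == r.id
                                       for ph in phases for a in ph.activities)})
    pathway = ClinicalPathway(
        id=pw_id, name=f"random pathway {index}",
        inclusion_diagnoses=[CodedConcept(system="ICD-10",
                                          value=f"C{rng.randrange(10, 99)}.{rng.randrange(10)}",
                                          display=f"{rng.choice(_WORDS)} neoplasm")
                             for _ in range(rng.randrange(1, 3))],
        episode_id=None, phases=phases,
        guideline_ids=linked_guidelines, parameters=params)

    systems = []
    if rng.random() < 0.4:
        systems.append(PathwaySystem(id=ids.next("rsys"), episodes=[
            EpisodeOfCare(id=ids.next("rep"), name="diagnostics",
                          pathway_ids=[pw_id]),
            EpisodeOfCare(id=ids.next("rep"), name="rehabilitation")]))

    return hl7_io.PathwayDocument(
        guidelines=[guideline], recommendations=recs,
        systems=systems, pathways=[pathway])
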