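# pathforge

Hospitals develop **clinical pathways** — institution-local, process-like
plans of care for a defined patient group — and are expected to ground
them in **clinical guidelines**, the narrative, evidence-graded statements
of best practice.  Bridging the two is hard: guidelines are prose,
pathways are executable process models, and every hospital information
system (HIS) represents pathways in its own formalism.

`pathforge` is a toolkit for clinical-informatics teams (pathway working
groups, medical controllers, HIS integrators) that covers this whole
lifecycle:

1. **Extraction** — pertinent guideline recommendations are marked up and
   classified by the interdisciplinary team (procedure, medication,
   encounter, observation, or additional information).  The toolkit
   records the classification; it never infers it.
2. **Formalization** — per activity kind, a configurable attribute schema
   (the "customized form") defines which descriptive fields are required
   (e.g. a procedure needs a name and an OPS code).  Values supplied by
   domain experts turn each excerpt into an HL7-style activity that keeps
   an `evidence_link` back to its recommendation.  Institution-local
   additions (nursing activities, the admission encounter) join without
   evidence links.
3. **Composition** — completed activities are assigned to treatment
   phases (e.g. *preoperative day*), sequenced with a control-flow DAG
   (sequence / parallel / conditional edges with guards) and enriched with
   responsibilities, resources, times and costs.  Flow-inert extras (risk
   factors, complications, guiding symptoms) live in a generic parameter
   system.
4. **Deployment** — the composed pathway is serialized to a
   care-plan-flavoured XML interchange format, converted to an ontological
   *instance model* (one typed node per element), merged with a
   target-system profile and a *component mapping* into a *reasoning
   model*, and queried: *which counterparts exist for this element in the
   target system?*  Elements with a unique counterpart translate
   automatically; elements with several alternatives are put to the user
   (choices are stored per user and replayable); the resolved plan is
   rendered into ready-to-use artifacts — a relational insert script
   (calendric view plus dimensions) or a target-dialect XML document.

The component mapping is a concept graph (set of subject–predicate–object
triples, exportable to RDF), not code: adding or adapting a target system
means editing a profile, a mapping and a template file.

## Worked example

The packaged fixture reproduces a simplified breast-carcinoma scenario: a
pathway with an inclusion diagnosis (*malignant neoplasm of lower-inner
quadrant of breast*, ICD-10 C50.3), a *preoperative day* phase and the
patient's admission encounter, deployed against a DOC.Path-like target
system that schedules elements in a calendric view and aggregates them in
dimensions.

```python
from pathforge.fixtures import breast_carcinoma_bundle
from pathforge.ontology import build_instance_model, merge_reasoning_model, query_counterparts
from pathforge.deployment import plan_deployment, resolve, render_relational

bundle = breast_carcinoma_bundle()
instance = build_instance_model(bundle.toy_pathway, bundle.repository)
model = merge_reasoning_model(instance, bundle.profile, bundle.mapping)

for node in instance.order:
    print(f"{node} ({instance.element_nodes[node]}):")
    for o in query_counterparts(model, node):
        print(f"    -> {o.label} [{o.target_concept}, {o.role}]")
```

prints

```text
inst:pw-breast-toy:dx0 (meta:InclusionDiagnosis):
    -> Inclusion diagnosis entry [docpath:InclusionDiagnosis, active]
inst:ph-preop (meta:TreatmentPhase):
    -> Dimension: phase [docpath:PhaseDimension, active]
    -> Optional element [docpath:OptionalElement, active]
inst:act-0006 (meta:Encounter):
    -> Admission entry [docpath:AdmissionEntry, active]
```

The inclusion diagnosis and the encounter have exactly one counterpart, so
their translation is automatic; the treatment phase offers two
alternatives and is put to the user.  Resolving the choice (here: place
the phase in the *phase* dimension) and rendering yields the insert
script; its diagnosis unit, for instance, is

```text
automatic: 2  pending: 1  unmapped: 0
INSERT INTO element (id, phase_day, dimension_id, kind, name, payload)
VALUES ('inst:pw-breast-toy:dx0', NULL, 'diagnosis', 'diagnosis',
        'malignant neoplasm of lower-inner quadrant of breast', 'ICD-10 C50.3');
```

The same pipeline is scriptable from the shell:

```bash
pathforge fixtures --seed 0 --dest bundle/
pathforge extract   --markup bundle/markup.tsv --guideline-file bundle/guideline.yaml --out kb.json
pathforge formalize --kb kb.json --values-dir bundle/values --out activities.json
pathforge compose   --activities activities.json --composition bundle/full_composition.yaml \
                    --kb kb.json --out pathway.xml
pathforge deploy    --pathway pathway.xml --profile bundle/docpath_profile.json \
                    --mapping bundle/docpath_mapping.json --choices bundle/choices.yaml \
                    --out-dir artifacts/
```

`deploy` writes `pathway_inserts.sql`, `pathway_target.xml` and a manifest
mapping every pathway element to its emitted unit.  Every run logs SHA-256
digests of its inputs and outputs, and errors surface as structured,
module-qualified reports with a non-zero exit.

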