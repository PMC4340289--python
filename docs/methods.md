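# Methods

## The meta-model

The toolkit's core is a meta-model that merges the information structures
of clinical guidelines and clinical pathways into one generic model.

* A **pathway system** describes the whole, intersectoral treatment of a
  disease as an ordered list of **episodes of care** (prevention,
  diagnostics, therapeutics, follow-up, rehabilitation; custom names are
  accepted because published episode lists vary).  An episode is
  "completely described" once at least one pathway realizes it; an empty
  episode is a validation warning, not an error.
* A **clinical pathway** carries inclusion diagnoses (coded concepts:
  coding system + code + display), an evident basis (the set of guidelines
  it implements) and an ordered list of **treatment phases**.
* A **phase** (e.g. *preoperative day*) anchors at a day offset from the
  pathway start, has an ISO-8601 duration, and owns **activities** in the
  four HL7 act styles — procedure, medication, encounter, observation —
  plus control-flow edges.
* **Control flow** is a per-pathway DAG over activities with three edge
  relations: `sequence`, `parallel`, and `conditional` (which requires a
  non-empty guard).  The underlying standard names a whole control suite
  of workflow attributes without enumerating it; this three-relation set
  is the minimal algebra that covers ordered execution, concurrency and
  branching, and it keeps acyclicity checkable in linear time.
* **Parameters** hold flow-inert additional information (risk factors,
  complications, guiding symptoms) scoped to a pathway, phase or activity.
  They can never participate in control flow by construction — they have
  no id-slot in an edge — so removing them provably never changes a
  control-flow verdict.
* **Provenance**: every activity may link to the guideline
  **recommendation** it implements (`evidence_link`); recommendations
  carry the verbatim excerpt, the human-assigned classification and
  evidence/recommendation grades.  Institution-local activities are
  flagged `local_origin` instead.

Validation is report-based (`validate_pathway` returns errors and
warnings, it never raises): reference closure over the whole object graph,
DAG-ness of the edge set (with a witness cycle on failure, found via
`networkx`), evidence-kind agreement, parameter-scope resolution, and —
when an attribute-schema set is supplied — kind-specific completeness.

## Derivation

Classification is a human decision the system records; there is no text
mining.  Formalization is driven by per-kind attribute schemas shipped as
configuration (`data/activity_attributes.yaml`), not code, because the
"customized forms" domain experts fill in are generated from exactly such
definitions and must be extensible without a release.  The shipped schema
is a reconstruction from the worked examples (procedure: name + OPS code;
medication: substance, dosage, route; observation: target; encounter:
encounter type); `name` is required for every kind.  Values outside the
schema are kept as extras with a warning — domain knowledge should never
be silently dropped.  Incomplete drafts persist (the workflow spans
sessions) but the composition step is a hard completeness gate: a pathway
can never contain an activity with missing required attributes, an
unassigned activity, or a control-flow cycle.  One recommendation
formalizes to one activity; calling `formalize` repeatedly covers
one-to-many cases.

Fresh identifiers come from a deterministic counter (`IdAllocator`), so
identical inputs give byte-identical serialized outputs.  Identifiers are
otherwise caller-supplied; the toolkit rejects duplicates and never
renames.

## XML interchange format

Pathways travel in a care-plan-flavoured XML vocabulary defined by this
repository (`data/pathway.xsd`).  The five extensions beyond a plain care
plan each have designated elements: guideline assignment (`guideline` /
`guidelineRef`), intersectoral structure (`pathwaySystem` /
`episodeOfCare`), evidence and cost (`evidenceRef`, grade attributes,
`cost`), the control suite (`edge`), and the parameter system
(`parameter`).  The vocabulary claims structural fidelity to the care-plan
idea, not normative HL7 v3 wire conformance — the underlying model is a
draft standard, and no reference serialization is published.

Determinism and round-trip identity are contracts: UTF-8, fixed element
order, attribute maps in sorted key order, recommendations canonicalized
into guideline order at document construction.  `read_xml(write_xml(d)) ==
d` for every valid document; writing refuses invalid pathways, reading
validates against the packaged schema and never returns partial models.

## Ontology-based deployment

"Reasoning" here is counterpart lookup over a merged concept graph; no
description-logic reasoner is involved because the deployment queries
(*which counterparts exist for this element?*) need nothing beyond typing
and edge traversal.  The internal triple store is a plain set of
`(subject, predicate, object, literal?)` statements with a documented
flat-JSON serialization; an RDF export (`ConceptGraph.to_rdflib`) is a
convenience for OWL tooling, not the internal format.

* The **instance model** has one typed node per pathway element
  (diagnoses, phases, activities, parameters) plus a separately held
  pathway node.  An element types to exactly one meta-model concept;
  concept hierarchies are expected to be flattened when a profile is
  authored.
* The **reasoning model** is the set union of instance, target profile,
  component mapping and the meta-model ontology — idempotent, monotone in
  mapping entries, and never mutated by queries.
* Counterpart options are ordered lexicographically by target-concept
  label so that choice indices are stable across runs.
* Elements are **active** (the target system must create an executable
  construct, e.g. an order for a lab test) unless *all* their options are
  passive (parameter content copied as pure data).

## Deployment planning and rendering

Elements with exactly one counterpart are translated automatically; with
two or more they are pending a user choice; with none they are unmapped
and block deployment (fail-closed; an explicit flag downgrades them to
logged omissions).  Choice configurations are per user; element-level
selections beat concept-level defaults, and an automatic assignment can
only be "overridden" by explicitly confirming it — any other selection is
an invalid choice.  Interactive runs record their answers, so every
interactive session replays strictly.

Rendering is template-driven: one text template per (representation
option, dialect), shipped as data (`data/docpath_templates.yaml`).  The
reference relational schema emulates a calendric path module —
`pathway`, `phase_day`, `dimension`, `element`, `attachment` — because the
reference target arranges elements in a calendar and aggregates equal
types in dimensions; its real table layout is not public, so this minimal
structure is the repository's own design.  Two invariants are enforced and
independently audited:

* **Conservation** — every resolved element yields exactly one emitted
  unit (an `element` row / XML node for active representations, an
  `attachment` row / node for passive ones), recorded in the manifest and
  re-counted by loading the script into an embedded SQLite database or
  parsing the XML.
* **Choice locality** — the scaffold (pathway row, phase-day rows, the
  full dimension set) is emitted unconditionally, so changing one
  element's choice changes only that element's unit.

## Synthetic data

Real guideline corpora cannot ship with the toolkit.  The fixture module
reconstructs the worked breast-carcinoma example from its published
description: four classified recommendations (the DEXA bone-density
observation, a breast-conserving-surgery procedure, adjuvant tamoxifen,
and an obesity risk factor), the simplified three-element pathway
(diagnosis, preoperative day, admission), a nine-element full pathway, the
DOC.Path-like profile, and the component mapping with the published
counterpart counts (diagnosis 1, phase 2, medication 1, parameter 3).
The encounter's unique mapping is a fixture decision — the reference
description does not state how encounters map.  A randomized generator
produces valid documents exercising the whole XML vocabulary (forward-only
edges guarantee DAG-ness by construction).  What the fixtures do **not**
emulate: the scale and ambiguity of real guidelines, free-text dosage
conventions, terminology-server code validation, or a real HIS endpoint —
passing tests show structural correctness of the machinery, not clinical
validity of any generated pathway.

## Numerical and procedural choices

* Durations are ISO-8601 day/time strings (`P1D`, `PT2H30M`); calendar
  months are rejected because phase-relative offsets need a fixed length.
  Phase anchors are integer day offsets from the pathway start.
* Cycle detection uses depth-first search; tests and the acceptance
  script compare its verdicts against exhaustive enumeration of all
  ordered node subsets on graphs of up to 8 nodes (the largest size where
  the brute-force oracle stays instant).
* Property sweeps use 50 randomized documents for round-trip identity and
  30 random graphs for acyclicity — sizes chosen to keep the whole suite
  in the low seconds while exercising every serialization branch.
* SQL string literals are escaped by quote doubling; XML template values
  are entity-escaped before substitution.

## Known limitations

* No patient-level enactment: the toolkit produces pathway *models*, not
  running care processes (no variance documentation or outcome
  surveillance).
* No terminology-server validation of OPS/ICD codes; codes are carried,
  not verified.
* The target-XML dialect and relational schema are reference designs; a
  real HIS integration would supply its own profile, mapping and template
  files.
* One recommendation maps to one activity per `formalize` call; composite
  recommendations must be marked up as several excerpts.
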