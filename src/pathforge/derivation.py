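"""Three-step derivation of a guideline-compliant pathway.

Step 1 — *extraction*: pertinent narrative recommendations are marked up
and classified by the interdisciplinary team (classification is a human
decision the toolkit records, never infers).

Step 2 — *formalization*: per activity kind, a configured attribute schema
defines which descriptive fields are required (the "customized form");
values supplied by the domain experts turn an excerpt into an HL7-style
activity.  Institution-local activities (e.g. nursing activities) are added
the same way without an evidence link.  Incomplete activities persist as
drafts but never reach a composed pathway.

Step 3 — *composition*: completed activities are assigned to treatment
phases, sequenced with control-flow edges, and enriched with
responsibilities, resources and quantified time information.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator  # noqa: F401

from .errors import (
    CompositionError,
    ConfigurationError,
    EnumerationError,
    KindMismatchError,
)
from .metamodel import (
    Activity,
    ActivityKind,
    ClinicalPathway,
    CodedConcept,
    ControlFlowEdge,
    ModelRepository,
    Parameter,
    ParameterCategory,
    Recommendation,
    RecommendationKind,
    TimeSpec,
    TreatmentPhase,
    validate_pathway,
)

__all__ = [
    "IdAllocator",
    "MarkupRecord",
    "AttributeSchema",
    "AttributeSchemaSet",
    "FormalizationResult",
    "PhaseSpec",
    "PhasePlan",
    "load_markup",
    "classify_recommendation",
    "schema_for",
    "formalize",
    "formalize_parameter",
    "add_local_activity",
    "compose",
]


class IdAllocator:
    """Deterministic fresh-id source: ``prefix-0001``, ``prefix-0002``, ...

    A caller-provided start value plays the role of a seed, so repeated runs
    over the same inputs mint identical identifiers.
    """

    def __init__(self, start: int = 1):
        self._counters: dict[str, int] = {}
        self._start = start

    def next(self, prefix: str) -> str:
        n = self._counters.get(prefix, self._start)
        self._counters[prefix] = n + 1
        return f"{prefix}-{n:04d}"


class MarkupRecord(BaseModel):
    """One marked-up guideline excerpt with its human-supplied classification."""

    model_config = ConfigDict(extra="forbid")

    guideline_id: str
    excerpt: str
    kind: RecommendationKind
    annotator: str = ""
    evidence_grade: str = ""
    recommendation_grade: str = ""

    @field_validator("excerpt")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("excerpt must be non-empty")
        return v


def load_markup(path: str | Path) -> list[MarkupRecord]:
    """Read a markup file: one tab-separated record per line.

    Columns: guideline_id, kind, annotator, evidence_grade,
    recommendation_grade, excerpt.  Blank lines and ``#`` comments are
    skipped.
    """
    records = []
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise EnumerationError(f"{path}:{ln}: expected 6 tab-separated fields")
        gid, kind, annotator, eg, rg, excerpt = parts
        try:
            rk = RecommendationKind(kind)
        except ValueError as exc:
            raise EnumerationError(f"{path}:{ln}: unknown kind {kind!r}") from exc
        records.append(MarkupRecord(
            guideline_id=gid, excerpt=excerpt, kind=rk, annotator=annotator,
            evidence_grade=eg, recommendation_grade=rg))
    return records


def classify_recommendation(
    record: MarkupRecord, repository: ModelRepository, ids: IdAllocator
) -> Recommendation:
    """Persist a marked-up excerpt as a classified Recommendation.

    The classification is echoed from the record; provenance to the owning
    guideline is stored so the evident basis of the pathway is preserved.
    """
    if not record.excerpt.strip():
        raise EnumerationError("recommendation excerpt must be non-empty")
    rec = Recommendation(
        id=ids.next("rec"),
        guideline_id=record.guideline_id,
        text=record.excerpt,
        kind=record.kind,
        evidence_grade=record.evidence_grade,
        recommendation_grade=record.recommendation_grade,
    )
    return repository.add_recommendation(rec)


# ---------------------------------------------------------------------------
# attribute schemas (step 2 configuration)

class AttributeSchema(BaseModel):
    """Required/optional descriptive attributes for one activity kind."""

    model_config = ConfigDict(extra="forbid")

    kind: ActivityKind
    required: list[str]
    optional: list[str] = []

    @model_validator(mode="after")
    def _check(self) -> "AttributeSchema":
        if set(self.required) & set(self.optional):
            raise ValueError("required and optional attribute sets must be disjoint")
        if "name" not in self.required:
            raise ValueError("'name' is always a required attribute")
        return self

    @property
    def all_attributes(self) -> set[str]:
        return set(self.required) | set(self.optional)


class AttributeSchemaSet(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schemas: dict[str, AttributeSchema]

    def get(self, kind: str) -> Optional[AttributeSchema]:
        return self.schemas.get(kind)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "AttributeSchemaSet":
        out = {}
        for kind, spec in data.items():
            out[kind] = AttributeSchema(
                kind=ActivityKind(kind),
                required=list(spec.get("required", [])),
                optional=list(spec.get("optional", [])),
            )
        return cls(schemas=out)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AttributeSchemaSet":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "AttributeSchemaSet":
        """The schema set shipped with the package (``data/activity_attributes.yaml``)."""
        text = resources.files("pathforge.data").joinpath(
            "activity_attributes.yaml").read_text(encoding="utf-8")
        return cls.from_mapping(yaml.safe_load(text))


def schema_for(kind: str | ActivityKind, schemas: AttributeSchemaSet) -> AttributeSchema:
    """Look up the configured attribute schema for an activity kind."""
    key = kind.value if isinstance(kind, ActivityKind) else kind
    schema = schemas.get(key)
    if schema is None:
        raise ConfigurationError(f"no attribute schema configured for kind {key!r}")
    return schema


# ---------------------------------------------------------------------------
# formalization (step 2)

class FormalizationResult(BaseModel):
    model_config = ConfigDict(extra="forbid")

    activity: Activity
    missing: list[str] = []
    extras: dict[str, str] = {}
    warnings: list[str] = []

    @property
    def complete(self) -> bool:
        return not self.missing


def _build_activity(
    kind: ActivityKind,
    values: Mapping[str, str],
    schema: AttributeSchema,
    ids: IdAllocator,
    evidence_link: Optional[str],
    local_origin: bool,
) -> FormalizationResult:
    values = {k: str(v) for k, v in values.items() if str(v).strip()}
    missing = sorted(r for r in schema.required if r not in values)
    extras = {k: v for k, v in sorted(values.items()) if k not in schema.all_attributes}
    warnings = [f"attribute {k!r} is not part of the {kind.value} schema; kept as extra"
                for k in extras]

    code = None
    if "ops_code" in values:
        code = CodedConcept(system="OPS", value=values["ops_code"],
                            display=values.get("name", values["ops_code"]))
    attributes = {k: v for k, v in sorted(values.items()) if k != "name"}
    activity = Activity(
        id=ids.next("act"),
        kind=kind,
        name=values.get("name", ""),
        code=code,
        evidence_link=evidence_link,
        local_origin=local_origin,
        attributes=attributes,
    )
    return FormalizationResult(activity=activity, missing=missing,
                               extras=extras, warnings=warnings)


def formalize(
    rec: Recommendation,
    values: Mapping[str, str],
    schemas: AttributeSchemaSet,
    ids: IdAllocator,
) -> FormalizationResult:
    """Turn a classified recommendation plus form values into an activity draft.

    The activity carries ``evidence_link = rec.id``; attributes required by
    the kind's schema but absent from ``values`` are listed in ``missing``
    (domain experts complement them later).  Values outside the schema are
    kept as extras with a warning, never rejected.
    """
    if rec.kind is RecommendationKind.additional_information:
        raise KindMismatchError(
            "additional_information recommendations become parameters, not activities")
    kind = ActivityKind(rec.kind.value)
    schema = schema_for(kind, schemas)
    return _build_activity(kind, values, schema, ids,
                           evidence_link=rec.id, local_origin=False)


def add_local_activity(
    kind: str | ActivityKind,
    values: Mapping[str, str],
    schemas: AttributeSchemaSet,
    ids: IdAllocator,
) -> FormalizationResult:
    """Add an institution-local activity (e.g. a nursing activity).

    Same contract as :func:`formalize` but without guideline evidence:
    ``evidence_link`` stays unset and ``local_origin`` is flagged.
    """
    try:
        ak = ActivityKind(kind) if not isinstance(kind, ActivityKind) else kind
    except ValueError as exc:
        raise EnumerationError(f"unknown activity kind {kind!r}") from exc
    schema = schema_for(ak, schemas)
    return _build_activity(ak, values, schema, ids, evidence_link=None, local_origin=True)


def formalize_parameter(
    rec: Recommendation,
    category: ParameterCategory | str,
    scope: str,
    ids: IdAllocator,
    key: str = "",
) -> Parameter:
    """Turn an additional-information recommendation into a parameter record.

    Parameters carry the excerpt verbatim and are attached to a pathway,
    phase or activity scope; they never participate in control flow.
    """
    if rec.kind is not RecommendationKind.additional_information:
        raise KindMismatchError(
            f"recommendation {rec.id!r} has activity kind {rec.kind.value}; "
            "use formalize() instead")
    cat = ParameterCategory(category) if not isinstance(category, ParameterCategory) else category
    return Parameter(
        id=ids.next("param"),
        key=key or cat.value,
        value=rec.text,
        category=cat,
        scope=scope,
    )


# ---------------------------------------------------------------------------
# composition (step 3)

class PhaseSpec(BaseModel):
    """Definition of one treatment phase and the activities assigned to it."""

    model_config = ConfigDict(extra="forbid")

    id: str
    name: str
    anchor_offset: int = 0
    duration: str = "P1D"
    activity_ids: list[str] = []
    edges: list[ControlFlowEdge] = []


class PhasePlan(BaseModel):
    """Explicit phase assignment plus per-activity overrides for step 3."""

    model_config = ConfigDict(extra="forbid")

    phases: list[PhaseSpec]
    responsibilities: dict[str, str] = {}
    resources: dict[str, list[str]] = {}
    times: dict[str, TimeSpec] = {}
    costs: dict[str, str] = {}  # activity id -> decimal amount (EUR)


def compose(
    results: Sequence[FormalizationResult],
    phase_plan: PhasePlan,
    *,
    pathway_id: str,
    name: str,
    inclusion_diagnoses: Sequence[CodedConcept] = (),
    episode_id: Optional[str] = None,
    parameters: Sequence[Parameter] = (),
    repository: Optional[ModelRepository] = None,
) -> ClinicalPathway:
    """Compose a guideline-compliant pathway from completed activities.

    Rejects incomplete activities (listing their missing attributes),
    unassigned or doubly-assigned activities, and cyclic control flow.  The
    pathway's guideline set is the union of guidelines reachable through the
    activities' evidence links.
    """
    incomplete = {r.activity.id: r.missing for r in results if not r.complete}
    if incomplete:
        raise CompositionError(
            "incomplete activities cannot be composed: "
            + "; ".join(f"{aid} missing {', '.join(m)}" for aid, m in sorted(incomplete.items())),
            details=incomplete,
        )

    by_id = {r.activity.id: r.activity for r in results}
    assigned: dict[str, str] = {}
    for ph in phase_plan.phases:
        for aid in ph.activity_ids:
            if aid not in by_id:
                raise CompositionError(f"phase {ph.id!r} assigns unknown activity {aid!r}")
            if aid in assigned:
                raise CompositionError(
                    f"activity {aid!r} assigned to both {assigned[aid]!r} and {ph.id!r}")
            assigned[aid] = ph.id
    unassigned = sorted(set(by_id) - set(assigned))
    if unassigned:
        raise CompositionError(f"activities not assigned to any phase: {', '.join(unassigned)}")

    from .metamodel import _find_cycle  # shared cycle detector

    all_edges = [e for ph in phase_plan.phases for e in ph.edges]
    cycle = _find_cycle(list(by_id), all_edges)
    if cycle is not None:
        raise CompositionError(
            f"control flow contains a cycle: {' -> '.join(cycle)}", details=cycle)

    phases = []
    for ph in phase_plan.phases:
        acts = []
        for aid in ph.activity_ids:
            act = by_id[aid].model_copy(deep=True)
            if aid in phase_plan.responsibilities:
                act.responsibility = phase_plan.responsibilities[aid]
            if aid in phase_plan.resources:
                act.resources = list(phase_plan.resources[aid])
            if aid in phase_plan.times:
                act.time = phase_plan.times[aid]
            if aid in phase_plan.costs:
                from .metamodel import Cost
                act.cost = Cost(amount=phase_plan.costs[aid])
            acts.append(act)
        phases.append(TreatmentPhase(
            id=ph.id, name=ph.name, anchor_offset=ph.anchor_offset,
            duration=ph.duration, activities=acts, edges=list(ph.edges)))

    guideline_ids: set[str] = set()
    if repository is not None:
        for act in by_id.values():
            if act.evidence_link:
                rec = repository.recommendations.get(act.evidence_link)
                if rec is None:
                    raise CompositionError(
                        f"activity {act.id!r} links to unknown recommendation "
                        f"{act.evidence_link!r}")
                guideline_ids.add(rec.guideline_id)

    pathway = ClinicalPathway(
        id=pathway_id, name=name,
        inclusion_diagnoses=list(inclusion_diagnoses),
        episode_id=episode_id, phases=phases,
        guideline_ids=sorted(guideline_ids),
        parameters=list(parameters),
    )
    report = validate_pathway(pathway, repository)
    if not report.ok:
        raise CompositionError("composed pathway failed validation:\n" + report.summary(),
                               details=[i.model_dump() for i in report.errors])
    return pathway
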