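"""Meta-model for guideline-compliant, intersectoral clinical pathways.

The model merges the two knowledge structures used in hospital quality
management: clinical *guidelines* (narrative, evidence-graded
recommendations) and clinical *pathways* (institution-local care process
plans).  A pathway system covers the whole treatment as episodes of care
(prevention, diagnostics, therapeutics, follow-up, rehabilitation); each
episode is realized by clinical pathways; a pathway is divided into
treatment phases (e.g. a preoperative day) holding HL7-style activities
(procedure, medication, encounter, observation) plus control flow.
Flow-inert additional information (risk factors, complications, guiding
symptoms) lives in a generic parameter system.

Every activity may carry an ``evidence_link`` back to the guideline
recommendation it implements; that link is the provenance that makes a
pathway *guideline-compliant*.
"""

from __future__ import annotations

import re
from decimal import Decimal
from enum import Enum
from typing import Iterable, Optional

import networkx as nx
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import DuplicateIdError, ReferenceResolutionError

__all__ = [
    "ActivityKind",
    "RecommendationKind",
    "ParameterCategory",
    "EdgeRelation",
    "CodedConcept",
    "TimeSpec",
    "Cost",
    "ControlFlowEdge",
    "Parameter",
    "Activity",
    "TreatmentPhase",
    "ClinicalPathway",
    "EpisodeOfCare",
    "PathwaySystem",
    "Recommendation",
    "Guideline",
    "ModelRepository",
    "Issue",
    "ValidationReport",
    "parse_duration_seconds",
    "validate_pathway",
    "validate_system",
    "check_acyclic",
]

# ---------------------------------------------------------------------------
# enumerations

class ActivityKind(str, Enum):
    procedure = "procedure"
    medication = "medication"
    encounter = "encounter"
    observation = "observation"


class RecommendationKind(str, Enum):
    procedure = "procedure"
    medication = "medication"
    encounter = "encounter"
    observation = "observation"
    additional_information = "additional_information"


class ParameterCategory(str, Enum):
    risk_factor = "risk_factor"
    complication = "complication"
    guiding_symptom = "guiding_symptom"
    other = "other"


class EdgeRelation(str, Enum):
    sequence = "sequence"
    parallel = "parallel"
    conditional = "conditional"


#: canonical episode names; anything else is accepted as a custom episode
STANDARD_EPISODES = (
    "prevention",
    "diagnostics",
    "therapeutics",
    "follow-up",
    "rehabilitation",
)

# ---------------------------------------------------------------------------
# ISO-8601 durations (day/time designators only; calendar months are not
# meaningful for phase-relative offsets)

_DURATION_RE = re.compile(
    r"^P(?:(?P<d>\d+)D)?(?:T(?:(?P<h>\d+)H)?(?:(?P<m>\d+)M)?(?:(?P<s>\d+)S)?)?$"
)


def parse_duration_seconds(text: str) -> int:
    """Parse a non-negative ISO-8601 duration (``P1D``, ``PT2H30M``) to seconds."""
    m = _DURATION_RE.match(text)
    if not m or text in ("P", "PT"):
        raise ValueError(f"not an ISO-8601 day/time duration: {text!r}")
    d, h, mi, s = (int(m.group(g) or 0) for g in ("d", "h", "m", "s"))
    return ((d * 24 + h) * 60 + mi) * 60 + s


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


# ---------------------------------------------------------------------------
# leaf types

class CodedConcept(_Base):
    """A coded clinical concept: coding system (e.g. OPS, ICD-10), code, display.

    Display-only concepts (no system/value) are allowed; a system without a
    value, or vice versa, is not.
    """

    system: str = ""
    value: str = ""
    display: str

    @model_validator(mode="after")
    def _check(self) -> "CodedConcept":
        if not self.display.strip():
            raise ValueError("display must be non-empty")
        if bool(self.system) != bool(self.value):
            raise ValueError("system and value must both be set or both empty")
        return self


class TimeSpec(_Base):
    """Quantified execution time: offset from the phase anchor plus duration."""

    offset: str = "PT0S"
    duration: str = "PT0S"

    @field_validator("offset", "duration")
    @classmethod
    def _iso(cls, v: str) -> str:
        parse_duration_seconds(v)
        return v


class Cost(_Base):
    amount: Decimal
    currency: str = "EUR"

    @field_validator("amount")
    @classmethod
    def _nonneg(cls, v: Decimal) -> Decimal:
        if v < 0:
            raise ValueError("cost must be non-negative")
        return v


class ControlFlowEdge(_Base):
    """Directed workflow dependency between two activities.

    The relation set (sequence / parallel / conditional with a guard) is the
    minimal control suite needed to express a detailed, enactable flow.
    """

    from_activity: str
    to_activity: str
    relation: EdgeRelation = EdgeRelation.sequence
    guard: str = ""

    @model_validator(mode="after")
    def _check(self) -> "ControlFlowEdge":
        if self.from_activity == self.to_activity:
            raise ValueError("edge endpoints must be distinct")
        if self.relation is EdgeRelation.conditional and not self.guard.strip():
            raise ValueError("conditional edges require a non-empty guard")
        if self.relation is not EdgeRelation.conditional and self.guard:
            raise ValueError("guard is only allowed on conditional edges")
        return self


class Parameter(_Base):
    """Flow-inert additional information displayed on demand in target systems."""

    id: str
    key: str
    value: str
    category: ParameterCategory = ParameterCategory.other
    scope: str  # id of the pathway, phase or activity it annotates


class Activity(_Base):
    """One unit of patient treatment in HL7 act style.

    ``attributes`` holds the kind-specific descriptive fields (medication:
    substance/dosage/route, observation: method/target, encounter:
    encounter_type, ...) whose required/optional split is configuration, not
    code.  ``local_origin`` marks institution-local additions (e.g. nursing
    activities) that have no guideline evidence link by design.
    """

    id: str
    kind: ActivityKind
    name: str
    code: Optional[CodedConcept] = None
    responsibility: str = ""
    resources: list[str] = []
    time: Optional[TimeSpec] = None
    evidence_link: Optional[str] = None
    cost: Optional[Cost] = None
    local_origin: bool = False
    attributes: dict[str, str] = {}


class TreatmentPhase(_Base):
    """Time-bounded subdivision of a pathway, owning activities and edges."""

    id: str
    name: str
    anchor_offset: int = 0  # days relative to pathway start
    duration: str = "P1D"
    activities: list[Activity] = []
    edges: list[ControlFlowEdge] = []

    @field_validator("duration")
    @classmethod
    def _iso(cls, v: str) -> str:
        parse_duration_seconds(v)
        return v

    @property
    def activity_ids(self) -> list[str]:
        return [a.id for a in self.activities]


class ClinicalPathway(_Base):
    id: str
    name: str
    inclusion_diagnoses: list[CodedConcept] = []
    episode_id: Optional[str] = None
    phases: list[TreatmentPhase] = []
    guideline_ids: list[str] = []
    parameters: list[Parameter] = []

    @field_validator("guideline_ids")
    @classmethod
    def _sorted_unique(cls, v: list[str]) -> list[str]:
        return sorted(set(v))

    # -- convenience accessors -------------------------------------------
    def iter_activities(self) -> Iterable[tuple[TreatmentPhase, Activity]]:
        for ph in self.phases:
            for act in ph.activities:
                yield ph, act

    def activity_index(self) -> dict[str, Activity]:
        return {a.id: a for _, a in self.iter_activities()}

    def all_edges(self) -> list[ControlFlowEdge]:
        return [e for ph in self.phases for e in ph.edges]


class EpisodeOfCare(_Base):
    id: str
    name: str  # one of STANDARD_EPISODES or a custom name
    pathway_ids: list[str] = []

    @field_validator("pathway_ids")
    @classmethod
    def _sorted_unique(cls, v: list[str]) -> list[str]:
        return sorted(set(v))


class PathwaySystem(_Base):
    """Intersectoral view: the whole treatment as an ordered list of episodes."""

    id: str
    episodes: list[EpisodeOfCare] = []

    @field_validator("episodes")
    @classmethod
    def _unique_names(cls, v: list[EpisodeOfCare]) -> list[EpisodeOfCare]:
        names = [e.name for e in v]
        if len(names) != len(set(names)):
            raise ValueError("episode names must be unique within a system")
        return v


class Recommendation(_Base):
    """A classified narrative guideline excerpt with its evidence grades."""

    id: str
    guideline_id: str
    text: str
    kind: RecommendationKind
    evidence_grade: str = ""
    recommendation_grade: str = ""

    @field_validator("text")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("recommendation text must be non-empty")
        return v


class Guideline(_Base):
    id: str
    title: str
    version: str = ""
    citation: str = ""
    recommendations: list[str] = []


# ---------------------------------------------------------------------------
# repository

class ModelRepository:
    """In-memory store for guidelines, recommendations, pathways and systems.

    Identifiers are caller-supplied; the repository rejects duplicates and
    never renames.
    """

    def __init__(self) -> None:
        self.guidelines: dict[str, Guideline] = {}
        self.recommendations: dict[str, Recommendation] = {}
        self.pathways: dict[str, ClinicalPathway] = {}
        self.systems: dict[str, PathwaySystem] = {}

    def _add(self, store: dict, record, label: str):
        if record.id in store:
            raise DuplicateIdError(f"duplicate {label} id {record.id!r}")
        store[record.id] = record
        return record

    def add_guideline(self, g: Guideline) -> Guideline:
        return self._add(self.guidelines, g, "guideline")

    def add_recommendation(self, r: Recommendation) -> Recommendation:
        if r.guideline_id not in self.guidelines:
            raise ReferenceResolutionError(
                f"recommendation {r.id!r} references unknown guideline {r.guideline_id!r}"
            )
        self._add(self.recommendations, r, "recommendation")
        g = self.guidelines[r.guideline_id]
        if r.id not in g.recommendations:
            g.recommendations.append(r.id)
        return r

    def add_pathway(self, p: ClinicalPathway) -> ClinicalPathway:
        return self._add(self.pathways, p, "pathway")

    def add_system(self, s: PathwaySystem) -> PathwaySystem:
        return self._add(self.systems, s, "system")


# ---------------------------------------------------------------------------
# validation

class Issue(_Base):
    code: str
    element: str
    message: str


class ValidationReport(_Base):
    errors: list[Issue] = []
    warnings: list[Issue] = []

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        lines = [f"ERROR   {i.code} [{i.element}] {i.message}" for i in self.errors]
        lines += [f"WARNING {i.code} [{i.element}] {i.message}" for i in self.warnings]
        return "\n".join(lines) or "ok"


def _find_cycle(node_ids: list[str], edges: Iterable[ControlFlowEdge]):
    """Return one witness cycle as a node list, or None if the graph is a DAG."""
    g = nx.DiGraph()
    g.add_nodes_from(node_ids)
    g.add_edges_from((e.from_activity, e.to_activity) for e in edges)
    try:
        cyc = nx.find_cycle(g, orientation="original")
    except nx.NetworkXNoCycle:
        return None
    return [u for u, _, _ in cyc]


def check_acyclic(phase: TreatmentPhase) -> tuple[bool, Optional[list[str]]]:
    """Verdict on the phase's control-flow graph; on failure return a witness cycle.

    Raises :class:`ReferenceResolutionError` if an edge endpoint is not an
    activity of the phase.
    """
    known = set(phase.activity_ids)
    for e in phase.edges:
        for end in (e.from_activity, e.to_activity):
            if end not in known:
                raise ReferenceResolutionError(
                    f"edge endpoint {end!r} is not an activity of phase {phase.id!r}"
                )
    cycle = _find_cycle(phase.activity_ids, phase.edges)
    return (cycle is None), cycle


def validate_pathway(
    pathway: ClinicalPathway,
    repository: Optional[ModelRepository] = None,
    schemas=None,
) -> ValidationReport:
    """Structural validation of a pathway against the meta-model rules.

    Problems are reported, never raised.  Cross-record references
    (guidelines, evidence links) are checked only when a repository is
    given.  When an attribute-schema set is supplied, kind-specific required
    attributes are additionally enforced for every activity.
    """
    errors: list[Issue] = []
    warnings: list[Issue] = []

    def err(code, element, message):
        errors.append(Issue(code=code, element=element, message=message))

    def warn(code, element, message):
        warnings.append(Issue(code=code, element=element, message=message))

    if not pathway.phases:
        err("no-phases", pathway.id, "a deployable pathway needs at least one phase")

    phase_ids = [p.id for p in pathway.phases]
    if len(phase_ids) != len(set(phase_ids)):
        err("duplicate-phase-id", pathway.id, "phase ids must be unique")

    acts = {}
    for ph in pathway.phases:
        for a in ph.activities:
            if a.id in acts:
                err("duplicate-activity-id", a.id, "activity id reused within pathway")
            acts[a.id] = (ph, a)

    # control flow: endpoints must resolve within this pathway; graph acyclic
    for ph in pathway.phases:
        for e in ph.edges:
            for end in (e.from_activity, e.to_activity):
                if end not in acts:
                    err(
                        "unresolved-edge-endpoint",
                        f"{ph.id}:{e.from_activity}->{e.to_activity}",
                        f"edge endpoint {end!r} is not an activity of this pathway",
                    )
    if not any(i.code == "unresolved-edge-endpoint" for i in errors):
        cycle = _find_cycle(list(acts), pathway.all_edges())
        if cycle is not None:
            err("cycle", "->".join(cycle), "control-flow edges must form a DAG")

    # provenance
    for ph, a in pathway.iter_activities():
        if a.evidence_link is not None:
            if repository is not None:
                rec = repository.recommendations.get(a.evidence_link)
                if rec is None:
                    err("unresolved-evidence", a.id,
                        f"evidence link {a.evidence_link!r} does not resolve")
                elif rec.kind.value != a.kind.value:
                    err("evidence-kind-mismatch", a.id,
                        f"recommendation kind {rec.kind.value} != activity kind {a.kind.value}")
        elif not a.local_origin:
            warn("no-provenance", a.id,
                 "activity has neither an evidence link nor a local-origin flag")
        if schemas is not None:
            schema = schemas.get(a.kind.value)
            if schema is not None:
                supplied = set(a.attributes) | {"name"} if a.name else set(a.attributes)
                missing = [r for r in schema.required if r not in supplied]
                if a.code is not None and "ops_code" in missing:
                    missing.remove("ops_code")
                if missing:
                    err("missing-attributes", a.id,
                        f"required attributes missing: {', '.join(sorted(missing))}")

    if repository is not None:
        for gid in pathway.guideline_ids:
            if gid not in repository.guidelines:
                err("unresolved-guideline", pathway.id,
                    f"guideline id {gid!r} does not resolve")

    # parameter scopes resolve to the pathway, one of its phases or activities
    scope_ids = {pathway.id} | set(phase_ids) | set(acts)
    for p in pathway.parameters:
        if p.scope not in scope_ids:
            err("unresolved-parameter-scope", p.id,
                f"parameter scope {p.scope!r} does not resolve")

    return ValidationReport(errors=errors, warnings=warnings)


def validate_system(system: PathwaySystem, repository: ModelRepository) -> ValidationReport:
    """Validate an intersectoral pathway system; empty episodes are warnings."""
    errors: list[Issue] = []
    warnings: list[Issue] = []
    for ep in system.episodes:
        if not ep.pathway_ids:
            warnings.append(Issue(
                code="empty-episode", element=ep.id,
                message=f"episode {ep.name!r} is not completely described (no pathways)"))
        for pid in ep.pathway_ids:
            if pid not in repository.pathways:
                errors.append(Issue(
                    code="unresolved-pathway", element=ep.id,
                    message=f"pathway id {pid!r} does not resolve"))
    return ValidationReport(errors=errors, warnings=warnings)
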