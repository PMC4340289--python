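"""Ontological component mapping between the meta-model and target systems.

Deployment into a hospital information system starts from three concept
graphs — an *explicit formal specification of a shared conceptualisation*:

* the meta-model ontology (what a guideline-compliant pathway consists of),
* a target-system profile (which representation facilities the HIS offers),
* a component mapping relating the two (one meta-model concept may map to
  one *or several* equivalent target representations).

A concrete pathway is converted into an *instance model* (one typed node
per pathway element), and the union of instance, profile and mapping forms
the *reasoning model* that answers counterpart queries: "which target
representations exist for this element?".  The queries need nothing beyond
type lookup and edge traversal, so no description-logic reasoner is
involved; graphs can be exported to RDF for interoperability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .errors import MappingIntegrityError, QueryError, ValidationRefusedError
from .metamodel import (
    ActivityKind,
    ClinicalPathway,
    ModelRepository,
    validate_pathway,
)

__all__ = [
    "TYPE", "LABEL", "SOURCE_ELEMENT", "PART_OF", "MAPS_FROM", "MAPS_TO", "ROLE",
    "META_CONCEPTS",
    "Triple", "ConceptGraph", "metamodel_ontology",
    "TargetSystemProfile", "MappingEntry", "ComponentMapping",
    "InstanceModel", "ReasoningModel", "RepresentationOption",
    "build_instance_model", "merge_reasoning_model",
    "query_counterparts", "classify_active_passive", "ActivePassivePartition",
]

# predicate vocabulary
TYPE = "type"
LABEL = "label"
SOURCE_ELEMENT = "sourceElement"
PART_OF = "partOf"
MAPS_FROM = "mapsFrom"
MAPS_TO = "mapsTo"
ROLE = "role"
CAPABILITY = "capability"

#: meta-model concepts a pathway element can be typed by
META_PATHWAY = "meta:ClinicalPathway"
META_DIAGNOSIS = "meta:InclusionDiagnosis"
META_PHASE = "meta:TreatmentPhase"
META_PARAMETER = "meta:Parameter"
META_ACTIVITY = {
    ActivityKind.procedure: "meta:Procedure",
    ActivityKind.medication: "meta:Medication",
    ActivityKind.encounter: "meta:Encounter",
    ActivityKind.observation: "meta:Observation",
}
META_CONCEPTS = {
    META_PATHWAY: "Clinical pathway",
    META_DIAGNOSIS: "Inclusion diagnosis",
    META_PHASE: "Treatment phase",
    META_PARAMETER: "Parameter information",
    "meta:Procedure": "Procedure",
    "meta:Medication": "Medication",
    "meta:Encounter": "Encounter",
    "meta:Observation": "Observation",
}


def _read_json_source(source) -> object:
    """Accept a path or raw JSON text; file contents win for path-like input."""
    if isinstance(source, Path):
        return json.loads(source.read_text(encoding="utf-8"))
    text = str(source)
    if text.lstrip().startswith(("{", "[")):
        return json.loads(text)
    return json.loads(Path(text).read_text(encoding="utf-8"))


@dataclass(frozen=True, order=True)
class Triple:
    """One (subject, predicate, object) statement.

    Subjects and predicates are identifiers; the object is an identifier
    unless ``literal`` is set.
    """

    subject: str
    predicate: str
    object: str
    literal: bool = False


class ConceptGraph:
    """A set of triples with a namespace tag; duplicates collapse."""

    def __init__(self, namespace: str = "", triples: Iterable[Triple] = ()):
        self.namespace = namespace
        self.triples: set[Triple] = set(triples)

    def add(self, s: str, p: str, o: str, literal: bool = False) -> None:
        self.triples.add(Triple(s, p, o, literal))

    def objects(self, subject: str, predicate: str) -> list[str]:
        return sorted(t.object for t in self.triples
                      if t.subject == subject and t.predicate == predicate)

    def subjects(self, predicate: str, obj: str) -> list[str]:
        return sorted(t.subject for t in self.triples
                      if t.predicate == predicate and t.object == obj)

    def union(self, *others: "ConceptGraph", namespace: str = "") -> "ConceptGraph":
        out = ConceptGraph(namespace or self.namespace, self.triples)
        for g in others:
            out.triples |= g.triples
        return out

    def __len__(self) -> int:
        return len(self.triples)

    def __eq__(self, other) -> bool:
        return (isinstance(other, ConceptGraph)
                and self.namespace == other.namespace
                and self.triples == other.triples)

    # -- serialization ---------------------------------------------------
    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        data = {"namespace": self.namespace,
                "triples": [[t.subject, t.predicate, t.object, t.literal]
                            for t in sorted(self.triples)]}
        text = json.dumps(data, indent=1, ensure_ascii=False, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "ConceptGraph":
        data = _read_json_source(source)
        return cls(data.get("namespace", ""),
                   (Triple(s, pr, o, lit) for s, pr, o, lit in data["triples"]))

    def to_rdflib(self):
        """Export to an :mod:`rdflib` graph (convenience for OWL/RDF tooling)."""
        import rdflib

        g = rdflib.Graph()
        base = rdflib.Namespace("urn:pathforge:")

        def node(ident: str):
            return base[ident.replace(":", ".")]

        for t in sorted(self.triples):
            obj = rdflib.Literal(t.object) if t.literal else node(t.object)
            g.add((node(t.subject), node(t.predicate), obj))
        return g


def metamodel_ontology() -> ConceptGraph:
    """The ontological specification of the meta-model shipped with the toolkit."""
    g = ConceptGraph("meta")
    for concept, label in META_CONCEPTS.items():
        g.add(concept, TYPE, "MetamodelConcept")
        g.add(concept, LABEL, label, literal=True)
    return g


# ---------------------------------------------------------------------------
# target profiles and mappings

class TargetSystemProfile:
    """Concept graph describing one target system's representation facilities."""

    def __init__(self, name: str, graph: Optional[ConceptGraph] = None):
        self.name = name
        self.graph = graph or ConceptGraph(name)

    def declare(self, concept: str, label: str, *capabilities: str) -> None:
        self.graph.add(concept, TYPE, "TargetConcept")
        self.graph.add(concept, LABEL, label, literal=True)
        for cap in capabilities:
            self.graph.add(concept, CAPABILITY, cap, literal=True)

    @property
    def concepts(self) -> set[str]:
        return set(self.graph.subjects(TYPE, "TargetConcept"))

    def label(self, concept: str) -> str:
        labels = self.graph.objects(concept, LABEL)
        return labels[0] if labels else concept

    def to_json(self, path=None) -> str:
        data = {"name": self.name, "graph": json.loads(self.graph.to_json())}
        text = json.dumps(data, indent=1, ensure_ascii=False, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "TargetSystemProfile":
        data = _read_json_source(source)
        g = data["graph"]
        return cls(data["name"], ConceptGraph(
            g.get("namespace", ""),
            (Triple(s, pr, o, lit) for s, pr, o, lit in g["triples"])))


@dataclass(frozen=True)
class MappingEntry:
    """One edge of the component mapping.

    ``role`` distinguishes *active* representations (the target system must
    create an executable construct, e.g. an order for a lab test) from
    *passive* ones (the content is copied as pure data).
    """

    metamodel_concept: str
    target_concept: str
    role: str  # "active" | "passive"
    notes: str = ""

    def __post_init__(self):
        if self.role not in ("active", "passive"):
            raise ValueError(f"role must be 'active' or 'passive', got {self.role!r}")


class ComponentMapping:
    """The 1..n correspondence between meta-model and target concepts."""

    def __init__(self, entries: Sequence[MappingEntry] = ()):
        self.entries: list[MappingEntry] = list(dict.fromkeys(entries))

    def for_concept(self, metamodel_concept: str) -> list[MappingEntry]:
        return [e for e in self.entries if e.metamodel_concept == metamodel_concept]

    def integrity_errors(self, profile: TargetSystemProfile,
                         metamodel: Optional[ConceptGraph] = None) -> list[str]:
        meta = metamodel or metamodel_ontology()
        meta_concepts = set(meta.subjects(TYPE, "MetamodelConcept"))
        errors = []
        for e in self.entries:
            if e.metamodel_concept not in meta_concepts:
                errors.append(f"unknown metamodel concept {e.metamodel_concept!r}")
            if e.target_concept not in profile.concepts:
                errors.append(f"unknown target concept {e.target_concept!r}")
        return errors

    def to_graph(self) -> ConceptGraph:
        g = ConceptGraph("mapping")
        for i, e in enumerate(self.entries):
            node = f"map:entry{i:03d}"
            g.add(node, TYPE, "MappingEntry")
            g.add(node, MAPS_FROM, e.metamodel_concept)
            g.add(node, MAPS_TO, e.target_concept)
            g.add(node, ROLE, e.role, literal=True)
            if e.notes:
                g.add(node, "notes", e.notes, literal=True)
        return g

    def to_json(self, path=None) -> str:
        data = [{"metamodel_concept": e.metamodel_concept,
                 "target_concept": e.target_concept,
                 "role": e.role, "notes": e.notes} for e in self.entries]
        text = json.dumps(data, indent=1, ensure_ascii=False) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "ComponentMapping":
        return cls([MappingEntry(**e) for e in _read_json_source(source)])


# ---------------------------------------------------------------------------
# instance and reasoning models

@dataclass
class InstanceModel:
    """Ontological description of one concrete pathway.

    ``element_nodes`` maps each node id to its meta-model concept; node
    count equals the element count of the source pathway (diagnoses,
    phases, activities, parameters).  The pathway itself appears as an
    additional, separately held node.
    """

    graph: ConceptGraph
    pathway_node: str
    element_nodes: dict[str, str] = field(default_factory=dict)  # node -> concept
    element_ids: dict[str, str] = field(default_factory=dict)    # node -> source id
    order: list[str] = field(default_factory=list)               # document order


def build_instance_model(
    pathway: ClinicalPathway,
    repository: Optional[ModelRepository] = None,
) -> InstanceModel:
    """Transform a validated pathway into its ontological instance model."""
    report = validate_pathway(pathway, repository)
    if not report.ok:
        raise ValidationRefusedError(
            f"pathway {pathway.id!r} is invalid:\n" + report.summary(),
            details=[i.model_dump() for i in report.errors])

    g = ConceptGraph("instance")
    pnode = f"inst:{pathway.id}"
    g.add(pnode, TYPE, META_PATHWAY)
    g.add(pnode, LABEL, pathway.name, literal=True)
    g.add(pnode, SOURCE_ELEMENT, pathway.id, literal=True)

    inst = InstanceModel(graph=g, pathway_node=pnode)

    def add(node: str, concept: str, source_id: str, label: str, parent: str):
        g.add(node, TYPE, concept)
        g.add(node, LABEL, label, literal=True)
        g.add(node, SOURCE_ELEMENT, source_id, literal=True)
        g.add(node, PART_OF, parent)
        inst.element_nodes[node] = concept
        inst.element_ids[node] = source_id
        inst.order.append(node)

    for i, dx in enumerate(pathway.inclusion_diagnoses):
        add(f"inst:{pathway.id}:dx{i}", META_DIAGNOSIS,
            f"{pathway.id}:dx{i}", dx.display, pnode)
    for ph in pathway.phases:
        phnode = f"inst:{ph.id}"
        add(phnode, META_PHASE, ph.id, ph.name, pnode)
        for a in ph.activities:
            add(f"inst:{a.id}", META_ACTIVITY[a.kind], a.id, a.name, phnode)
    for par in pathway.parameters:
        add(f"inst:{par.id}", META_PARAMETER, par.id, par.key, pnode)
    return inst


@dataclass(frozen=True)
class RepresentationOption:
    """One possible representation of an element in the target system."""

    target_concept: str
    label: str
    role: str


@dataclass
class ReasoningModel:
    """Union of instance model, target profile and component mapping.

    The merged triple set is the formal artifact; the constituent parts are
    kept for convenient query evaluation.  Queries never mutate the model.
    """

    graph: ConceptGraph
    instance: InstanceModel
    profile: TargetSystemProfile
    mapping: ComponentMapping


def merge_reasoning_model(
    instance: InstanceModel,
    profile: TargetSystemProfile,
    mapping: ComponentMapping,
) -> ReasoningModel:
    """Merge the three graphs (set union, idempotent) after integrity checks."""
    offenders = mapping.integrity_errors(profile)
    if offenders:
        raise MappingIntegrityError(
            "component mapping references unknown concepts: " + "; ".join(offenders),
            details=offenders)
    merged = instance.graph.union(
        profile.graph, mapping.to_graph(), metamodel_ontology(),
        namespace="reasoning")
    return ReasoningModel(graph=merged, instance=instance,
                          profile=profile, mapping=mapping)


def query_counterparts(model: ReasoningModel, element_node: str) -> list[RepresentationOption]:
    """Which counterparts exist in the target system for this element?

    Returns the mapping entries whose meta-model concept types the element,
    ordered lexicographically by target-concept label so that choice
    indices are stable across runs.
    """
    concept = model.instance.element_nodes.get(element_node)
    if concept is None:
        raise QueryError(f"unknown element node {element_node!r}")
    options = [RepresentationOption(
        target_concept=e.target_concept,
        label=model.profile.label(e.target_concept),
        role=e.role)
        for e in model.mapping.for_concept(concept)]
    return sorted(options, key=lambda o: (o.label, o.target_concept))


@dataclass
class ActivePassivePartition:
    active: list[str]
    passive: list[str]
    unmapped: list[str]


def classify_active_passive(
    instance: InstanceModel, mapping: ComponentMapping
) -> ActivePassivePartition:
    """Partition element nodes into active / passive / unmapped.

    Passive elements (all of whose representation options are passive, such
    as parameter-system content) can simply be copied to the target system;
    active elements require creating executable constructs there.
    """
    active, passive, unmapped = [], [], []
    for node in instance.order:
        entries = mapping.for_concept(instance.element_nodes[node])
        if not entries:
            unmapped.append(node)
        elif all(e.role == "passive" for e in entries):
            passive.append(node)
        else:
            active.append(node)
    return ActivePassivePartition(active=active, passive=passive, unmapped=unmapped)
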