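"""Reader/writer for the pathway interchange XML format.

The format is a care-plan-flavoured XML vocabulary defined by this toolkit
(see ``data/pathway.xsd``).  It carries, besides the plain pathway
structure, the five extensions the meta-model adds over a basic care plan:

* guideline assignment (``guidelineRef`` / embedded ``guideline`` records),
* intersectoral structure (``pathwaySystem`` / ``episodeOfCare``),
* evidence and cost concepts (``evidenceRef``, grades, ``cost``),
* the control suite (``edge`` elements with sequence/parallel/conditional
  relations and guards),
* the parameter system (``parameter`` elements).

Writing refuses invalid models; reading validates against the packaged
schema and reconstructs a model that is equal (as a value) to the one
written: ``read_xml(write_xml(doc)) == doc`` for every valid document.
Output is deterministic: UTF-8, fixed element order, attribute maps in
sorted key order.
"""

from __future__ import annotations

import io
from decimal import Decimal
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from lxml import etree
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ValidationRefusedError, VersionError, XmlParseError
from .metamodel import (
    Activity,
    ActivityKind,
    ClinicalPathway,
    CodedConcept,
    ControlFlowEdge,
    Cost,
    EdgeRelation,
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
    validate_pathway,
)

__all__ = ["FORMAT_VERSION", "PathwayDocument", "as_document", "write_xml", "read_xml"]

FORMAT_VERSION = "1.0"

_schema_cache: Optional[etree.XMLSchema] = None


def _schema() -> etree.XMLSchema:
    global _schema_cache
    if _schema_cache is None:
        text = resources.files("pathforge.data").joinpath("pathway.xsd").read_bytes()
        _schema_cache = etree.XMLSchema(etree.parse(io.BytesIO(text)))
    return _schema_cache


class PathwayDocument(BaseModel):
    """A serializable bundle: pathways/systems plus their provenance records.

    On construction the recommendation list is canonicalized (grouped by
    guideline, document order preserved within a guideline) and each
    embedded guideline's recommendation-id list is rewritten to match, so
    that serialization order is well defined and round-trips are identities.
    """

    model_config = ConfigDict(extra="forbid")

    version: str = FORMAT_VERSION
    guidelines: list[Guideline] = []
    recommendations: list[Recommendation] = []
    systems: list[PathwaySystem] = []
    pathways: list[ClinicalPathway] = []

    @model_validator(mode="after")
    def _canonicalize(self) -> "PathwayDocument":
        known = {g.id for g in self.guidelines}
        orphans = [r.id for r in self.recommendations if r.guideline_id not in known]
        if orphans:
            raise ValueError(f"recommendations without embedded guideline: {orphans}")
        grouped = [r for g in self.guidelines
                   for r in self.recommendations if r.guideline_id == g.id]
        object.__setattr__(self, "recommendations", grouped)
        for g in self.guidelines:
            g.recommendations = [r.id for r in grouped if r.guideline_id == g.id]
        return self

    def repository(self) -> ModelRepository:
        repo = ModelRepository()
        for g in self.guidelines:
            repo.add_guideline(g.model_copy(deep=True))
        for r in self.recommendations:
            repo.add_recommendation(r.model_copy(deep=True))
        for p in self.pathways:
            repo.add_pathway(p)
        for s in self.systems:
            repo.add_system(s)
        return repo


def as_document(
    model: Union[ClinicalPathway, PathwaySystem],
    repository: Optional[ModelRepository] = None,
) -> PathwayDocument:
    """Wrap a pathway or system in a document, embedding its provenance.

    Guidelines referenced via ``guideline_ids`` or reachable through
    evidence links are embedded together with the referenced
    recommendations.
    """
    guidelines: dict[str, Guideline] = {}
    recs: dict[str, Recommendation] = {}
    pathways: list[ClinicalPathway] = []
    systems: list[PathwaySystem] = []

    def embed_pathway(p: ClinicalPathway):
        pathways.append(p)
        if repository is None:
            return
        wanted = set(p.guideline_ids)
        for _, act in p.iter_activities():
            if act.evidence_link and act.evidence_link in repository.recommendations:
                r = repository.recommendations[act.evidence_link]
                recs[r.id] = r
                wanted.add(r.guideline_id)
        for gid in sorted(wanted):
            if gid in repository.guidelines:
                guidelines[gid] = repository.guidelines[gid]

    if isinstance(model, ClinicalPathway):
        embed_pathway(model)
    else:
        systems.append(model)
        if repository is not None:
            for ep in model.episodes:
                for pid in ep.pathway_ids:
                    if pid in repository.pathways:
                        embed_pathway(repository.pathways[pid])

    return PathwayDocument(
        guidelines=[guidelines[k] for k in sorted(guidelines)],
        recommendations=list(recs.values()),
        systems=systems,
        pathways=pathways,
    )


# ---------------------------------------------------------------------------
# writing

def _code_el(parent, tag: str, code: CodedConcept):
    el = etree.SubElement(parent, tag)
    if code.system:
        el.set("system", code.system)
    if code.value:
        el.set("value", code.value)
    el.set("display", code.display)
    return el


def _write_pathway(parent, p: ClinicalPathway):
    pe = etree.SubElement(parent, "clinicalPathway")
    pe.set("id", p.id)
    pe.set("name", p.name)
    if p.episode_id:
        pe.set("episodeId", p.episode_id)
    for dx in p.inclusion_diagnoses:
        _code_el(etree.SubElement(pe, "inclusionDiagnosis"), "code", dx)
    for gid in p.guideline_ids:
        etree.SubElement(pe, "guidelineRef").set("ref", gid)
    for ph in p.phases:
        phe = etree.SubElement(pe, "phase")
        phe.set("anchorOffset", str(ph.anchor_offset))
        phe.set("duration", ph.duration)
        phe.set("id", ph.id)
        phe.set("name", ph.name)
        for a in ph.activities:
            ae = etree.SubElement(phe, "activity")
            ae.set("id", a.id)
            ae.set("kind", a.kind.value)
            ae.set("localOrigin", "true" if a.local_origin else "false")
            ae.set("name", a.name)
            if a.code is not None:
                _code_el(ae, "code", a.code)
            if a.evidence_link:
                etree.SubElement(ae, "evidenceRef").set("ref", a.evidence_link)
            if a.cost is not None:
                ce = etree.SubElement(ae, "cost")
                ce.set("amount", str(a.cost.amount))
                ce.set("currency", a.cost.currency)
            if a.responsibility:
                etree.SubElement(ae, "responsibility").text = a.responsibility
            for res in a.resources:
                etree.SubElement(ae, "resource").text = res
            if a.time is not None:
                te = etree.SubElement(ae, "time")
                te.set("duration", a.time.duration)
                te.set("offset", a.time.offset)
            for key in sorted(a.attributes):
                at = etree.SubElement(ae, "attribute")
                at.set("key", key)
                at.text = a.attributes[key]
        for e in ph.edges:
            ee = etree.SubElement(phe, "edge")
            ee.set("from", e.from_activity)
            if e.guard:
                ee.set("guard", e.guard)
            ee.set("relation", e.relation.value)
            ee.set("to", e.to_activity)
    for par in p.parameters:
        pae = etree.SubElement(pe, "parameter")
        pae.set("category", par.category.value)
        pae.set("id", par.id)
        pae.set("key", par.key)
        pae.set("scope", par.scope)
        pae.text = par.value


def write_xml(
    doc: Union[PathwayDocument, ClinicalPathway, PathwaySystem],
    dest: Optional[Union[str, Path]] = None,
    repository: Optional[ModelRepository] = None,
) -> bytes:
    """Serialize a document (or bare pathway/system) to schema-valid XML.

    Every contained pathway is validated first; a pathway with structural
    errors is refused.  Returns the UTF-8 bytes and, when ``dest`` is
    given, also writes them there.
    """
    if not isinstance(doc, PathwayDocument):
        doc = as_document(doc, repository)
    repo = doc.repository()
    for p in doc.pathways:
        report = validate_pathway(p, repo)
        if not report.ok:
            raise ValidationRefusedError(
                f"refusing to write invalid pathway {p.id!r}:\n" + report.summary(),
                details=[i.model_dump() for i in report.errors])

    root = etree.Element("pathwayDocument")
    root.set("version", doc.version)
    for g in doc.guidelines:
        ge = etree.SubElement(root, "guideline")
        if g.citation:
            ge.set("citation", g.citation)
        ge.set("id", g.id)
        ge.set("title", g.title)
        if g.version:
            ge.set("version", g.version)
        for r in (x for x in doc.recommendations if x.guideline_id == g.id):
            re_ = etree.SubElement(ge, "recommendation")
            if r.evidence_grade:
                re_.set("evidenceGrade", r.evidence_grade)
            re_.set("id", r.id)
            re_.set("kind", r.kind.value)
            if r.recommendation_grade:
                re_.set("recommendationGrade", r.recommendation_grade)
            re_.text = r.text
    for s in doc.systems:
        se = etree.SubElement(root, "pathwaySystem")
        se.set("id", s.id)
        for ep in s.episodes:
            epe = etree.SubElement(se, "episodeOfCare")
            epe.set("id", ep.id)
            epe.set("name", ep.name)
            for pid in ep.pathway_ids:
                etree.SubElement(epe, "pathwayRef").set("ref", pid)
    for p in doc.pathways:
        _write_pathway(root, p)

    tree = etree.ElementTree(root)
    if not _schema().validate(tree):
        raise XmlParseError(
            "serialized document does not satisfy the packaged schema: "
            + str(_schema().error_log))
    payload = etree.tostring(tree, xml_declaration=True, encoding="UTF-8",
                             pretty_print=True)
    if dest is not None:
        Path(dest).write_bytes(payload)
    return payload


# ---------------------------------------------------------------------------
# reading

def _read_code(el) -> CodedConcept:
    return CodedConcept(system=el.get("system", ""), value=el.get("value", ""),
                        display=el.get("display"))


def read_xml(source: Union[str, Path, bytes]) -> PathwayDocument:
    """Parse and validate a pathway document; returns the full model bundle.

    Malformed or schema-invalid input raises :class:`XmlParseError` citing
    the offending element path; an unsupported format version raises
    :class:`VersionError`.  No partial models are ever returned.
    """
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        else:
            root = etree.parse(str(source)).getroot()
    except etree.XMLSyntaxError as exc:
        raise XmlParseError(f"not well-formed XML: {exc}") from exc

    if root.tag != "pathwayDocument":
        raise XmlParseError(f"unexpected root element {root.tag!r}")
    version = root.get("version")
    if version != FORMAT_VERSION:
        raise VersionError(f"unsupported format version {version!r} "
                           f"(supported: {FORMAT_VERSION})")
    schema = _schema()
    if not schema.validate(root.getroottree()):
        err = schema.error_log.last_error
        raise XmlParseError(f"schema violation at {err.path}: {err.message}")

    guidelines, recommendations, systems, pathways = [], [], [], []
    for ge in root.findall("guideline"):
        guidelines.append(Guideline(
            id=ge.get("id"), title=ge.get("title"),
            version=ge.get("version", ""), citation=ge.get("citation", "")))
        for re_ in ge.findall("recommendation"):
            recommendations.append(Recommendation(
                id=re_.get("id"), guideline_id=ge.get("id"),
                text=re_.text or "", kind=RecommendationKind(re_.get("kind")),
                evidence_grade=re_.get("evidenceGrade", ""),
                recommendation_grade=re_.get("recommendationGrade", "")))
    for se in root.findall("pathwaySystem"):
        systems.append(PathwaySystem(
            id=se.get("id"),
            episodes=[EpisodeOfCare(
                id=epe.get("id"), name=epe.get("name"),
                pathway_ids=[pr.get("ref") for pr in epe.findall("pathwayRef")])
                for epe in se.findall("episodeOfCare")]))
    for pe in root.findall("clinicalPathway"):
        phases = []
        for phe in pe.findall("phase"):
            activities = []
            for ae in phe.findall("activity"):
                code_el = ae.find("code")
                cost_el = ae.find("cost")
                time_el = ae.find("time")
                ev = ae.find("evidenceRef")
                resp = ae.find("responsibility")
                activities.append(Activity(
                    id=ae.get("id"), kind=ActivityKind(ae.get("kind")),
                    name=ae.get("name"),
                    code=None if code_el is None else _read_code(code_el),
                    responsibility="" if resp is None else (resp.text or ""),
                    resources=[r.text or "" for r in ae.findall("resource")],
                    time=None if time_el is None else TimeSpec(
                        offset=time_el.get("offset"), duration=time_el.get("duration")),
                    evidence_link=None if ev is None else ev.get("ref"),
                    cost=None if cost_el is None else Cost(
                        amount=Decimal(cost_el.get("amount")),
                        currency=cost_el.get("currency")),
                    local_origin=ae.get("localOrigin") in ("true", "1"),
                    attributes={at.get("key"): at.text or ""
                                for at in ae.findall("attribute")}))
            edges = [ControlFlowEdge(
                from_activity=ee.get("from"), to_activity=ee.get("to"),
                relation=EdgeRelation(ee.get("relation")), guard=ee.get("guard", ""))
                for ee in phe.findall("edge")]
            phases.append(TreatmentPhase(
                id=phe.get("id"), name=phe.get("name"),
                anchor_offset=int(phe.get("anchorOffset")),
                duration=phe.get("duration"), activities=activities, edges=edges))
        pathways.append(ClinicalPathway(
            id=pe.get("id"), name=pe.get("name"),
            inclusion_diagnoses=[_read_code(de.find("code"))
                                 for de in pe.findall("inclusionDiagnosis")],
            episode_id=pe.get("episodeId"),
            phases=phases,
            guideline_ids=[gr.get("ref") for gr in pe.findall("guidelineRef")],
            parameters=[Parameter(
                id=pae.get("id"), key=pae.get("key"), value=pae.text or "",
                category=ParameterCategory(pae.get("category")),
                scope=pae.get("scope")) for pae in pe.findall("parameter")]))

    return PathwayDocument(version=version, guidelines=guidelines,
                           recommendations=recommendations,
                           systems=systems, pathways=pathways)
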