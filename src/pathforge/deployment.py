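"""Deployment planning, choice resolution and artifact rendering.

From a reasoning model the planner partitions pathway elements into those
whose translation is automatic (exactly one counterpart in the target
system), those needing a human choice (several counterparts) and those
without any counterpart.  Choices are resolved from a per-user
configuration (strict mode) or interactively; interactive runs save their
answers so they replay strictly.  A fully resolved plan is rendered into
ready-to-use artifacts: an ANSI-style relational insert script (calendric
view plus dimensions) or a target-dialect XML document.  Rendering is
template-driven — one text template per (representation option, dialect) —
and conserves elements: each resolved element yields exactly one emitted
unit, recorded in the artifact manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from string import Template
from typing import Callable, Optional, Sequence, Union
from xml.sax.saxutils import escape as xml_escape

import yaml
from lxml import etree
from pydantic import BaseModel, ConfigDict

from .errors import (
    CoverageError,
    DialectGapError,
    InvalidChoiceError,
    UnresolvedChoiceError,
)
from .metamodel import ClinicalPathway
from .ontology import (
    InstanceModel,
    ReasoningModel,
    RepresentationOption,
    build_instance_model,
    query_counterparts,
)

__all__ = [
    "DeploymentPlan", "ChoiceConfig", "ResolvedPlan", "RenderedArtifact",
    "TemplateSet", "plan_deployment", "resolve",
    "render_relational", "render_target_xml", "RELATIONAL_DDL",
]


# ---------------------------------------------------------------------------
# planning

@dataclass
class DeploymentPlan:
    """Partition of element nodes by how their translation proceeds."""

    auto: dict[str, RepresentationOption]
    pending: dict[str, list[RepresentationOption]]
    unmapped: list[str]
    concepts: dict[str, str]  # node -> metamodel concept (for default choices)
    order: list[str]          # document order of all element nodes

    def to_json(self, path=None) -> str:
        def opt(o: RepresentationOption) -> dict:
            return {"target_concept": o.target_concept, "label": o.label, "role": o.role}

        data = {
            "auto": {k: opt(v) for k, v in self.auto.items()},
            "pending": {k: [opt(o) for o in v] for k, v in self.pending.items()},
            "unmapped": self.unmapped,
            "concepts": self.concepts,
            "order": self.order,
        }
        text = json.dumps(data, indent=1, ensure_ascii=False, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "DeploymentPlan":
        from .ontology import _read_json_source

        data = _read_json_source(source)

        def opt(d: dict) -> RepresentationOption:
            return RepresentationOption(**d)

        return cls(
            auto={k: opt(v) for k, v in data["auto"].items()},
            pending={k: [opt(o) for o in v] for k, v in data["pending"].items()},
            unmapped=list(data["unmapped"]),
            concepts=dict(data["concepts"]),
            order=list(data["order"]),
        )


def plan_deployment(model: ReasoningModel) -> DeploymentPlan:
    """Partition every element node by its counterpart count (1 / >=2 / 0)."""
    auto: dict[str, RepresentationOption] = {}
    pending: dict[str, list[RepresentationOption]] = {}
    unmapped: list[str] = []
    for node in model.instance.order:
        options = query_counterparts(model, node)
        if len(options) == 1:
            auto[node] = options[0]
        elif options:
            pending[node] = options
        else:
            unmapped.append(node)
    return DeploymentPlan(auto=auto, pending=pending, unmapped=unmapped,
                          concepts=dict(model.instance.element_nodes),
                          order=list(model.instance.order))


# ---------------------------------------------------------------------------
# choice resolution

class ChoiceConfig(BaseModel):
    """Per-user selections: element node (or metamodel concept, as a default)
    mapped to the chosen target concept."""

    model_config = ConfigDict(extra="forbid")

    user: str = ""
    selections: dict[str, str] = {}

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ChoiceConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


@dataclass
class ResolvedPlan:
    """Total element -> option assignment, plus an audit log of overrides."""

    assignments: dict[str, RepresentationOption]
    order: list[str]
    log: list[str] = field(default_factory=list)


def resolve(
    plan: DeploymentPlan,
    choices: Optional[ChoiceConfig] = None,
    mode: str = "strict",
    chooser: Optional[Callable[[str, list[RepresentationOption]], RepresentationOption]] = None,
    allow_unmapped: bool = False,
) -> ResolvedPlan:
    """Resolve every pending element to one of its offered options.

    Element-level selections beat concept-level defaults.  In strict mode
    all pending elements must be covered; in interactive mode uncovered
    elements are delegated to ``chooser`` (by default a terminal prompt).
    Unmapped elements block deployment unless explicitly downgraded.
    """
    choices = choices or ChoiceConfig()
    if plan.unmapped and not allow_unmapped:
        raise CoverageError(
            "elements without any counterpart block deployment: "
            + ", ".join(plan.unmapped), details=list(plan.unmapped))
    if mode not in ("strict", "interactive"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "interactive" and chooser is None:
        chooser = _terminal_chooser

    assignments: dict[str, RepresentationOption] = {}
    log: list[str] = []

    for node, option in plan.auto.items():
        sel = choices.selections.get(node)
        if sel is not None:
            if sel != option.target_concept:
                raise InvalidChoiceError(
                    f"{node}: option {sel!r} is not offered "
                    f"(unique counterpart is {option.target_concept!r})")
            log.append(f"{node}: explicit selection confirms automatic choice "
                       f"{option.target_concept}")
        assignments[node] = option

    uncovered: list[str] = []
    for node, options in plan.pending.items():
        sel = choices.selections.get(node)
        source = "element"
        if sel is None:
            sel = choices.selections.get(plan.concepts[node])
            source = "concept-default"
        if sel is None:
            if mode == "interactive":
                picked = chooser(node, options)
                assignments[node] = picked
                log.append(f"{node}: interactively chosen {picked.target_concept}")
                choices.selections[node] = picked.target_concept
                continue
            uncovered.append(node)
            continue
        match = [o for o in options if o.target_concept == sel]
        if not match:
            offered = ", ".join(o.target_concept for o in options)
            raise InvalidChoiceError(
                f"{node}: option {sel!r} is not offered (offered: {offered})")
        assignments[node] = match[0]
        log.append(f"{node}: {source} selection {sel}")

    if uncovered:
        raise UnresolvedChoiceError(
            "pending elements without a selection: " + ", ".join(sorted(uncovered)),
            details=sorted(uncovered))

    order = [n for n in plan.order if n in assignments]
    return ResolvedPlan(assignments=assignments, order=order, log=log)


def _terminal_chooser(node: str, options: list[RepresentationOption]) -> RepresentationOption:
    import click

    click.echo(f"Element {node} can be represented as:")
    for i, o in enumerate(options, 1):
        click.echo(f"  [{i}] {o.label} ({o.target_concept}, {o.role})")
    idx = click.prompt("choose", type=click.IntRange(1, len(options)))
    return options[idx - 1]


# ---------------------------------------------------------------------------
# rendering

class TemplateSet:
    """Text templates keyed by (representation option, dialect)."""

    def __init__(self, dialect_set: str, dimensions: dict[str, str],
                 options: dict[str, dict]):
        self.dialect_set = dialect_set
        self.dimensions = dimensions
        self.options = options

    @classmethod
    def from_mapping(cls, data: dict) -> "TemplateSet":
        return cls(data.get("dialect_set", "unnamed"),
                   dict(data.get("dimensions", {})),
                   dict(data.get("options", {})))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "TemplateSet":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "TemplateSet":
        text = resources.files("pathforge.data").joinpath(
            "docpath_templates.yaml").read_text(encoding="utf-8")
        return cls.from_mapping(yaml.safe_load(text))


@dataclass
class RenderedArtifact:
    dialect: str  # "relational" | "target_xml"
    payload: str
    manifest: dict[str, int]  # element node -> emitted-unit index


RELATIONAL_DDL = [
    "CREATE TABLE pathway (id TEXT PRIMARY KEY, name TEXT NOT NULL);",
    "CREATE TABLE phase_day (id TEXT PRIMARY KEY, pathway_id TEXT NOT NULL, "
    "day_index INTEGER NOT NULL, label TEXT NOT NULL);",
    "CREATE TABLE dimension (id TEXT PRIMARY KEY, label TEXT NOT NULL);",
    "CREATE TABLE element (id TEXT PRIMARY KEY, phase_day TEXT, dimension_id TEXT, "
    "kind TEXT NOT NULL, name TEXT NOT NULL, payload TEXT);",
    "CREATE TABLE attachment (element_id TEXT NOT NULL, kind TEXT NOT NULL, "
    "content TEXT NOT NULL);",
]


@dataclass
class _ElementContext:
    node: str
    element_id: str
    label: str
    kind: str
    payload: str
    day_id: str   # phase_day id or ""
    scope: str    # annotated node (parameters) or own node


def _element_contexts(pathway: ClinicalPathway, instance: InstanceModel) -> dict[str, _ElementContext]:
    """Per-node rendering context, derived by walking the pathway in document order."""
    ctx: dict[str, _ElementContext] = {}
    phase_of_activity: dict[str, str] = {}
    for ph in pathway.phases:
        for a in ph.activities:
            phase_of_activity[a.id] = ph.id

    def day_id(phase_id: str) -> str:
        return f"{pathway.id}:d{phase_id}"

    for i, dx in enumerate(pathway.inclusion_diagnoses):
        node = f"inst:{pathway.id}:dx{i}"
        code = f"{dx.system} {dx.value}".strip()
        ctx[node] = _ElementContext(node, f"{pathway.id}:dx{i}", dx.display,
                                    "diagnosis", code or dx.display, "", node)
    for ph in pathway.phases:
        node = f"inst:{ph.id}"
        ctx[node] = _ElementContext(node, ph.id, ph.name, "phase",
                                    f"day {ph.anchor_offset}", day_id(ph.id), node)
        for a in ph.activities:
            anode = f"inst:{a.id}"
            payload = "; ".join(f"{k}={v}" for k, v in sorted(a.attributes.items()))
            ctx[anode] = _ElementContext(anode, a.id, a.name, a.kind.value,
                                         payload, day_id(ph.id), anode)
    id_to_node = {c.element_id: c.node for c in ctx.values()}
    id_to_node[pathway.id] = f"inst:{pathway.id}"
    for par in pathway.parameters:
        node = f"inst:{par.id}"
        scope_node = id_to_node.get(par.scope, f"inst:{pathway.id}")
        ctx[node] = _ElementContext(node, par.id, par.key, "parameter",
                                    par.value, "", scope_node)
    missing = set(instance.order) - set(ctx)
    if missing:
        raise ValueError(f"instance nodes without rendering context: {sorted(missing)}")
    return ctx


def _sql_quote(text: str) -> str:
    return text.replace("'", "''")


def _template_for(templates: TemplateSet, option: RepresentationOption, dialect_key: str):
    spec = templates.options.get(option.target_concept)
    if spec is None or dialect_key not in spec:
        raise DialectGapError(
            f"no {dialect_key} template for option {option.target_concept!r} "
            f"in dialect set {templates.dialect_set!r}")
    return spec


def render_relational(
    resolved: ResolvedPlan,
    pathway: ClinicalPathway,
    templates: Optional[TemplateSet] = None,
) -> RenderedArtifact:
    """Render an insert script against the reference relational schema.

    The script creates the calendric scaffold (pathway row, one phase_day
    row per treatment phase, the dimensions used) and then one emitted unit
    per resolved element — an element row for active representations, a
    data/attachment row for passive ones.  Loading the script into an empty
    embedded database and counting unit rows must reproduce the manifest.
    """
    templates = templates or TemplateSet.default()
    instance = build_instance_model(pathway)
    ctx = _element_contexts(pathway, instance)

    stmts: list[str] = [f"-- pathforge relational deployment ({templates.dialect_set})",
                        f"-- pathway: {pathway.id}"]
    stmts += RELATIONAL_DDL
    stmts.append("INSERT INTO pathway (id, name) VALUES "
                 f"('{_sql_quote(pathway.id)}', '{_sql_quote(pathway.name)}');")

    # stable scaffold: every dimension the dialect declares, regardless of
    # which options were chosen, so choices stay local to their element
    for dim in sorted(templates.dimensions):
        label = templates.dimensions[dim]
        stmts.append("INSERT INTO dimension (id, label) VALUES "
                     f"('{_sql_quote(dim)}', '{_sql_quote(label)}');")
    for ph in pathway.phases:
        stmts.append(
            "INSERT INTO phase_day (id, pathway_id, day_index, label) VALUES "
            f"('{_sql_quote(pathway.id)}:d{_sql_quote(ph.id)}', "
            f"'{_sql_quote(pathway.id)}', {ph.anchor_offset}, '{_sql_quote(ph.name)}');")

    manifest: dict[str, int] = {}
    for unit_index, node in enumerate(resolved.order):
        option = resolved.assignments[node]
        spec = _template_for(templates, option, "relational")
        c = ctx[node]
        stmt = Template(spec["relational"]).substitute(
            node=_sql_quote(c.node),
            element_id=_sql_quote(c.element_id),
            label=_sql_quote(c.label),
            kind=_sql_quote(c.kind),
            payload=_sql_quote(c.payload),
            day=f"'{_sql_quote(c.day_id)}'" if c.day_id else "NULL",
            scope=_sql_quote(c.scope),
        )
        stmts.append(stmt)
        manifest[node] = unit_index
    return RenderedArtifact(dialect="relational",
                            payload="\n".join(stmts) + "\n", manifest=manifest)


def render_target_xml(
    resolved: ResolvedPlan,
    pathway: ClinicalPathway,
    templates: Optional[TemplateSet] = None,
) -> RenderedArtifact:
    """Render the target-dialect XML document for a resolved plan.

    Each resolved element contributes exactly one node carrying an
    ``element`` attribute, placed under the container its chosen option
    dictates (a dimension, the optional-element list, or the attachment
    list).  Output is byte-deterministic.
    """
    templates = templates or TemplateSet.default()
    instance = build_instance_model(pathway)
    ctx = _element_contexts(pathway, instance)

    root = etree.Element("docPathExport")
    root.set("dialect", templates.dialect_set)
    root.set("path", pathway.id)
    root.set("name", pathway.name)
    calendar = etree.SubElement(root, "calendar")
    for ph in pathway.phases:
        de = etree.SubElement(calendar, "day")
        de.set("id", f"{pathway.id}:d{ph.id}")
        de.set("index", str(ph.anchor_offset))
        de.set("label", ph.name)

    # stable scaffold: all declared dimensions plus the generic containers,
    # present regardless of which options were chosen
    container_keys = [f"dimension:{d}" for d in templates.dimensions]
    container_keys += ["optionalElements", "attachments"]
    for node in resolved.order:  # template sets may route to extra containers
        spec = _template_for(templates, resolved.assignments[node], "xml_fragment")
        key = spec.get("xml_container", "optionalElements")
        if key not in container_keys:
            container_keys.append(key)
    containers: dict[str, etree._Element] = {}
    for key in sorted(set(container_keys)):
        if key.startswith("dimension:"):
            dim = key.split(":", 1)[1]
            el = etree.SubElement(root, "dimension")
            el.set("id", dim)
            el.set("label", templates.dimensions.get(dim, dim))
        else:
            el = etree.SubElement(root, key)
        containers[key] = el

    manifest: dict[str, int] = {}
    for unit_index, node in enumerate(resolved.order):
        option = resolved.assignments[node]
        spec = _template_for(templates, option, "xml_fragment")
        c = ctx[node]
        fragment = Template(spec["xml_fragment"]).substitute(
            node=xml_escape(c.node, {'"': "&quot;"}),
            element_id=xml_escape(c.element_id, {'"': "&quot;"}),
            label=xml_escape(c.label, {'"': "&quot;"}),
            kind=xml_escape(c.kind, {'"': "&quot;"}),
            payload=xml_escape(c.payload, {'"': "&quot;"}),
            day=xml_escape(c.day_id, {'"': "&quot;"}),
            scope=xml_escape(c.scope, {'"': "&quot;"}),
        )
        containers[spec.get("xml_container", "optionalElements")].append(
            etree.fromstring(fragment))
        manifest[node] = unit_index

    payload = etree.tostring(etree.ElementTree(root), xml_declaration=True,
                             encoding="UTF-8", pretty_print=True).decode("utf-8")
    return RenderedArtifact(dialect="target_xml", payload=payload, manifest=manifest)
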