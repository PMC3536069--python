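"""Model documents: a human-editable YAML format, plus graph export.

A model document has top-level blocks ``objects``, ``processes``,
``structural_links``, ``procedural_links``, ``logic_groups``, ``opds``,
``facts`` and ``gaps``, and optional template shorthand blocks
(``binding``, ``catalyzing``, ``transporting``) that are expanded through
the biology templates at load time.  Saving emits a canonical key order so
that save / load / save round-trips are byte-identical.
"""

from __future__ import annotations

from typing import Optional

import yaml

from . import bio_templates
from .gap_analysis import KnowledgeGap, record_gap
from .model_core import (
    OPD,
    FactRecord,
    LogicGroup,
    Model,
    ModelError,
    MolecularFunction,
    ObjectDef,
    ProceduralKind,
    ProceduralLink,
    ProcessDef,
    Role,
    StructuralKind,
    StructuralLink,
    add_object,
    add_process,
    link,
    validate_model,
)

__all__ = ["FORMAT_VERSION", "load_model", "loads_model", "save_model", "dumps_model",
           "export_graph"]

FORMAT_VERSION = 1


class SchemaError(ModelError):
    def __init__(self, message: str, field: Optional[str] = None):
        super().__init__("schema-violation", message)
        self.field = field


def _require(mapping: dict, field: str, context: str):
    if field not in mapping:
        raise SchemaError(f"{context}: missing required field {field!r}", field=field)
    return mapping[field]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _object_doc(o: ObjectDef) -> dict:
    doc: dict = {"name": o.name}
    if o.role is not Role.NONE:
        doc["role"] = o.role.value
    if o.affiliation.value != "systemic":
        doc["affiliation"] = o.affiliation.value
    if o.states:
        doc["states"] = list(o.states)
    if o.initial_state is not None:
        doc["initial_state"] = o.initial_state
    if o.conjecture:
        doc["conjecture"] = True
    if o.compartment is not None:
        doc["compartment"] = o.compartment
    if o.initially_existent is not None:
        doc["initially_existent"] = o.initially_existent
    return doc


def _process_doc(p: ProcessDef) -> dict:
    doc: dict = {"name": p.name, "rank": p.rank}
    if p.parent is not None:
        doc["parent"] = p.parent
    if p.molecular_function is not None:
        doc["molecular_function"] = p.molecular_function.value
    if p.conjecture:
        doc["conjecture"] = True
    return doc


def dumps_model(model: Model) -> str:
    doc = {
        "format_version": FORMAT_VERSION,
        "name": model.name,
        "objects": [_object_doc(o) for o in model.objects()],
        "processes": [_process_doc(p) for p in model.processes()],
        "structural_links": [
            {k: v for k, v in (
                ("kind", l.kind.value), ("source", l.source), ("target", l.target),
                ("cardinality", l.cardinality), ("label", l.label),
            ) if v is not None}
            for l in model.structural_links
        ],
        "procedural_links": [
            {k: v for k, v in (
                ("kind", l.kind.value), ("object", l.object_end),
                ("process", l.process_end), ("state", l.state_qualifier),
                ("group", l.group),
            ) if v is not None}
            for l in model.procedural_links
        ],
        "logic_groups": [
            {"id": g.id, "operator": g.operator.value, "members": list(g.members)}
            for g in model.logic_groups.values()
        ],
        "opds": [
            {"id": o.id, "title": o.title,
             **({"focus_process": o.focus_process} if o.focus_process else {}),
             "visible_things": list(o.visible_things)}
            for o in model.opds_in_tree_order()
        ],
        "facts": [
            {"id": f.id, "statement": f.statement, "citation": f.citation,
             "linked_things": list(f.linked_things),
             **({"reconstructed": True} if f.reconstructed else {})}
            for f in model.facts
        ],
        "gaps": [
            {"id": g.id, "question": g.question, "gap_type": g.gap_type.value,
             "associated_function": g.associated_function.value,
             "linked_things": list(g.linked_things),
             "detection": g.detection.value,
             **({"conjecture": g.conjecture} if g.conjecture else {})}
            for g in model.gaps
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True, width=88)


def save_model(model: Model, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_model(model))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def loads_model(text: str, validate: bool = True) -> Model:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"document is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("document root must be a mapping")
    version = _require(doc, "format_version", "document")
    if version != FORMAT_VERSION:
        raise ModelError("version-mismatch",
                         f"document version {version!r}, expected {FORMAT_VERSION}")

    known = {"format_version", "name", "objects", "processes", "structural_links",
             "procedural_links", "logic_groups", "opds", "facts", "gaps",
             "binding", "catalyzing", "transporting", "metadata"}
    for key in doc:
        if key not in known:
            raise SchemaError(f"unknown top-level block {key!r}", field=key)

    model = Model(name=doc.get("name", "model"), metadata=doc.get("metadata", {}))

    for entry in doc.get("objects") or []:
        name = _require(entry, "name", "object")
        try:
            add_object(model, ObjectDef(
                name,
                role=Role(entry.get("role", "none")),
                affiliation=entry.get("affiliation", "systemic"),
                states=tuple(entry.get("states") or ()),
                initial_state=entry.get("initial_state"),
                conjecture=bool(entry.get("conjecture", False)),
                compartment=entry.get("compartment"),
                initially_existent=entry.get("initially_existent"),
            ))
        except ValueError as exc:
            if isinstance(exc, ModelError):
                raise
            raise SchemaError(f"object {name!r}: {exc}") from exc

    # two passes: parents may appear after children in the document
    entries = doc.get("processes") or []
    for entry in entries:
        name = _require(entry, "name", "process")
        mf = entry.get("molecular_function")
        model.things[name] = ProcessDef(
            name, rank=int(entry.get("rank", 0)), parent=entry.get("parent"),
            molecular_function=MolecularFunction(mf) if mf else None,
            conjecture=bool(entry.get("conjecture", False)),
        )
    for entry in entries:
        parent = entry.get("parent")
        if parent is not None:
            if parent not in model.things:
                raise SchemaError(f"process {entry['name']!r}: unknown parent {parent!r}")
            model.process(parent).children.append(entry["name"])

    for entry in doc.get("structural_links") or []:
        kind = _require(entry, "kind", "structural link")
        try:
            skind = StructuralKind(kind)
        except ValueError as exc:
            raise ModelError("unknown-link-kind", f"structural kind {kind!r}") from exc
        link(model, StructuralLink(
            skind, _require(entry, "source", "structural link"),
            _require(entry, "target", "structural link"),
            cardinality=entry.get("cardinality"), label=entry.get("label"),
        ))

    for entry in doc.get("procedural_links") or []:
        kind = _require(entry, "kind", "procedural link")
        try:
            pkind = ProceduralKind(kind)
        except ValueError as exc:
            raise ModelError("unknown-link-kind", f"procedural kind {kind!r}") from exc
        link(model, ProceduralLink(
            pkind, _require(entry, "object", "procedural link"),
            _require(entry, "process", "procedural link"),
            state_qualifier=entry.get("state"), group=entry.get("group"),
        ))

    for entry in doc.get("logic_groups") or []:
        gid = _require(entry, "id", "logic group")
        model.logic_groups[gid] = LogicGroup(
            gid, _require(entry, "operator", "logic group"),
            list(_require(entry, "members", "logic group")),
        )

    for entry in doc.get("opds") or []:
        oid = _require(entry, "id", "opd")
        model.opds[oid] = OPD(
            oid, title=entry.get("title", ""),
            focus_process=entry.get("focus_process"),
            visible_things=list(entry.get("visible_things") or []),
        )

    for entry in doc.get("facts") or []:
        model.facts.append(FactRecord(
            int(_require(entry, "id", "fact")), entry.get("statement", ""),
            entry.get("citation", ""), tuple(entry.get("linked_things") or ()),
            reconstructed=bool(entry.get("reconstructed", False)),
        ))

    for entry in doc.get("gaps") or []:
        record_gap(model.gaps, KnowledgeGap(
            int(_require(entry, "id", "gap")),
            _require(entry, "question", "gap"),
            _require(entry, "gap_type", "gap"),
            _require(entry, "associated_function", "gap"),
            tuple(entry.get("linked_things") or ()),
            entry.get("detection", "manual"),
            entry.get("conjecture"),
        ), model=model)

    # template shorthand blocks
    for entry in doc.get("binding") or []:
        bio_templates.expand_binding(
            model, _require(entry, "partner_a", "binding"),
            _require(entry, "partner_b", "binding"),
            _require(entry, "complex", "binding"),
            _require(entry, "link_set", "binding"),
            detail=entry.get("detail", "flat"),
            parent=entry.get("parent"), rank=int(entry.get("rank", 0)),
        )
    for entry in doc.get("catalyzing") or []:
        bio_templates.expand_catalyzing(
            model,
            bio_templates.MolecularFunctionSpec(
                _require(entry, "function", "catalyzing"),
                _require(entry, "process", "catalyzing"),
                enzyme=entry.get("enzyme"),
                substrates=tuple(entry.get("substrates") or ()),
                products=tuple(entry.get("products") or ()),
                from_state=entry.get("from_state"), to_state=entry.get("to_state"),
            ),
            parent=entry.get("parent"), rank=int(entry.get("rank", 0)),
        )
    for entry in doc.get("transporting") or []:
        bio_templates.expand_transporting(
            model, _require(entry, "cargo", "transporting"),
            _require(entry, "from", "transporting"),
            _require(entry, "to", "transporting"),
            parent=entry.get("parent"), rank=int(entry.get("rank", 0)),
            process_name=entry.get("process"),
        )

    if validate:
        violations = validate_model(model)
        if violations:
            raise ModelError(
                "invalid-model", "; ".join(str(v) for v in violations[:5])
            )
    return model


def load_model(path, validate: bool = True) -> Model:
    with open(path, "r", encoding="utf-8") as fh:
        return loads_model(fh.read(), validate=validate)


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------

def export_graph(model: Model, flavor: str = "dot", opd_id: Optional[str] = None) -> str:
    """Model (or one diagram of it) as DOT or GraphML text.

    Nodes are things (boxes for objects, ellipses for processes, grey fill
    for conjectured elements); edges are links, styled by kind.
    """
    if opd_id is not None:
        visible = set(model.opds[opd_id].visible_things)
        names = [n for n in model.things if n in visible]
    else:
        names = list(model.things)
    name_set = set(names)

    edges: list[tuple[str, str, str]] = []
    for l in model.structural_links:
        if l.source in name_set and l.target in name_set:
            edges.append((l.source, l.target, l.kind.value))
    for l in model.procedural_links:
        if l.object_end in name_set and l.process_end in name_set:
            if l.kind in (ProceduralKind.RESULT, ProceduralKind.INVOCATION):
                edges.append((l.process_end, l.object_end, l.kind.value))
            else:
                edges.append((l.object_end, l.process_end, l.kind.value))

    if flavor == "dot":
        lines = [f'digraph "{model.name}" {{']
        for n in names:
            thing = model.things[n]
            shape = "box" if isinstance(thing, ObjectDef) else "ellipse"
            attrs = [f"shape={shape}"]
            if getattr(thing, "conjecture", False):
                attrs.append('style=filled, fillcolor=grey')
            if isinstance(thing, ObjectDef) and thing.affiliation.value == "environmental":
                attrs.append("peripheries=2")
            lines.append(f'  "{n}" [{", ".join(attrs)}];')
        style = {"aggregation": "solid", "exhibition": "dashed",
                 "unidirectional": "dotted", "consumption": "solid",
                 "result": "solid", "instrument": "dashed",
                 "condition": "dashed", "effect": "solid", "invocation": "bold"}
        for src, dst, kind in edges:
            lines.append(
                f'  "{src}" -> "{dst}" [label="{kind}", style={style.get(kind, "solid")}];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"

    if flavor == "graphml":
        import networkx as nx

        graph = nx.DiGraph(name=model.name)
        for n in names:
            thing = model.things[n]
            graph.add_node(
                n,
                kind="object" if isinstance(thing, ObjectDef) else "process",
                conjecture=str(getattr(thing, "conjecture", False)),
            )
        for src, dst, kind in edges:
            graph.add_edge(src, dst, kind=kind)
        return "\n".join(nx.generate_graphml(graph)) + "\n"

    raise ModelError("bad-flavor", f"unknown graph flavor {flavor!r}")
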