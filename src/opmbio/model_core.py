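"""Core domain types for object-process models of molecular systems.

An object-process model (OPM) is a single hierarchical description of a
system's structure and behaviour.  *Objects* are stateful things that exist
(molecules, complexes, binding sites, explicit association objects);
*processes* are things that happen to objects and transform them -- create
them, consume them, or move them between states.  Processes may be refined
("in-zoomed") into ordered sub-processes, producing a tree of diagrams
(OPDs).  The vertical position of a process inside its in-zoomed frame is
replaced here by an explicit integer ``rank``: smaller ranks execute
earlier, equal ranks execute concurrently.

Objects and processes share one namespace.  All mutating operations either
leave the model internally consistent or raise :class:`ModelError` without
applying a partial change.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Union

import networkx as nx

__all__ = [
    "Role",
    "Affiliation",
    "StructuralKind",
    "ProceduralKind",
    "LogicOperator",
    "MolecularFunction",
    "ObjectDef",
    "ProcessDef",
    "StructuralLink",
    "ProceduralLink",
    "LogicGroup",
    "OPD",
    "FactRecord",
    "Model",
    "ModelError",
    "Violation",
    "add_object",
    "add_process",
    "link",
    "validate_model",
    "in_zoom",
    "find",
    "show_all_appearances",
    "model_statistics",
]


class Role(str, Enum):
    """Biological typing of an object (shown at the upper-left corner of an
    object box in diagram renderings)."""

    NONE = "none"
    COMPLEX = "Complex"
    PROTEIN = "Protein"
    DOMAIN = "Domain"
    BINDING_SITE = "BindingSite"
    LINK = "Link"
    DOMAIN_LINK_SET = "DomainLinkSet"
    PROTEIN_LINK_SET = "ProteinLinkSet"
    COMPLEX_LINK_SET = "ComplexLinkSet"
    NUCLEOTIDE_SET = "NucleotideSet"
    OTHER = "Other"


#: Roles that denote explicit association objects at some level of the
#: link hierarchy.
LINK_ROLES = frozenset(
    {Role.LINK, Role.DOMAIN_LINK_SET, Role.PROTEIN_LINK_SET, Role.COMPLEX_LINK_SET}
)

#: Ascending levels of the link hierarchy (binding-site links at the bottom,
#: complex link sets at the top).
LINK_HIERARCHY_LEVEL = {
    Role.LINK: 0,
    Role.DOMAIN_LINK_SET: 1,
    Role.PROTEIN_LINK_SET: 2,
    Role.COMPLEX_LINK_SET: 3,
}


class Affiliation(str, Enum):
    SYSTEMIC = "systemic"
    ENVIRONMENTAL = "environmental"


class StructuralKind(str, Enum):
    AGGREGATION = "aggregation"  # part-of
    EXHIBITION = "exhibition"    # attribute
    UNIDIRECTIONAL = "unidirectional"


class ProceduralKind(str, Enum):
    CONSUMPTION = "consumption"
    RESULT = "result"
    EFFECT = "effect"
    INSTRUMENT = "instrument"
    CONDITION = "condition"
    INVOCATION = "invocation"


#: Link kinds that place an object in the preprocess object set.
PRE_KINDS = frozenset(
    {ProceduralKind.CONSUMPTION, ProceduralKind.INSTRUMENT, ProceduralKind.CONDITION}
)
#: Enabler kinds: required but not transformed.
ENABLER_KINDS = frozenset({ProceduralKind.INSTRUMENT, ProceduralKind.CONDITION})


class LogicOperator(str, Enum):
    AND = "AND"
    OR = "OR"
    XOR = "XOR"


class MolecularFunction(str, Enum):
    """The three atomic molecular-function classes (catalysis split into its
    two template variants, binding paired with its inverse dissociation)."""

    CATALYZING_SUBSTRATE_CONSUMED = "catalyzing_substrate_consumed"
    CATALYZING_SUBSTRATE_CHANGED = "catalyzing_substrate_changed"
    BINDING = "binding"
    DISSOCIATION = "dissociation"
    TRANSPORTING = "transporting"


class ModelError(ValueError):
    """Raised when an operation would leave the model inconsistent."""

    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code


@dataclass
class Violation:
    """One invariant violation found by :func:`validate_model`."""

    rule: str
    element: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.rule}] {self.element}: {self.message}"


@dataclass
class ObjectDef:
    name: str
    role: Role = Role.NONE
    affiliation: Affiliation = Affiliation.SYSTEMIC
    states: tuple[str, ...] = ()
    initial_state: Optional[str] = None
    conjecture: bool = False
    compartment: Optional[str] = None
    #: explicit initial existence; None derives it (non-existent iff some
    #: process creates the object during execution)
    initially_existent: Optional[bool] = None

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        self.affiliation = Affiliation(self.affiliation)
        self.states = tuple(self.states)
        if len(set(self.states)) != len(self.states):
            raise ModelError("duplicate-state", f"object {self.name!r} repeats a state name")
        if self.initial_state is not None and self.initial_state not in self.states:
            raise ModelError(
                "initial-state-unknown",
                f"object {self.name!r}: initial state {self.initial_state!r} not declared",
            )


@dataclass
class ProcessDef:
    name: str
    rank: int = 0
    parent: Optional[str] = None
    children: list[str] = field(default_factory=list)
    molecular_function: Optional[MolecularFunction] = None
    conjecture: bool = False

    def __post_init__(self) -> None:
        if self.rank < 0:
            raise ModelError("negative-rank", f"process {self.name!r} has rank {self.rank}")
        if self.molecular_function is not None:
            self.molecular_function = MolecularFunction(self.molecular_function)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class StructuralLink:
    kind: StructuralKind
    source: str
    target: str
    cardinality: Optional[str] = None
    label: Optional[str] = None

    _CARD_RE = re.compile(r"^(\d+)(?:\.\.(\d+|m))?$")

    def __post_init__(self) -> None:
        self.kind = StructuralKind(self.kind)
        if self.cardinality is not None and not self._CARD_RE.match(self.cardinality):
            raise ModelError(
                "bad-cardinality",
                f"cardinality {self.cardinality!r} is not of the form 'a', 'a..b' or 'a..m'",
            )

    def multiplicity_lower(self) -> int:
        """Lower bound of the participation multiplicity (default 1)."""
        if self.cardinality is None:
            return 1
        return int(self._CARD_RE.match(self.cardinality).group(1))


@dataclass
class ProceduralLink:
    kind: ProceduralKind
    object_end: str
    process_end: str
    state_qualifier: Optional[str] = None
    group: Optional[str] = None

    def __post_init__(self) -> None:
        self.kind = ProceduralKind(self.kind)


@dataclass
class LogicGroup:
    id: str
    operator: LogicOperator
    #: indices into Model.procedural_links
    members: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.operator = LogicOperator(self.operator)


@dataclass
class OPD:
    """One diagram in the hierarchical diagram tree; ids follow the dotted
    ``SD``, ``SD1``, ``SD1.1.1`` convention."""

    id: str
    title: str = ""
    focus_process: Optional[str] = None
    visible_things: list[str] = field(default_factory=list)


@dataclass
class FactRecord:
    id: int
    statement: str
    citation: str
    linked_things: tuple[str, ...] = ()
    reconstructed: bool = False


@dataclass
class Model:
    name: str = "model"
    things: dict[str, Union[ObjectDef, ProcessDef]] = field(default_factory=dict)
    structural_links: list[StructuralLink] = field(default_factory=list)
    procedural_links: list[ProceduralLink] = field(default_factory=list)
    logic_groups: dict[str, LogicGroup] = field(default_factory=dict)
    opds: dict[str, OPD] = field(default_factory=dict)
    facts: list[FactRecord] = field(default_factory=list)
    gaps: list = field(default_factory=list)  # KnowledgeGap records (see gap_analysis)
    metadata: dict = field(default_factory=dict)

    # -- accessors ---------------------------------------------------------
    def objects(self) -> Iterator[ObjectDef]:
        return (t for t in self.things.values() if isinstance(t, ObjectDef))

    def processes(self) -> Iterator[ProcessDef]:
        return (t for t in self.things.values() if isinstance(t, ProcessDef))

    def object(self, name: str) -> ObjectDef:
        thing = self.things.get(name)
        if not isinstance(thing, ObjectDef):
            raise ModelError("thing-not-found", f"no object named {name!r}")
        return thing

    def process(self, name: str) -> ProcessDef:
        thing = self.things.get(name)
        if not isinstance(thing, ProcessDef):
            raise ModelError("thing-not-found", f"no process named {name!r}")
        return thing

    def links_of(self, process: str) -> list[ProceduralLink]:
        """Procedural links attached to *process*, in insertion order."""
        return [l for l in self.procedural_links if l.process_end == process]

    def parts_of(self, whole: str) -> list[StructuralLink]:
        return [
            l
            for l in self.structural_links
            if l.kind is StructuralKind.AGGREGATION and l.source == whole
        ]

    def attributes_of(self, owner: str) -> list[str]:
        return [
            l.target
            for l in self.structural_links
            if l.kind is StructuralKind.EXHIBITION and l.source == owner
        ]

    def is_attribute(self, name: str) -> bool:
        """Whether *name* is the target of some exhibition link."""
        return any(
            l.kind is StructuralKind.EXHIBITION and l.target == name
            for l in self.structural_links
        )

    def root_processes(self) -> list[ProcessDef]:
        return [p for p in self.processes() if p.parent is None]

    def root_opd(self) -> OPD:
        if "SD" not in self.opds:
            raise ModelError("no-root-opd", "model has no root diagram 'SD'")
        return self.opds["SD"]

    def opds_in_tree_order(self) -> list[OPD]:
        """Diagrams ordered depth-first by dotted id (numeric components)."""

        def key(opd_id: str) -> tuple:
            if opd_id == "SD":
                return ()
            body = opd_id[2:]  # strip "SD"
            return tuple(int(part) for part in body.split("."))

        return [self.opds[i] for i in sorted(self.opds, key=key)]


# ---------------------------------------------------------------------------
# Mutating operations
# ---------------------------------------------------------------------------

def add_object(model: Model, obj: ObjectDef) -> Model:
    if obj.name in model.things:
        raise ModelError("duplicate-name", f"a thing named {obj.name!r} already exists")
    model.things[obj.name] = obj
    return model


def add_process(model: Model, proc: ProcessDef) -> Model:
    if proc.name in model.things:
        raise ModelError("duplicate-name", f"a thing named {proc.name!r} already exists")
    if proc.parent is not None:
        parent = model.process(proc.parent)
        model.things[proc.name] = proc
        if proc.name not in parent.children:
            parent.children.append(proc.name)
    else:
        model.things[proc.name] = proc
    return model


def link(model: Model, edge: Union[StructuralLink, ProceduralLink]) -> Model:
    """Insert a structural or procedural link after checking its endpoints."""
    if isinstance(edge, StructuralLink):
        if edge.source == edge.target:
            raise ModelError("self-link", f"{edge.source!r} linked to itself")
        for end in (edge.source, edge.target):
            if not isinstance(model.things.get(end), ObjectDef):
                raise ModelError("dangling-endpoint", f"no object named {end!r}")
        if edge.kind is StructuralKind.AGGREGATION and _would_cycle(model, edge):
            raise ModelError(
                "aggregation-cycle", f"{edge.target!r} would become part of itself"
            )
        model.structural_links.append(edge)
        return model

    if not isinstance(edge, ProceduralLink):  # pragma: no cover - defensive
        raise TypeError(f"not a link: {edge!r}")
    proc = model.things.get(edge.process_end)
    if not isinstance(proc, ProcessDef):
        raise ModelError("dangling-endpoint", f"no process named {edge.process_end!r}")
    other = model.things.get(edge.object_end)
    if edge.kind is ProceduralKind.INVOCATION:
        if not isinstance(other, ProcessDef):
            raise ModelError(
                "dangling-endpoint",
                f"invocation source {edge.object_end!r} is not a process",
            )
    else:
        if not isinstance(other, ObjectDef):
            raise ModelError("dangling-endpoint", f"no object named {edge.object_end!r}")
        if edge.state_qualifier is not None and edge.state_qualifier not in other.states:
            raise ModelError(
                "state-qualifier-unknown",
                f"object {edge.object_end!r} has no state {edge.state_qualifier!r}",
            )
    model.procedural_links.append(edge)
    return model


def _would_cycle(model: Model, edge: StructuralLink) -> bool:
    graph = nx.DiGraph()
    for l in model.structural_links:
        if l.kind is StructuralKind.AGGREGATION:
            graph.add_edge(l.source, l.target)
    graph.add_edge(edge.source, edge.target)
    return not nx.is_directed_acyclic_graph(graph)


def add_logic_group(
    model: Model, group_id: str, operator: LogicOperator, member_indices: Iterable[int]
) -> Model:
    members = list(member_indices)
    if len(members) < 2:
        raise ModelError("group-too-small", f"group {group_id!r} needs at least 2 members")
    if group_id in model.logic_groups:
        raise ModelError("duplicate-name", f"logic group {group_id!r} already exists")
    for idx in members:
        lnk = model.procedural_links[idx]
        if lnk.group is not None:
            raise ModelError(
                "link-regrouped", f"link #{idx} already belongs to group {lnk.group!r}"
            )
        lnk.group = group_id
    model.logic_groups[group_id] = LogicGroup(group_id, operator, members)
    return model


# ---------------------------------------------------------------------------
# In-zooming
# ---------------------------------------------------------------------------

def home_opd(model: Model, process: str) -> OPD:
    """The diagram in which *process* is introduced: the in-zoom diagram of
    its parent, or the root diagram for top-level processes."""
    proc = model.process(process)
    if proc.parent is not None:
        for opd in model.opds.values():
            if opd.focus_process == proc.parent:
                return opd
    return model.root_opd()


def in_zoom(
    model: Model,
    process: str,
    children_with_ranks: Iterable[tuple[str, int]],
) -> OPD:
    """Refine *process* into ordered sub-processes and open its diagram.

    ``children_with_ranks`` pairs each child name with its timeline rank;
    equal ranks denote concurrent execution (not an error).  Child names may
    be fresh (registered here) or name existing childless top-level
    processes, which get re-parented.
    """
    proc = model.process(process)
    parent_opd = home_opd(model, process)
    n_existing = sum(
        1 for o in model.opds if o.startswith(parent_opd.id) and _is_child_id(parent_opd.id, o)
    )
    new_id = _child_opd_id(parent_opd.id, n_existing + 1)
    children = list(children_with_ranks)
    for name, rank in children:
        if name in model.things:
            child = model.process(name)
            if child.children or (child.parent not in (None, process)):
                raise ModelError(
                    "not-a-fresh-child", f"{name!r} is not a fresh or childless process"
                )
            child.parent = process
            child.rank = rank
        else:
            model.things[name] = ProcessDef(name, rank=rank, parent=process)
        if name not in proc.children:
            proc.children.append(name)
    opd = OPD(
        id=new_id,
        title=f"{process} in-zoomed",
        focus_process=process,
        visible_things=[process] + [name for name, _ in children],
    )
    model.opds[new_id] = opd
    if process not in parent_opd.visible_things:
        parent_opd.visible_things.append(process)
    return opd


def _child_opd_id(parent_id: str, n: int) -> str:
    return f"SD{n}" if parent_id == "SD" else f"{parent_id}.{n}"


def _is_child_id(parent_id: str, candidate: str) -> bool:
    if candidate == parent_id:
        return False
    if parent_id == "SD":
        return candidate.startswith("SD") and "." not in candidate and candidate != "SD"
    return candidate.startswith(parent_id + ".") and "." not in candidate[len(parent_id) + 1 :]


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def find(
    model: Model,
    pattern: str,
    kinds: Optional[set[str]] = None,
    regex: bool = False,
) -> list[tuple[str, str]]:
    """All (thing-or-state, OPD id) locations whose name contains *pattern*.

    ``kinds`` restricts the search to a subset of {"object", "process",
    "state"}; by default all three are searched.  With ``regex=True`` the
    pattern is a regular expression, otherwise a literal substring.
    """
    kinds = kinds or {"object", "process", "state"}
    try:
        matcher = re.compile(pattern if regex else re.escape(pattern))
    except re.error as exc:
        raise ModelError("invalid-pattern", str(exc)) from exc

    hits: list[tuple[str, str]] = []
    for opd in model.opds_in_tree_order():
        for name in opd.visible_things:
            thing = model.things.get(name)
            if thing is None:
                continue
            if isinstance(thing, ObjectDef):
                if "object" in kinds and matcher.search(name):
                    hits.append((name, opd.id))
                if "state" in kinds:
                    for state in thing.states:
                        if matcher.search(state):
                            hits.append((f"{name}.{state}", opd.id))
            elif "process" in kinds and matcher.search(name):
                hits.append((name, opd.id))
    return hits


def show_all_appearances(model: Model, thing: str) -> list[str]:
    """OPD ids in which *thing* is visible, in diagram-tree order."""
    if thing not in model.things:
        raise ModelError("thing-not-found", f"no thing named {thing!r}")
    return [opd.id for opd in model.opds_in_tree_order() if thing in opd.visible_things]


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass
class ModelStatistics:
    objects: int
    processes: int
    higher_level_processes: int
    leaf_processes: int
    tree_depth: int

    def as_dict(self) -> dict[str, int]:
        return {
            "objects": self.objects,
            "processes": self.processes,
            "higher_level_processes": self.higher_level_processes,
            "leaf_processes": self.leaf_processes,
            "tree_depth": self.tree_depth,
        }


def model_statistics(model: Model) -> ModelStatistics:
    objects = sum(1 for _ in model.objects())
    processes = list(model.processes())
    higher = sum(1 for p in processes if p.children)
    leaves = sum(1 for p in processes if not p.children)

    def depth(proc: ProcessDef) -> int:
        if not proc.children:
            return 1
        return 1 + max(depth(model.process(c)) for c in proc.children)

    tree_depth = max((depth(p) for p in model.root_processes()), default=0)
    return ModelStatistics(objects, len(processes), higher, leaves, tree_depth)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def effect_pairs(model: Model, process: str) -> list[tuple[str, str, str]]:
    """State-change pairs of *process*: (object, from_state, to_state).

    A state change is written as a state-qualified consumption paired with a
    state-qualified result on the same object and process.
    """
    consumed: dict[str, str] = {}
    created: dict[str, str] = {}
    for l in model.links_of(process):
        if l.state_qualifier is None:
            continue
        if l.kind is ProceduralKind.CONSUMPTION:
            consumed[l.object_end] = l.state_qualifier
        elif l.kind is ProceduralKind.RESULT:
            created[l.object_end] = l.state_qualifier
    return [
        (obj, consumed[obj], created[obj]) for obj in consumed if obj in created
    ]


def paired_objects(model: Model, process: str) -> set[str]:
    return {obj for obj, _, _ in effect_pairs(model, process)}


def creation_links(model: Model, obj: str) -> list[ProceduralLink]:
    """Result links that genuinely create *obj* (not halves of state-change
    pairs)."""
    out = []
    for l in model.procedural_links:
        if l.kind is ProceduralKind.RESULT and l.object_end == obj:
            if obj not in paired_objects(model, l.process_end):
                out.append(l)
    return out


def validate_model(model: Model) -> list[Violation]:
    """Every invariant violation in the model; empty iff well-formed.

    Violations are data (not exceptions): a loaded or fuzzed model may break
    several rules at once and all of them are reported.
    """
    v: list[Violation] = []

    # structural link endpoints and acyclicity
    agg = nx.DiGraph()
    for i, l in enumerate(model.structural_links):
        for end in (l.source, l.target):
            if not isinstance(model.things.get(end), ObjectDef):
                v.append(
                    Violation("dangling-endpoint", f"structural#{i}", f"missing object {end!r}")
                )
        if l.source == l.target:
            v.append(Violation("self-link", f"structural#{i}", f"{l.source!r} part of itself"))
        elif l.kind is StructuralKind.AGGREGATION:
            agg.add_edge(l.source, l.target)
    if agg.number_of_nodes() and not nx.is_directed_acyclic_graph(agg):
        cycle = nx.find_cycle(agg)
        v.append(
            Violation(
                "aggregation-cycle",
                cycle[0][0],
                "aggregation contains a cycle: " + " > ".join(e[0] for e in cycle),
            )
        )

    # procedural link endpoints and state qualifiers
    for i, l in enumerate(model.procedural_links):
        proc = model.things.get(l.process_end)
        if not isinstance(proc, ProcessDef):
            v.append(
                Violation(
                    "dangling-endpoint", f"procedural#{i}", f"missing process {l.process_end!r}"
                )
            )
        other = model.things.get(l.object_end)
        if l.kind is ProceduralKind.INVOCATION:
            if not isinstance(other, ProcessDef):
                v.append(
                    Violation(
                        "dangling-endpoint",
                        f"procedural#{i}",
                        f"invocation source {l.object_end!r} is not a process",
                    )
                )
        elif not isinstance(other, ObjectDef):
            v.append(
                Violation(
                    "dangling-endpoint", f"procedural#{i}", f"missing object {l.object_end!r}"
                )
            )
        elif l.state_qualifier is not None and l.state_qualifier not in other.states:
            v.append(
                Violation(
                    "state-qualifier-unknown",
                    f"procedural#{i}",
                    f"{l.object_end!r} has no state {l.state_qualifier!r}",
                )
            )

    # process containment consistency
    for p in model.processes():
        if p.parent is not None:
            parent = model.things.get(p.parent)
            if not isinstance(parent, ProcessDef) or p.name not in parent.children:
                v.append(
                    Violation("containment", p.name, f"parent {p.parent!r} does not list it")
                )
        for c in p.children:
            child = model.things.get(c)
            if not isinstance(child, ProcessDef) or child.parent != p.name:
                v.append(Violation("containment", p.name, f"child {c!r} inconsistent"))
    tree = nx.DiGraph()
    for p in model.processes():
        for c in p.children:
            tree.add_edge(p.name, c)
    if tree.number_of_nodes() and not nx.is_directed_acyclic_graph(tree):
        v.append(Violation("containment-cycle", "processes", "process tree has a cycle"))

    # logic groups
    for g in model.logic_groups.values():
        if len(g.members) < 2:
            v.append(Violation("group-too-small", g.id, "fewer than 2 members"))
            continue
        links = [model.procedural_links[i] for i in g.members if i < len(model.procedural_links)]
        if len(links) != len(g.members):
            v.append(Violation("group-dangling", g.id, "member index out of range"))
            continue
        procs = {l.process_end for l in links}
        sides = {l.kind in PRE_KINDS for l in links}
        if len(procs) != 1 or len(sides) != 1:
            v.append(Violation("group-mixed", g.id, "members span processes or sides"))

    # diagram tree
    if "SD" not in model.opds:
        if model.opds:
            v.append(Violation("no-root-opd", "opds", "no diagram with id 'SD'"))
    for opd in model.opds.values():
        for name in opd.visible_things:
            if name not in model.things:
                v.append(Violation("dangling-visible", opd.id, f"unknown thing {name!r}"))
        if opd.focus_process is not None and opd.focus_process not in model.things:
            v.append(Violation("dangling-focus", opd.id, f"unknown process {opd.focus_process!r}"))

    # concurrent-group write conflicts: two same-rank siblings consuming one object
    for p in model.processes():
        by_rank: dict[int, list[str]] = {}
        for c in p.children:
            child = model.things.get(c)
            if isinstance(child, ProcessDef):
                by_rank.setdefault(child.rank, []).append(c)
        for rank, group in by_rank.items():
            if len(group) < 2:
                continue
            consumed: dict[str, str] = {}
            for c in group:
                for l in model.links_of(c):
                    if l.kind is ProceduralKind.CONSUMPTION and l.object_end not in paired_objects(model, c):
                        if l.object_end in consumed and consumed[l.object_end] != c:
                            v.append(
                                Violation(
                                    "concurrent-conflict",
                                    p.name,
                                    f"rank {rank}: {consumed[l.object_end]!r} and {c!r} "
                                    f"both consume {l.object_end!r}",
                                )
                            )
                        consumed[l.object_end] = c

    # template shapes for annotated leaves (deferred import: bio_templates
    # builds on this module)
    from . import bio_templates

    for p in model.processes():
        if p.is_leaf and p.molecular_function is not None:
            v.extend(bio_templates.validate_template(model, p.name))

    # facts
    seen_fact_ids = set()
    for f in model.facts:
        if f.id in seen_fact_ids:
            v.append(Violation("duplicate-fact-id", str(f.id), "fact id reused"))
        seen_fact_ids.add(f.id)

    return v
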