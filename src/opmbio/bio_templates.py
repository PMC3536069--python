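"""Biology-specific structural and molecular-function templates.

Molecular structures follow a fixed containment chain -- a Complex consists
of Proteins, a Protein of Domains, a Domain of Binding Sites -- and
non-covalent associations between molecules are reified as explicit objects
forming a parallel link hierarchy: a Link joins two binding sites, a Domain
Link Set aggregates Links, a Protein Link Set aggregates Domain Link Sets,
and a Complex Link Set sits at the top.  Covalent modifications are never
expressed as Link objects; they go through a catalyzing template.

At the lowest level of the process tree every behaviour is one of three
molecular functions:

* catalyzing -- enzyme-enabled transformation, either consuming substrates
  into products or switching a substrate between two of its states;
* binding / dissociation -- non-covalent association of two or more
  partners, producing (or consuming) a complex plus a link-set object;
* transporting -- directed movement of a cargo between cell compartments,
  modelled as a state change of an exhibited location attribute.

The ``expand_*`` helpers write these templates into a model;
:func:`classify_process` recovers the class of a leaf process from the
shape of its links alone, so a model built by hand can be cross-checked
against the templates it claims to instantiate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model_core import (
    LINK_HIERARCHY_LEVEL,
    LINK_ROLES,
    Affiliation,
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
    Violation,
    add_object,
    add_process,
    effect_pairs,
    link,
)

__all__ = [
    "MolecularFunctionSpec",
    "ModelDelta",
    "expand_binding",
    "expand_dissociation",
    "expand_catalyzing",
    "expand_transporting",
    "classify_process",
    "validate_template",
    "location_attribute_name",
]


@dataclass
class MolecularFunctionSpec:
    """Parameters of one molecular-function template instantiation."""

    function: MolecularFunction
    process_name: str
    enzyme: Optional[str] = None
    substrates: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    partners: tuple[str, ...] = ()
    cargo: Optional[str] = None
    source_compartment: Optional[str] = None
    target_compartment: Optional[str] = None
    from_state: Optional[str] = None
    to_state: Optional[str] = None

    def __post_init__(self) -> None:
        self.function = MolecularFunction(self.function)
        self.substrates = tuple(self.substrates)
        self.products = tuple(self.products)
        self.partners = tuple(self.partners)

    def validate(self) -> None:
        f = self.function
        if f is MolecularFunction.CATALYZING_SUBSTRATE_CHANGED:
            if self.enzyme is None:
                raise ModelError("missing-enzyme", f"{self.process_name!r} needs an enzyme")
            if len(self.substrates) != 1:
                raise ModelError("bad-spec", "substrate-changed takes exactly one substrate")
            if self.from_state is None or self.to_state is None:
                raise ModelError("missing-state", "substrate-changed needs from/to states")
            if self.from_state == self.to_state:
                raise ModelError("missing-state", "from_state must differ from to_state")
        elif f is MolecularFunction.CATALYZING_SUBSTRATE_CONSUMED:
            if self.enzyme is None:
                raise ModelError("missing-enzyme", f"{self.process_name!r} needs an enzyme")
            if not self.substrates:
                raise ModelError("bad-spec", "substrate-consumed needs >=1 substrate")
        elif f in (MolecularFunction.BINDING, MolecularFunction.DISSOCIATION):
            if len(self.partners) < 2:
                raise ModelError("bad-spec", "binding/dissociation needs >=2 partners")
        elif f is MolecularFunction.TRANSPORTING:
            if self.cargo is None:
                raise ModelError("bad-spec", "transporting needs a cargo")
            if self.source_compartment == self.target_compartment:
                raise ModelError("same-compartment", "compartments must differ")


@dataclass
class ModelDelta:
    """Names of elements added to a model by a template expansion."""

    objects: list[str] = field(default_factory=list)
    processes: list[str] = field(default_factory=list)
    procedural_links: list[int] = field(default_factory=list)
    structural_links: list[int] = field(default_factory=list)


def _track_links(model: Model, delta: ModelDelta, n_proc_before: int, n_struct_before: int) -> None:
    delta.procedural_links.extend(range(n_proc_before, len(model.procedural_links)))
    delta.structural_links.extend(range(n_struct_before, len(model.structural_links)))


# ---------------------------------------------------------------------------
# Binding / dissociation
# ---------------------------------------------------------------------------

def expand_binding(
    model: Model,
    partner_a: str,
    partner_b: str,
    complex_name: str,
    link_set_name: str,
    detail: str = "flat",
    parent: Optional[str] = None,
    rank: int = 0,
) -> ModelDelta:
    """Write a binding template: a process that, enabled by its two
    partners, creates a new complex aggregating both and a new link-set
    object recording the non-covalent association.

    With ``detail="zoomed"`` the process is refined into its two ordered
    sub-processes, link-set generation first, complex assembly second.
    """
    for p in (partner_a, partner_b):
        if not isinstance(model.things.get(p), ObjectDef):
            raise ModelError("partner-missing", f"no object named {p!r}")
    for fresh in (complex_name, link_set_name):
        if fresh in model.things:
            raise ModelError("name-clash", f"{fresh!r} already exists")
    process_name = f"{partner_a} and {partner_b} Binding"
    if process_name in model.things:
        raise ModelError("name-clash", f"{process_name!r} already exists")

    delta = ModelDelta()
    np, ns = len(model.procedural_links), len(model.structural_links)

    add_object(model, ObjectDef(complex_name, role=Role.COMPLEX))
    add_object(model, ObjectDef(link_set_name, role=Role.COMPLEX_LINK_SET))
    delta.objects += [complex_name, link_set_name]

    proc = ProcessDef(process_name, rank=rank, parent=parent,
                      molecular_function=MolecularFunction.BINDING)
    add_process(model, proc)
    delta.processes.append(process_name)

    link(model, ProceduralLink(ProceduralKind.INSTRUMENT, partner_a, process_name))
    link(model, ProceduralLink(ProceduralKind.INSTRUMENT, partner_b, process_name))

    if detail == "zoomed":
        gen = f"{link_set_name} Generating"
        asm = f"{complex_name} Assembling"
        add_process(model, ProcessDef(gen, rank=0, parent=process_name,
                                      molecular_function=MolecularFunction.BINDING))
        add_process(model, ProcessDef(asm, rank=1, parent=process_name,
                                      molecular_function=MolecularFunction.BINDING))
        delta.processes += [gen, asm]
        link(model, ProceduralLink(ProceduralKind.INSTRUMENT, partner_a, gen))
        link(model, ProceduralLink(ProceduralKind.INSTRUMENT, partner_b, gen))
        link(model, ProceduralLink(ProceduralKind.RESULT, link_set_name, gen))
        link(model, ProceduralLink(ProceduralKind.INSTRUMENT, partner_a, asm))
        link(model, ProceduralLink(ProceduralKind.INSTRUMENT, partner_b, asm))
        link(model, ProceduralLink(ProceduralKind.RESULT, complex_name, asm))
    else:
        link(model, ProceduralLink(ProceduralKind.RESULT, complex_name, process_name))
        link(model, ProceduralLink(ProceduralKind.RESULT, link_set_name, process_name))

    link(model, StructuralLink(StructuralKind.AGGREGATION, complex_name, partner_a))
    link(model, StructuralLink(StructuralKind.AGGREGATION, complex_name, partner_b))
    _track_links(model, delta, np, ns)
    return delta


def expand_dissociation(
    model: Model,
    complex_name: str,
    link_set_name: str,
    parent: Optional[str] = None,
    rank: int = 0,
) -> ModelDelta:
    """Write the inverse of binding: a process consuming the complex and its
    link set, re-establishing the free partners."""
    cx = model.object(complex_name)
    if cx.role is not Role.COMPLEX:
        raise ModelError("shape-mismatch", f"{complex_name!r} is not a Complex")
    ls = model.object(link_set_name)
    if ls.role not in LINK_ROLES:
        raise ModelError("shape-mismatch", f"{link_set_name!r} is not a link-set object")
    partners = [l.target for l in model.parts_of(complex_name)]
    if len(partners) < 2:
        raise ModelError("shape-mismatch", f"{complex_name!r} has fewer than 2 parts")

    process_name = f"{complex_name} Dissociating"
    if process_name in model.things:
        raise ModelError("name-clash", f"{process_name!r} already exists")
    delta = ModelDelta()
    np, ns = len(model.procedural_links), len(model.structural_links)
    add_process(model, ProcessDef(process_name, rank=rank, parent=parent,
                                  molecular_function=MolecularFunction.DISSOCIATION))
    delta.processes.append(process_name)
    link(model, ProceduralLink(ProceduralKind.CONSUMPTION, complex_name, process_name))
    link(model, ProceduralLink(ProceduralKind.CONSUMPTION, link_set_name, process_name))
    from .model_core import creation_links

    for partner in partners:
        # a partner that pre-existed keeps its initial existence: the new
        # result link re-establishes it, it does not make it created-only
        partner_def = model.object(partner)
        if partner_def.initially_existent is None and not creation_links(model, partner):
            partner_def.initially_existent = True
        link(model, ProceduralLink(ProceduralKind.RESULT, partner, process_name))
    _track_links(model, delta, np, ns)
    return delta


# ---------------------------------------------------------------------------
# Catalyzing
# ---------------------------------------------------------------------------

def expand_catalyzing(model: Model, spec: MolecularFunctionSpec,
                      parent: Optional[str] = None, rank: int = 0) -> ModelDelta:
    spec.validate()
    if spec.function not in (
        MolecularFunction.CATALYZING_SUBSTRATE_CONSUMED,
        MolecularFunction.CATALYZING_SUBSTRATE_CHANGED,
    ):
        raise ModelError("bad-spec", f"{spec.function.value} is not a catalyzing template")
    if spec.process_name in model.things:
        raise ModelError("name-clash", f"{spec.process_name!r} already exists")
    enzyme = model.object(spec.enzyme)  # noqa: F841 -- existence check
    delta = ModelDelta()
    np, ns = len(model.procedural_links), len(model.structural_links)
    add_process(model, ProcessDef(spec.process_name, rank=rank, parent=parent,
                                  molecular_function=spec.function))
    delta.processes.append(spec.process_name)
    link(model, ProceduralLink(ProceduralKind.INSTRUMENT, spec.enzyme, spec.process_name))
    if spec.function is MolecularFunction.CATALYZING_SUBSTRATE_CHANGED:
        substrate = model.object(spec.substrates[0])
        for state in (spec.from_state, spec.to_state):
            if state not in substrate.states:
                raise ModelError(
                    "missing-state", f"{substrate.name!r} has no state {state!r}"
                )
        link(model, ProceduralLink(ProceduralKind.CONSUMPTION, substrate.name,
                                   spec.process_name, state_qualifier=spec.from_state))
        link(model, ProceduralLink(ProceduralKind.RESULT, substrate.name,
                                   spec.process_name, state_qualifier=spec.to_state))
    else:
        for s in spec.substrates:
            link(model, ProceduralLink(ProceduralKind.CONSUMPTION, s, spec.process_name))
        for p in spec.products:
            link(model, ProceduralLink(ProceduralKind.RESULT, p, spec.process_name))
    _track_links(model, delta, np, ns)
    return delta


# ---------------------------------------------------------------------------
# Transporting
# ---------------------------------------------------------------------------

def location_attribute_name(cargo: str) -> str:
    return f"{cargo} Location"


def expand_transporting(
    model: Model,
    cargo: str,
    from_compartment: str,
    to_compartment: str,
    parent: Optional[str] = None,
    rank: int = 0,
    process_name: Optional[str] = None,
) -> ModelDelta:
    """Write a transporting template: cargo movement between compartments is
    a state change of a location attribute exhibited by the cargo."""
    if from_compartment == to_compartment:
        raise ModelError("same-compartment", f"cargo stays in {from_compartment!r}")
    model.object(cargo)
    process_name = process_name or f"{cargo} Transporting"
    if process_name in model.things:
        raise ModelError("name-clash", f"{process_name!r} already exists")
    delta = ModelDelta()
    np, ns = len(model.procedural_links), len(model.structural_links)

    attr_name = location_attribute_name(cargo)
    attr = model.things.get(attr_name)
    if attr is None:
        attr = ObjectDef(attr_name, role=Role.OTHER,
                         states=(from_compartment, to_compartment),
                         initial_state=from_compartment)
        add_object(model, attr)
        delta.objects.append(attr_name)
        link(model, StructuralLink(StructuralKind.EXHIBITION, cargo, attr_name))
    else:
        missing = [s for s in (from_compartment, to_compartment) if s not in attr.states]
        if missing:
            attr.states = attr.states + tuple(missing)

    add_process(model, ProcessDef(process_name, rank=rank, parent=parent,
                                  molecular_function=MolecularFunction.TRANSPORTING))
    delta.processes.append(process_name)
    link(model, ProceduralLink(ProceduralKind.CONSUMPTION, attr_name, process_name,
                               state_qualifier=from_compartment))
    link(model, ProceduralLink(ProceduralKind.RESULT, attr_name, process_name,
                               state_qualifier=to_compartment))
    _track_links(model, delta, np, ns)
    return delta


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_process(model: Model, process: str) -> str:
    """Infer the molecular-function class of a process from link shape.

    Higher-level processes are ``"composite"``; a leaf whose links match no
    template is ``"unclassified"``.  Matching looks only at the links, so
    the result is invariant under link reordering.
    """
    proc = model.process(process)
    if proc.children:
        return "composite"
    links = model.links_of(process)
    pairs = effect_pairs(model, process)
    paired = {obj for obj, _, _ in pairs}
    enablers = [l for l in links if l.kind in (ProceduralKind.INSTRUMENT, ProceduralKind.CONDITION)]
    consumed = [l for l in links
                if l.kind is ProceduralKind.CONSUMPTION and l.object_end not in paired]
    created = [l for l in links
               if l.kind is ProceduralKind.RESULT and l.object_end not in paired]

    # transporting: the changed object is an exhibited (location) attribute
    if pairs and all(model.is_attribute(obj) for obj, _, _ in pairs):
        return MolecularFunction.TRANSPORTING.value

    # substrate change: enzyme enabler + a state-change pair on a molecule
    if pairs and enablers:
        return MolecularFunction.CATALYZING_SUBSTRATE_CHANGED.value

    def role_of(name: str) -> Role:
        thing = model.things.get(name)
        return thing.role if isinstance(thing, ObjectDef) else Role.NONE

    creates_assembly = any(
        role_of(l.object_end) is Role.COMPLEX or role_of(l.object_end) in LINK_ROLES
        for l in created
    )
    participants = {l.object_end for l in enablers} | {l.object_end for l in consumed}

    # dissociation first: it consumes a complex + link set and re-creates the
    # partners, which may themselves be complexes
    consumes_assembly = any(
        role_of(l.object_end) is Role.COMPLEX for l in consumed
    ) and any(role_of(l.object_end) in LINK_ROLES for l in consumed)
    if consumes_assembly and len(created) >= 2:
        return MolecularFunction.DISSOCIATION.value

    if creates_assembly and len(participants) >= 2:
        return MolecularFunction.BINDING.value
    if creates_assembly and len(participants) == 1 and role_of(next(iter(participants))) in (
        Role.PROTEIN, Role.COMPLEX, Role.BINDING_SITE, Role.DOMAIN,
    ):
        # single named partner with the other side implicit (selective refinement)
        return MolecularFunction.BINDING.value

    if enablers and consumed and not pairs:
        return MolecularFunction.CATALYZING_SUBSTRATE_CONSUMED.value

    return "unclassified"


# ---------------------------------------------------------------------------
# Template validation
# ---------------------------------------------------------------------------

#: part roles a whole of the given role may aggregate; a Complex may list a
#: Domain directly when its protein level is elided (selective refinement)
_ALLOWED_PARTS = {
    Role.COMPLEX: {Role.PROTEIN, Role.COMPLEX, Role.DOMAIN, Role.NONE, Role.OTHER}
    | LINK_ROLES,
    Role.PROTEIN: {Role.DOMAIN},
    Role.DOMAIN: {Role.DOMAIN, Role.BINDING_SITE},
}


def validate_template(model: Model, element: str) -> list[Violation]:
    """Shape violations of the structural or molecular-function template the
    *element* instantiates (judged by its role / annotation)."""
    v: list[Violation] = []
    thing = model.things.get(element)
    if thing is None:
        return [Violation("thing-not-found", element, "no such element")]

    if isinstance(thing, ProcessDef):
        if thing.molecular_function is None or thing.children:
            return v
        inferred = classify_process(model, element)
        declared = thing.molecular_function.value
        if inferred != declared:
            v.append(
                Violation(
                    "template-shape",
                    element,
                    f"declared {declared} but links match {inferred!r}",
                )
            )
        return v

    role = thing.role
    parts = model.parts_of(element)

    if role in (Role.COMPLEX, Role.PROTEIN, Role.DOMAIN):
        allowed = _ALLOWED_PARTS[role]
        for l in parts:
            part = model.things.get(l.target)
            if isinstance(part, ObjectDef) and part.role is not Role.NONE and part.role not in allowed:
                v.append(
                    Violation(
                        "template-part-role",
                        element,
                        f"{role.value} aggregates {l.target!r} of role {part.role.value}",
                    )
                )
        if role is Role.COMPLEX and parts and not any(
            isinstance(model.things.get(l.target), ObjectDef)
            and model.things[l.target].role in (Role.PROTEIN, Role.COMPLEX, Role.DOMAIN)
            for l in parts
        ):
            v.append(
                Violation("template-empty-complex", element,
                          "detailed Complex aggregates no molecular part")
            )

    elif role is Role.LINK:
        ends = [
            l.target
            for l in model.structural_links
            if l.kind is StructuralKind.UNIDIRECTIONAL and l.source == element
        ]
        if len(ends) != 2 or len(set(ends)) != 2:
            v.append(
                Violation("link-endpoints", element,
                          "a Link must reference exactly two distinct binding sites")
            )
        for end in set(ends):
            obj = model.things.get(end)
            if isinstance(obj, ObjectDef) and obj.role not in (Role.BINDING_SITE, Role.NONE):
                v.append(
                    Violation("link-endpoint-role", element,
                              f"endpoint {end!r} has role {obj.role.value}")
                )

    elif role in LINK_ROLES:  # the three set levels
        level = LINK_HIERARCHY_LEVEL[role]
        for l in parts:
            part = model.things.get(l.target)
            if not isinstance(part, ObjectDef):
                continue
            part_level = LINK_HIERARCHY_LEVEL.get(part.role)
            if part_level is None or part_level >= level:
                v.append(
                    Violation(
                        "link-hierarchy", element,
                        f"{role.value} aggregates {l.target!r} which is not strictly lower",
                    )
                )

    return v
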