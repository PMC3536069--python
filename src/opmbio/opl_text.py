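"""Deterministic rendering of a model into Object-Process Language (OPL).

OPL is a small controlled subset of natural English: every structural and
procedural link family has a fixed sentence template, so the text document
is exactly equivalent to the graphical model.  Sentences are emitted per
diagram, in diagram-tree order, structure before behaviour.  Within a
diagram, aggregation is *collapsed to the visible level*: a whole lists the
nearest visible descendants among its transitive parts, which is how an
abstracted diagram can truthfully say that a complex "consists of" a deeply
nested binding site.

State-qualified enablers render the state as a preposed adjective
("phosphorylated Serine 2"); state-specified creation uses the explicit
"yields X at state s." template, an extrapolation of the printed style (the
source diagrams draw the state graphically).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .model_core import (
    Model,
    ModelError,
    ObjectDef,
    OPD,
    ProceduralKind,
    ProcessDef,
    StructuralKind,
    effect_pairs,
)

__all__ = ["SentenceFamily", "SentencePlan", "render_sentence", "generate_opl"]


class SentenceFamily(str, Enum):
    CONSISTS_OF = "consists_of"
    EXHIBITS = "exhibits"
    CONSUMES = "consumes"
    YIELDS = "yields"
    YIELDS_AT_STATE = "yields_at_state"
    CHANGES_FROM_TO = "changes_from_to"
    REQUIRES = "requires"
    REQUIRES_AT_STATE = "requires_at_state"


@dataclass
class SentencePlan:
    family: SentenceFamily
    subject: str
    #: argument names; for enablers, optional "state " prefixes are applied
    #: via ``states`` entries aligned with ``arguments``
    arguments: tuple[str, ...] = ()
    states: tuple[Optional[str], ...] = ()

    def __post_init__(self) -> None:
        self.family = SentenceFamily(self.family)
        self.arguments = tuple(self.arguments)
        if not self.states:
            self.states = (None,) * len(self.arguments)
        self.states = tuple(self.states)


def _serial(items: list[str]) -> str:
    """Oxford-comma list: "A", "A and B", "A, B, and C"."""
    if len(items) == 1:
        return items[0]
    if len(items) == 2:
        return f"{items[0]} and {items[1]}"
    return ", ".join(items[:-1]) + f", and {items[-1]}"


def render_sentence(plan: SentencePlan) -> str:
    f = plan.family
    args = list(plan.arguments)
    if f in (SentenceFamily.CONSISTS_OF, SentenceFamily.CONSUMES,
             SentenceFamily.YIELDS, SentenceFamily.REQUIRES,
             SentenceFamily.REQUIRES_AT_STATE):
        if not args:
            raise ModelError("arity-mismatch", f"{f.value} needs at least one argument")
    decorated = [
        (f"{state} {name}" if state else name)
        for name, state in zip(args, plan.states)
    ]
    if f is SentenceFamily.CONSISTS_OF:
        return f"{plan.subject} consists of {_serial(args)}."
    if f is SentenceFamily.EXHIBITS:
        if len(args) != 1:
            raise ModelError("arity-mismatch", "exhibits takes exactly one attribute")
        return f"{plan.subject} exhibits {args[0]}."
    if f is SentenceFamily.CONSUMES:
        return f"{plan.subject} consumes {_serial(args)}."
    if f is SentenceFamily.YIELDS:
        return f"{plan.subject} yields {_serial(args)}."
    if f is SentenceFamily.YIELDS_AT_STATE:
        if len(args) != 2:
            raise ModelError("arity-mismatch", "yields_at_state takes (object, state)")
        return f"{plan.subject} yields {args[0]} at state {args[1]}."
    if f is SentenceFamily.CHANGES_FROM_TO:
        if len(args) != 3:
            raise ModelError(
                "arity-mismatch", "changes_from_to takes (object, from_state, to_state)"
            )
        return f"{plan.subject} changes {args[0]} from {args[1]} to {args[2]}."
    if f in (SentenceFamily.REQUIRES, SentenceFamily.REQUIRES_AT_STATE):
        return f"{plan.subject} requires {_serial(decorated)}."
    raise ModelError("arity-mismatch", f"unknown family {f!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Whole-model generation
# ---------------------------------------------------------------------------

def _visible_parts(model: Model, whole: str, visible: set[str]) -> list[str]:
    """Nearest visible transitive parts of *whole*, in edge insertion order."""
    out: list[str] = []

    def walk(node: str) -> None:
        for edge in model.parts_of(node):
            if edge.target in visible:
                if edge.target not in out:
                    out.append(edge.target)
            else:
                walk(edge.target)

    walk(whole)
    return out


def _ancestors_and_self(model: Model, process: str) -> list[str]:
    chain = [process]
    p = model.process(process)
    while p.parent is not None:
        chain.append(p.parent)
        p = model.process(p.parent)
    return chain


def _attributed_process(model: Model, process: str, visible: set[str]) -> Optional[str]:
    """Deepest visible process among *process* and its ancestors."""
    for candidate in _ancestors_and_self(model, process):
        if candidate in visible:
            return candidate
    return None


def opd_sentences(model: Model, opd: OPD) -> list[str]:
    visible = set(opd.visible_things)
    sentences: list[str] = []

    # -- structure ---------------------------------------------------------
    for name in opd.visible_things:
        thing = model.things.get(name)
        if not isinstance(thing, ObjectDef):
            continue
        parts = _visible_parts(model, name, visible - {name})
        if parts:
            sentences.append(
                render_sentence(SentencePlan(SentenceFamily.CONSISTS_OF, name, tuple(parts)))
            )
        for edge in model.structural_links:
            if (
                edge.kind is StructuralKind.EXHIBITION
                and edge.source == name
                and edge.target in visible
            ):
                sentences.append(
                    render_sentence(
                        SentencePlan(SentenceFamily.EXHIBITS, name, (edge.target,))
                    )
                )

    # -- behaviour ---------------------------------------------------------
    # Transformation links (consumption/result/effect pairs) are lifted to
    # the deepest visible ancestor of their process; enabler links render
    # only where their own process is visible.
    process_order = [
        n for n in opd.visible_things if isinstance(model.things.get(n), ProcessDef)
    ]
    order_index = {n: i for i, n in enumerate(process_order)}
    consumes: dict[str, list[str]] = {}
    yields_plain: dict[str, list[str]] = {}
    yields_state: dict[str, list[tuple[str, str]]] = {}
    changes: dict[str, list[tuple[str, str, str]]] = {}
    requires: dict[str, list[tuple[str, Optional[str]]]] = {}

    for proc in model.processes():
        shown = _attributed_process(model, proc.name, visible)
        if shown is None:
            continue
        pairs = effect_pairs(model, proc.name)
        paired = {obj for obj, _, _ in pairs}
        for obj, s1, s2 in pairs:
            if obj in visible:
                entry = (obj, s1, s2)
                if entry not in changes.setdefault(shown, []):
                    changes[shown].append(entry)
        for link in model.links_of(proc.name):
            if link.object_end not in visible or link.object_end in paired:
                continue
            if link.kind is ProceduralKind.CONSUMPTION:
                if link.object_end not in consumes.setdefault(shown, []):
                    consumes[shown].append(link.object_end)
            elif link.kind is ProceduralKind.RESULT:
                if link.state_qualifier is not None:
                    entry = (link.object_end, link.state_qualifier)
                    if entry not in yields_state.setdefault(shown, []):
                        yields_state[shown].append(entry)
                elif link.object_end not in yields_plain.setdefault(shown, []):
                    yields_plain[shown].append(link.object_end)
            elif link.kind in (ProceduralKind.INSTRUMENT, ProceduralKind.CONDITION):
                if proc.name == shown:  # enablers are level-local
                    entry = (link.object_end, link.state_qualifier)
                    if entry not in requires.setdefault(shown, []):
                        requires[shown].append(entry)

    for proc_name in sorted(
        set(consumes) | set(yields_plain) | set(yields_state) | set(changes) | set(requires),
        key=lambda n: order_index.get(n, len(order_index)),
    ):
        for objs in ([consumes[proc_name]] if proc_name in consumes else []):
            sentences.append(
                render_sentence(SentencePlan(SentenceFamily.CONSUMES, proc_name, tuple(objs)))
            )
        for obj, s1, s2 in changes.get(proc_name, []):
            sentences.append(
                render_sentence(
                    SentencePlan(SentenceFamily.CHANGES_FROM_TO, proc_name, (obj, s1, s2))
                )
            )
        for obj, state in yields_state.get(proc_name, []):
            sentences.append(
                render_sentence(
                    SentencePlan(SentenceFamily.YIELDS_AT_STATE, proc_name, (obj, state))
                )
            )
        if proc_name in yields_plain:
            sentences.append(
                render_sentence(
                    SentencePlan(SentenceFamily.YIELDS, proc_name,
                                 tuple(yields_plain[proc_name]))
                )
            )
        if proc_name in requires:
            names = tuple(n for n, _ in requires[proc_name])
            states = tuple(s for _, s in requires[proc_name])
            sentences.append(
                render_sentence(
                    SentencePlan(SentenceFamily.REQUIRES, proc_name, names, states)
                )
            )
    return sentences


def generate_opl(model: Model, opd_id: Optional[str] = None) -> str:
    """The OPL document: one sentence per line, diagrams in tree order, each
    introduced by a comment line naming the diagram.  ``opd_id`` restricts
    the output to a single diagram."""
    blocks: list[str] = []
    for opd in model.opds_in_tree_order():
        if opd_id is not None and opd.id != opd_id:
            continue
        sentences = opd_sentences(model, opd)
        if not sentences:
            continue
        blocks.append(f"# {opd.id}. {opd.title}" if opd.title else f"# {opd.id}")
        blocks.extend(sentences)
    return "\n".join(blocks) + ("\n" if blocks else "")
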