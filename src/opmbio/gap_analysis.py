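"""Knowledge-gap ledger, typology and execution-error suggestions.

A *knowledge gap* is a typed open question about the system: something the
model needs in order to execute completely and coherently but the
literature does not settle.  Gap types form a breadth hierarchy -- an
unknown mechanism (a whole set of unknown molecular functions) is wider
than an unknown molecular function, which is wider than an unknown
participating object, which is wider than an unknown temporal order.  Each
gap is phrased as a question, tagged with the molecular function it
concerns, and may point at a grey-marked *conjecture* element standing in
for the unknown biology until experiments settle it.

Gaps are found manually while modelling, or automatically when execution
errors reveal them: a missing association object points at an unresolved
recruitment order, and a wrong or unreachable state points at an
unmodelled molecular function or unknown object.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .execution import ErrorKind, Trace
from .model_core import LINK_ROLES, Model, ModelError, ObjectDef

__all__ = [
    "GapType",
    "AssociatedFunction",
    "Detection",
    "KnowledgeGap",
    "GapLedger",
    "record_gap",
    "summarize",
    "suggest_gaps_from_errors",
    "gap_report",
]


class GapType(str, Enum):
    UNKNOWN_MECHANISM = "unknown_mechanism"
    UNKNOWN_MOLECULAR_FUNCTION = "unknown_molecular_function"
    UNKNOWN_OBJECT = "unknown_object"
    UNKNOWN_TEMPORAL_ORDER = "unknown_temporal_order"

    @property
    def breadth(self) -> int:
        """Larger = wider gap."""
        order = [
            GapType.UNKNOWN_TEMPORAL_ORDER,
            GapType.UNKNOWN_OBJECT,
            GapType.UNKNOWN_MOLECULAR_FUNCTION,
            GapType.UNKNOWN_MECHANISM,
        ]
        return order.index(self)


class AssociatedFunction(str, Enum):
    BINDING = "binding"
    CATALYZING = "catalyzing"
    TRANSPORTING = "transporting"
    MISSING_MOLECULAR_FUNCTION = "missing_molecular_function"


class Detection(str, Enum):
    MANUAL = "manual"
    EXECUTION = "execution"


@dataclass
class KnowledgeGap:
    id: int
    question: str
    gap_type: GapType
    associated_function: AssociatedFunction
    linked_things: tuple[str, ...] = ()
    detection: Detection = Detection.MANUAL
    conjecture: Optional[str] = None  # name of a grey-marked stand-in element
    provenance: Optional[dict] = None  # for execution-suggested candidates

    def __post_init__(self) -> None:
        self.gap_type = GapType(self.gap_type)
        self.associated_function = AssociatedFunction(self.associated_function)
        self.detection = Detection(self.detection)
        self.linked_things = tuple(self.linked_things)


GapLedger = list  # a ledger is an ordered list of KnowledgeGap records


def record_gap(ledger: GapLedger, gap: KnowledgeGap, model: Optional[Model] = None) -> GapLedger:
    """Append *gap*, checking id uniqueness and (when a model is given) that
    linked things exist and any conjecture element is grey-marked."""
    if any(g.id == gap.id for g in ledger):
        raise ModelError("duplicate-id", f"gap id {gap.id} already recorded")
    if model is not None:
        for name in gap.linked_things:
            if name not in model.things:
                raise ModelError("dangling-thing", f"gap {gap.id}: unknown thing {name!r}")
        if gap.conjecture is not None:
            thing = model.things.get(gap.conjecture)
            if thing is None:
                raise ModelError(
                    "dangling-thing", f"gap {gap.id}: unknown conjecture {gap.conjecture!r}"
                )
            if not thing.conjecture:
                raise ModelError(
                    "conjecture-not-marked",
                    f"gap {gap.id}: {gap.conjecture!r} is not marked as a conjecture",
                )
    ledger.append(gap)
    return ledger


@dataclass
class GapSummary:
    total: int
    by_type: dict[str, int]
    by_type_percent: dict[str, int]
    by_function: dict[str, int]
    by_detection: dict[str, int]


def summarize(ledger: GapLedger) -> GapSummary:
    """Counts and integer-rounded percentages by type, function, detection."""
    total = len(ledger)
    by_type = Counter(g.gap_type.value for g in ledger)
    by_function = Counter(g.associated_function.value for g in ledger)
    by_detection = Counter(g.detection.value for g in ledger)
    percent = {
        t: int(round(100.0 * n / total)) if total else 0 for t, n in by_type.items()
    }
    return GapSummary(total, dict(by_type), percent, dict(by_function), dict(by_detection))


def suggest_gaps_from_errors(model: Model, trace: Trace) -> list[KnowledgeGap]:
    """Candidate gaps derived from execution errors (suggestions only; they
    are never auto-recorded).

    A *missing object* error on an association (link-set) object or a
    molecule suggests an unknown temporal order of the recruitment that
    should have produced it.  An *incorrect state* error suggests that no
    modelled molecular function drives the object into the required state:
    an unknown molecular function carried out by an unknown object.
    """
    candidates: list[KnowledgeGap] = []
    next_id = 1
    for err in trace.errors:
        provenance = {
            "process": err.process,
            "object": err.object,
            "tick": err.tick,
            "error_kind": err.kind.value,
        }
        obj = model.things.get(err.object)
        if err.kind is ErrorKind.MISSING_OBJECT:
            is_link_set = isinstance(obj, ObjectDef) and obj.role in LINK_ROLES
            what = "association" if is_link_set else "molecule"
            candidates.append(
                KnowledgeGap(
                    id=next_id,
                    question=(
                        f"When is the {what} {err.object} established relative to "
                        f"{err.process}?"
                    ),
                    gap_type=GapType.UNKNOWN_TEMPORAL_ORDER,
                    associated_function=AssociatedFunction.BINDING,
                    linked_things=(err.object,),
                    detection=Detection.EXECUTION,
                    provenance=provenance,
                )
            )
        else:
            candidates.append(
                KnowledgeGap(
                    id=next_id,
                    question=(
                        f"What molecular function transforms {err.object} to state "
                        f"{err.required_state}, and what molecule carries it out?"
                    ),
                    gap_type=GapType.UNKNOWN_MOLECULAR_FUNCTION,
                    associated_function=AssociatedFunction.CATALYZING,
                    linked_things=(err.object,),
                    detection=Detection.EXECUTION,
                    provenance=provenance,
                )
            )
        next_id += 1
    return candidates


def gap_report(ledger: GapLedger) -> list[tuple[int, str, str, str]]:
    """Table rows (id, gap_type, associated_function, question) in id order."""
    return [
        (g.id, g.gap_type.value, g.associated_function.value, g.question)
        for g in sorted(ledger, key=lambda g: g.id)
    ]


def gap_report_tsv(ledger: GapLedger) -> str:
    lines = ["id\tgap_type\tassociated_function\tquestion"]
    for row in gap_report(ledger):
        lines.append("\t".join(str(x) for x in row))
    return "\n".join(lines) + "\n"
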