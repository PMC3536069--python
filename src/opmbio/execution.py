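"""Synchronous, discrete-time qualitative execution of object-process models.

One instance exists per object.  Execution walks the process tree: inside
each in-zoomed frame the children run in ascending rank order, equal ranks
forming one concurrent step whose preconditions are all read against the
state at the start of the step ("reads before writes").  A process's
precondition is its preprocess object set -- every consumed or enabling
object must exist, some at a specific state; unsatisfied links combine into
two error kinds, *missing object* and *incorrect state*.

Two failure policies mirror the two enabler semantics: in **halt** mode an
unsatisfied precondition stops the run with a formatted error report; in
**skip** mode the failing process (with its whole subtree) is skipped and
execution continues, which is how perturbations such as the absence of an
environmental factor are analysed.

At initialization, systemic objects that no process creates start existent;
objects only created during execution start non-existent; stateful existent
objects take their declared initial state or, failing that, a seeded random
one; environmental objects are randomly existent or not (a seeded coin
flip), modelling external intervention, unless explicitly overridden.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .model_core import (
    Affiliation,
    LogicOperator,
    Model,
    ModelError,
    ObjectDef,
    ProceduralKind,
    ProceduralLink,
    ProcessDef,
    creation_links,
    effect_pairs,
    validate_model,
)

__all__ = [
    "ExecutionConfig",
    "RuntimeState",
    "ExecutionError",
    "ErrorKind",
    "Event",
    "Trace",
    "Outcome",
    "initialize",
    "derive_timeline",
    "evaluate_precondition",
    "fire",
    "run",
    "format_error",
    "parse_error_line",
]


class ErrorKind(str, Enum):
    MISSING_OBJECT = "missing_object"
    INCORRECT_STATE = "incorrect_state"


class Outcome(str, Enum):
    COMPLETED = "completed"
    HALTED = "halted"
    BUDGET_EXHAUSTED = "budget_exhausted"


@dataclass
class ExecutionConfig:
    mode: str = "halt"  # "halt" | "skip"
    seed: int = 0
    max_cycles: int = 100
    #: object name -> True (force existent) / False (force non-existent)
    environmental_overrides: dict[str, bool] = field(default_factory=dict)
    #: resample environmental objects at every top-level cycle (off by default)
    resample_environment: bool = False
    single_instance: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("halt", "skip"):
            raise ModelError("bad-mode", f"unknown execution mode {self.mode!r}")
        if self.max_cycles < 1:
            raise ModelError("bad-config", "max_cycles must be >= 1")


@dataclass
class ExecutionError:
    kind: ErrorKind
    process: str
    link_kind: str
    object: str
    required_state: Optional[str] = None
    tick: int = 0

    def __post_init__(self) -> None:
        self.kind = ErrorKind(self.kind)
        if self.kind is ErrorKind.INCORRECT_STATE and self.required_state is None:
            raise ModelError("bad-error", "incorrect_state requires required_state")


@dataclass
class Event:
    tick: int
    event: str
    element: str
    detail: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"tick": self.tick, "event": self.event, "element": self.element,
             "detail": self.detail},
            sort_keys=True,
        )


@dataclass
class Trace:
    events: list[Event] = field(default_factory=list)
    outcome: Optional[Outcome] = None
    errors: list[ExecutionError] = field(default_factory=list)
    final_runtime: Optional["RuntimeState"] = None

    def add(self, tick: int, event: str, element: str, **detail) -> None:
        self.events.append(Event(tick, event, element, detail))

    def to_jsonl(self) -> str:
        return "\n".join(e.to_json() for e in self.events) + "\n"

    def events_of(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.event == kind]


@dataclass
class RuntimeState:
    exists: dict[str, bool] = field(default_factory=dict)
    current_state: dict[str, Optional[str]] = field(default_factory=dict)
    clock: int = 0

    def state_of(self, obj: str) -> Optional[str]:
        return self.current_state.get(obj)

    def set_exists(self, obj: str, value: bool) -> None:
        self.exists[obj] = value
        if not value:
            self.current_state[obj] = None

    def check_invariants(self) -> None:
        for obj, state in self.current_state.items():
            if state is not None and not self.exists.get(obj, False):
                raise ModelError(
                    "runtime-invariant", f"{obj!r} has state {state!r} while non-existent"
                )


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def initialize(model: Model, config: ExecutionConfig) -> RuntimeState:
    rng = random.Random(config.seed)
    runtime = RuntimeState()
    for obj in model.objects():
        created_later = bool(creation_links(model, obj.name))
        if obj.affiliation is Affiliation.ENVIRONMENTAL:
            if obj.name in config.environmental_overrides:
                exists = config.environmental_overrides[obj.name]
            else:
                exists = rng.random() < 0.5
        elif obj.initially_existent is not None:
            exists = obj.initially_existent
        else:
            exists = not created_later
        runtime.exists[obj.name] = exists
        if exists and obj.states:
            if obj.initial_state is not None:
                runtime.current_state[obj.name] = obj.initial_state
            else:
                runtime.current_state[obj.name] = rng.choice(list(obj.states))
        else:
            runtime.current_state[obj.name] = None
    return runtime


# ---------------------------------------------------------------------------
# Timeline
# ---------------------------------------------------------------------------

def derive_timeline(model: Model, context_process: str) -> list[list[str]]:
    """Children of *context_process* as ordered groups of concurrent
    processes: sorted ascending by rank, equal ranks grouped together."""
    proc = model.process(context_process)
    by_rank: dict[int, list[str]] = {}
    for child in proc.children:
        by_rank.setdefault(model.process(child).rank, []).append(child)
    return [by_rank[r] for r in sorted(by_rank)]


# ---------------------------------------------------------------------------
# Precondition evaluation
# ---------------------------------------------------------------------------

def _link_satisfied(link: ProceduralLink, runtime: RuntimeState) -> Optional[ExecutionError]:
    """None if the pre-side link is satisfied, else the error it raises."""
    obj = link.object_end
    if not runtime.exists.get(obj, False):
        return ExecutionError(
            ErrorKind.MISSING_OBJECT, link.process_end, link.kind.value, obj,
            tick=runtime.clock,
        )
    if link.state_qualifier is not None and runtime.state_of(obj) != link.state_qualifier:
        return ExecutionError(
            ErrorKind.INCORRECT_STATE, link.process_end, link.kind.value, obj,
            required_state=link.state_qualifier, tick=runtime.clock,
        )
    return None


def evaluate_precondition(
    model: Model, process: str, runtime: RuntimeState
) -> list[ExecutionError]:
    """Errors preventing *process* from firing; empty means satisfied.

    Ungrouped pre-side links combine by AND.  Links in a logic group combine
    by the group's operator: OR needs at least one satisfied member, XOR
    exactly one.  Errors are reported for every failing ungrouped link and
    for every failing group, in link order.
    """
    pre_kinds = (ProceduralKind.CONSUMPTION, ProceduralKind.INSTRUMENT,
                 ProceduralKind.CONDITION)
    errors: list[ExecutionError] = []
    seen_groups: set[str] = set()
    for link in model.links_of(process):
        if link.kind not in pre_kinds:
            continue
        if link.group is None:
            err = _link_satisfied(link, runtime)
            if err is not None:
                errors.append(err)
            continue
        if link.group in seen_groups:
            continue
        seen_groups.add(link.group)
        group = model.logic_groups[link.group]
        members = [model.procedural_links[i] for i in group.members]
        member_errors = [_link_satisfied(m, runtime) for m in members]
        n_ok = sum(1 for e in member_errors if e is None)
        if group.operator is LogicOperator.AND:
            ok = n_ok == len(members)
        elif group.operator is LogicOperator.OR:
            ok = n_ok >= 1
        else:  # XOR
            ok = n_ok == 1
        if ok:
            continue
        failing = [e for e in member_errors if e is not None]
        if failing:
            errors.extend(failing)
        else:
            # XOR over-satisfied: exclusivity violated by the extra members
            extras = [m for m, e in zip(members, member_errors) if e is None][1:]
            for m in extras:
                errors.append(
                    ExecutionError(
                        ErrorKind.INCORRECT_STATE, process, m.kind.value, m.object_end,
                        required_state=m.state_qualifier or "absent (XOR exclusivity)",
                        tick=runtime.clock,
                    )
                )
    return errors


# ---------------------------------------------------------------------------
# Firing
# ---------------------------------------------------------------------------

class _Halt(Exception):
    def __init__(self, errors: list[ExecutionError]):
        self.errors = errors


class _BudgetExhausted(Exception):
    pass


def _apply_pre(model: Model, process: str, runtime: RuntimeState, trace: Trace) -> None:
    paired = {obj for obj, _, _ in effect_pairs(model, process)}
    for link in model.links_of(process):
        if link.kind is ProceduralKind.CONSUMPTION and link.object_end not in paired:
            if not runtime.exists.get(link.object_end, False):
                raise ModelError(
                    "postcondition-violation",
                    f"{process!r} consumed non-existent {link.object_end!r}",
                )
            runtime.set_exists(link.object_end, False)
            trace.add(runtime.clock, "object_consumed", link.object_end, process=process)


def _apply_post(model: Model, process: str, runtime: RuntimeState, trace: Trace) -> None:
    pairs = effect_pairs(model, process)
    paired = {obj for obj, _, _ in pairs}
    for obj, from_state, to_state in pairs:
        runtime.current_state[obj] = to_state
        trace.add(runtime.clock, "state_changed", obj,
                  process=process, from_state=from_state, to_state=to_state)
    for link in model.links_of(process):
        if link.kind is ProceduralKind.RESULT and link.object_end not in paired:
            already = runtime.exists.get(link.object_end, False)
            runtime.exists[link.object_end] = True
            if link.state_qualifier is not None:
                runtime.current_state[link.object_end] = link.state_qualifier
            elif not already:
                obj_def = model.things.get(link.object_end)
                if isinstance(obj_def, ObjectDef) and obj_def.states:
                    runtime.current_state[link.object_end] = (
                        obj_def.initial_state or obj_def.states[0]
                    )
            if not already:
                trace.add(runtime.clock, "object_created", link.object_end,
                          process=process,
                          state=runtime.current_state.get(link.object_end))
    # postcondition self-check: everything this process guarantees must hold
    for link in model.links_of(process):
        if link.kind is ProceduralKind.RESULT:
            if not runtime.exists.get(link.object_end, False):
                raise ModelError(
                    "postcondition-violation",
                    f"{process!r}: result object {link.object_end!r} does not exist",
                )
            if (
                link.object_end not in paired
                and link.state_qualifier is not None
                and runtime.state_of(link.object_end) != link.state_qualifier
            ):
                raise ModelError(
                    "postcondition-violation",
                    f"{process!r}: {link.object_end!r} not at {link.state_qualifier!r}",
                )
    for obj, _, to_state in pairs:
        if runtime.state_of(obj) != to_state:
            raise ModelError(
                "postcondition-violation", f"{process!r}: {obj!r} not at {to_state!r}"
            )
    runtime.check_invariants()


def fire(model: Model, process: str, runtime: RuntimeState, trace: Trace,
         config: Optional[ExecutionConfig] = None) -> None:
    """Fire *process*: apply consumptions, run children (if any) along the
    derived timeline, then apply results and state changes.

    The precondition is assumed satisfied (callers evaluate it first).
    """
    config = config or ExecutionConfig()
    runtime.clock += 1
    trace.add(runtime.clock, "process_started", process)
    _apply_pre(model, process, runtime, trace)
    proc = model.process(process)
    if proc.children:
        _run_timeline(model, process, runtime, trace, config,
                      budget={"cycles": config.max_cycles})
    _apply_post(model, process, runtime, trace)
    trace.add(runtime.clock, "process_finished", process)


def _run_timeline(
    model: Model,
    context: str,
    runtime: RuntimeState,
    trace: Trace,
    config: ExecutionConfig,
    budget: dict,
) -> None:
    timeline = derive_timeline(model, context)
    order = [p for group in timeline for p in group]
    index = 0
    while index < len(timeline):
        group = timeline[index]
        # reads before writes: evaluate the whole concurrent group first
        evaluated = [(p, evaluate_precondition(model, p, runtime)) for p in group]
        fired: list[str] = []
        for p, errors in evaluated:
            if errors:
                if config.mode == "halt":
                    trace.errors.extend(errors)
                    for e in errors:
                        e.tick = runtime.clock + 1
                        trace.add(runtime.clock + 1, "error_raised", p,
                                  kind=e.kind.value, object=e.object,
                                  link_kind=e.link_kind,
                                  required_state=e.required_state)
                    raise _Halt(errors)
                runtime.clock += 1
                trace.add(runtime.clock, "process_skipped", p,
                          reasons=[e.object for e in errors])
            else:
                fired.append(p)
        for p in fired:
            fire(model, p, runtime, trace, config)
        # invocation links: jump back to (or forward to) a sibling's slot
        jumped = False
        for p in fired:
            for link in model.procedural_links:
                if link.kind is ProceduralKind.INVOCATION and link.object_end == p:
                    target = link.process_end
                    if target in order:
                        budget["cycles"] -= 1
                        if budget["cycles"] <= 0:
                            raise _BudgetExhausted()
                        trace.add(runtime.clock, "invoked", target, by=p)
                        index = next(
                            i for i, g in enumerate(timeline) if target in g
                        )
                        jumped = True
                        break
            if jumped:
                break
        if not jumped:
            index += 1


def run(model: Model, config: ExecutionConfig) -> Trace:
    """Execute the model's root process tree under *config* and return the
    full trace, with outcome completed / halted / budget_exhausted."""
    violations = validate_model(model)
    if violations:
        raise ModelError(
            "invalid-model",
            "; ".join(str(v) for v in violations[:5]),
        )
    runtime = initialize(model, config)
    trace = Trace()
    roots = sorted(model.root_processes(), key=lambda p: p.rank)
    try:
        for root in roots:
            errors = evaluate_precondition(model, root.name, runtime)
            if errors:
                if config.mode == "halt":
                    trace.errors.extend(errors)
                    for e in errors:
                        e.tick = runtime.clock + 1
                        trace.add(runtime.clock + 1, "error_raised", root.name,
                                  kind=e.kind.value, object=e.object,
                                  link_kind=e.link_kind,
                                  required_state=e.required_state)
                    raise _Halt(errors)
                runtime.clock += 1
                trace.add(runtime.clock, "process_skipped", root.name,
                          reasons=[e.object for e in errors])
                continue
            fire(model, root.name, runtime, trace, config)
    except _Halt:
        trace.outcome = Outcome.HALTED
        trace.add(runtime.clock + 1, "halted", roots[0].name if roots else "")
    except _BudgetExhausted:
        trace.outcome = Outcome.BUDGET_EXHAUSTED
    else:
        trace.outcome = Outcome.COMPLETED
        trace.add(runtime.clock + 1, "completed", roots[0].name if roots else "")
    trace.final_runtime = runtime
    return trace


# ---------------------------------------------------------------------------
# Error formatting
# ---------------------------------------------------------------------------

def format_error(process: str, tick: int, errors: list[ExecutionError]) -> str:
    """Render a halt report in the canonical wording, e.g.::

        Process P failed to run (time = 3) for the following reasons:
        Instrument link is not satisfied because object X has no instances.
    """
    lines = [f"Process {process} failed to run (time = {tick}) for the following reasons:"]
    for e in errors:
        kind_word = e.link_kind.capitalize()
        if e.kind is ErrorKind.MISSING_OBJECT:
            lines.append(
                f"{kind_word} link is not satisfied because object {e.object} "
                f"has no instances."
            )
        else:
            lines.append(
                f"{kind_word} link is not satisfied because object {e.object} "
                f"has no instances at state {e.required_state}."
            )
    return "\n".join(lines)


_REASON_RE = re.compile(
    r"^(?P<link>\w+) link is not satisfied because object (?P<obj>.+?) "
    r"has no instances(?: at state (?P<state>.+?))?\.$"
)


def parse_error_line(line: str) -> tuple[ErrorKind, str, Optional[str]]:
    """Inverse of a :func:`format_error` reason line -> (kind, object, state)."""
    m = _REASON_RE.match(line.strip())
    if m is None:
        raise ModelError("unparseable-error", line)
    state = m.group("state")
    kind = ErrorKind.INCORRECT_STATE if state else ErrorKind.MISSING_OBJECT
    return kind, m.group("obj"), state
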