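"""Executor semantics: initialization, timelines, preconditions, firing,
halt/skip policies, determinism and the error report format."""

import itertools

import pytest

from opmbio import (
    ErrorKind,
    ExecutionConfig,
    Model,
    ModelError,
    ObjectDef,
    Outcome,
    ProceduralKind,
    ProceduralLink,
    ProcessDef,
    add_object,
    add_process,
    derive_timeline,
    evaluate_precondition,
    format_error,
    initialize,
    link,
    run,
)
from opmbio.execution import parse_error_line
from opmbio.fixtures import random_model
from opmbio.model_core import Affiliation, LogicOperator, add_logic_group


def test_initialize_existence_rules(transcription):
    cfg = ExecutionConfig(seed=0, environmental_overrides={"TFIIH": True})
    rt = initialize(transcription, cfg)
    assert rt.exists["TFIIB"] is True          # systemic, never created
    assert rt.exists["mRNA"] is False          # only created during execution
    assert rt.exists["Pre-Initiation Complex"] is False
    assert rt.exists["TFIIH"] is True          # forced
    assert rt.current_state["Serine 5"] == "dephosphorylated"
    assert rt.current_state["mRNA"] is None    # no state while non-existent


def test_initialize_empty_model():
    rt = initialize(Model(), ExecutionConfig(seed=0))
    assert rt.exists == {} and rt.current_state == {}


def test_environmental_sampling_unbiased():
    """Over 1000 seeds an unforced environmental object exists about half
    the time (binomial, p=0.5, within 3 sigma)."""
    m = Model()
    add_object(m, ObjectDef("Signal", affiliation=Affiliation.ENVIRONMENTAL))
    n = 1000
    k = sum(
        initialize(m, ExecutionConfig(seed=s)).exists["Signal"] for s in range(n)
    )
    sigma = (n * 0.25) ** 0.5
    assert abs(k - n / 2) <= 3 * sigma


def test_random_initial_state_is_seeded():
    m = Model()
    add_object(m, ObjectDef("X", states=("a", "b", "c")))  # no initial_state
    states = {initialize(m, ExecutionConfig(seed=s)).current_state["X"]
              for s in range(40)}
    assert states == {"a", "b", "c"}  # all reachable...
    assert (initialize(m, ExecutionConfig(seed=5)).current_state["X"]
            == initialize(m, ExecutionConfig(seed=5)).current_state["X"])  # ...reproducibly


def test_derive_timeline_orders_and_groups(transcription):
    assert derive_timeline(transcription, "Transcription Cycle") == [
        ["Re-initiation"], ["Elongation"], ["Termination"]]


def test_equal_ranks_form_concurrent_group():
    m = Model()
    add_process(m, ProcessDef("Ctx"))
    add_process(m, ProcessDef("P1", rank=0, parent="Ctx"))
    add_process(m, ProcessDef("P2", rank=0, parent="Ctx"))
    assert derive_timeline(m, "Ctx") == [["P1", "P2"]]


@pytest.mark.parametrize("seed", range(4))
def test_timeline_equals_stable_sort_oracle(seed):
    import random
    rng = random.Random(seed)
    m = Model()
    add_process(m, ProcessDef("Ctx"))
    ranks = {}
    for i in range(10):
        r = rng.randrange(4)
        add_process(m, ProcessDef(f"C{i}", rank=r, parent="Ctx"))
        ranks[f"C{i}"] = r
    flat = [p for group in derive_timeline(m, "Ctx") for p in group]
    assert flat == sorted(ranks, key=lambda n: ranks[n])


def test_precondition_empty_is_satisfied():
    m = Model()
    add_process(m, ProcessDef("P"))
    rt = initialize(m, ExecutionConfig(seed=0))
    assert evaluate_precondition(m, "P", rt) == []


@pytest.mark.parametrize("operator", [LogicOperator.AND, LogicOperator.OR,
                                      LogicOperator.XOR])
@pytest.mark.parametrize("n", [2, 3, 4])
def test_grouped_precondition_matches_truth_table(operator, n):
    """For every existence assignment of n grouped objects the evaluation
    equals the AND/OR/XOR truth table."""
    m = Model()
    add_process(m, ProcessDef("P"))
    for i in range(n):
        add_object(m, ObjectDef(f"O{i}"))
        link(m, ProceduralLink(ProceduralKind.INSTRUMENT, f"O{i}", "P"))
    add_logic_group(m, "g", operator, range(n))
    rt = initialize(m, ExecutionConfig(seed=0))
    for bits in itertools.product([False, True], repeat=n):
        for i, b in enumerate(bits):
            rt.exists[f"O{i}"] = b
        satisfied = evaluate_precondition(m, "P", rt) == []
        k = sum(bits)
        oracle = {LogicOperator.AND: k == n,
                  LogicOperator.OR: k >= 1,
                  LogicOperator.XOR: k == 1}[operator]
        assert satisfied == oracle, (operator, bits)


def test_ungrouped_links_all_reported(transcription):
    """The published two-error case: an enabling link set absent and the
    serine in the wrong state are both reported, in link order."""
    rt = initialize(transcription,
                    ExecutionConfig(seed=0, environmental_overrides={"TFIIH": True}))
    rt.exists["Pol II-TFIIH"] = False
    rt.exists["Serine 5"] = True
    rt.current_state["Serine 5"] = "phosphorylated"
    errors = evaluate_precondition(
        transcription, "Pol II.CTD.Serine 5 Phosphorylation", rt)
    assert [(e.kind, e.object) for e in errors] == [
        (ErrorKind.MISSING_OBJECT, "Pol II-TFIIH"),
        (ErrorKind.INCORRECT_STATE, "Serine 5"),
    ]
    assert errors[1].required_state == "dephosphorylated"


def test_fire_applies_consumption_creation_and_state_change(transcription):
    cfg = ExecutionConfig(mode="halt", seed=1, environmental_overrides={"TFIIH": True})
    trace = run(transcription, cfg)
    consumed = {e.element for e in trace.events_of("object_consumed")}
    assert "Elongators Nucleotide Subset" in consumed
    assert "Nucleotide Set" in consumed
    changed = [(e.element, e.detail["from_state"], e.detail["to_state"])
               for e in trace.events_of("state_changed")]
    assert ("mRNA", "capped", "elongated") in changed
    assert ("mRNA", "elongated", "mRNP") in changed


def test_process_without_postlinks_changes_nothing():
    m = Model()
    add_object(m, ObjectDef("A"))
    add_process(m, ProcessDef("Nop"))
    trace = run(m, ExecutionConfig(seed=0))
    assert trace.outcome is Outcome.COMPLETED
    assert trace.final_runtime.exists == {"A": True}
    kinds = {e.event for e in trace.events}
    assert kinds == {"process_started", "process_finished", "completed"}


@pytest.mark.parametrize("seed", range(5))
def test_no_state_without_existence_invariant(seed):
    """At every point in a run, an object has a current state only while it
    exists (state exclusivity is structural: one state slot per object)."""
    m = random_model(seed)
    trace = run(m, ExecutionConfig(mode="skip", seed=seed))
    rt = trace.final_runtime
    rt.check_invariants()
    for obj, state in rt.current_state.items():
        if state is not None:
            assert rt.exists[obj]


@pytest.mark.parametrize("mode", ["halt", "skip"])
def test_traces_deterministic_for_fixed_seed(transcription, mode):
    cfg = lambda: ExecutionConfig(mode=mode, seed=42)  # noqa: E731
    t1 = run(transcription, cfg())
    t2 = run(transcription, cfg())
    assert t1.to_jsonl() == t2.to_jsonl()
    assert t1.outcome == t2.outcome


def test_halt_trace_is_prefix_of_skip_trace(erroneous):
    cfg_halt = ExecutionConfig(mode="halt", seed=3,
                               environmental_overrides={"TFIIH": True})
    cfg_skip = ExecutionConfig(mode="skip", seed=3,
                               environmental_overrides={"TFIIH": True})
    halt_trace = run(erroneous, cfg_halt)
    skip_trace = run(erroneous, cfg_skip)
    assert halt_trace.outcome is Outcome.HALTED
    pre_failure = [e for e in halt_trace.events
                   if e.event not in ("error_raised", "halted")]
    skip_head = skip_trace.events[: len(pre_failure)]
    assert [e.to_json() for e in pre_failure] == [e.to_json() for e in skip_head]


def test_invocation_loop_bounded_by_budget():
    m = Model()
    add_object(m, ObjectDef("Fuel"))
    add_process(m, ProcessDef("Ctx"))
    add_process(m, ProcessDef("Step A", rank=0, parent="Ctx"))
    add_process(m, ProcessDef("Step B", rank=1, parent="Ctx"))
    # B re-invokes A unconditionally: an endless loop cut by the budget
    link(m, ProceduralLink(ProceduralKind.INVOCATION, "Step B", "Step A"))
    trace = run(m, ExecutionConfig(mode="halt", seed=0, max_cycles=5))
    assert trace.outcome is Outcome.BUDGET_EXHAUSTED
    assert len(trace.events_of("invoked")) == 4  # budget-1 completed jumps


def test_format_error_matches_canonical_wording():
    from opmbio.execution import ExecutionError
    errors = [
        ExecutionError(ErrorKind.MISSING_OBJECT, "P", "instrument", "Pol II-TFIIH"),
        ExecutionError(ErrorKind.INCORRECT_STATE, "P", "consumption", "Serine 5",
                       required_state="dephosphorylated"),
    ]
    text = format_error("Pol II.CTD.Serine 5 Phosphorylation", 17458, errors)
    assert text.splitlines()[0] == (
        "Process Pol II.CTD.Serine 5 Phosphorylation failed to run "
        "(time = 17458) for the following reasons:")
    assert ("Instrument link is not satisfied because object Pol II-TFIIH "
            "has no instances." in text)
    assert ("Consumption link is not satisfied because object Serine 5 "
            "has no instances at state dephosphorylated." in text)


def test_format_error_empty_is_header_only():
    text = format_error("P", 1, [])
    assert text == "Process P failed to run (time = 1) for the following reasons:"


def test_error_lines_round_trip():
    for line, expected in [
        ("Instrument link is not satisfied because object X has no instances.",
         (ErrorKind.MISSING_OBJECT, "X", None)),
        ("Consumption link is not satisfied because object Serine 5 "
         "has no instances at state dephosphorylated.",
         (ErrorKind.INCORRECT_STATE, "Serine 5", "dephosphorylated")),
    ]:
        assert parse_error_line(line) == expected


def test_run_rejects_invalid_model():
    m = Model()
    add_process(m, ProcessDef("P"))
    m.procedural_links.append(
        ProceduralLink(ProceduralKind.CONSUMPTION, "Ghost", "P"))
    with pytest.raises(ModelError, match="invalid-model"):
        run(m, ExecutionConfig(seed=0))


@pytest.mark.parametrize("seed", range(5))
def test_skip_mode_always_terminates(seed):
    trace = run(random_model(seed), ExecutionConfig(mode="skip", seed=seed,
                                                    max_cycles=10))
    assert trace.outcome in (Outcome.COMPLETED, Outcome.BUDGET_EXHAUSTED)
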