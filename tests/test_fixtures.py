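"""The packaged transcription-cycle reconstruction and its published totals."""

import pytest

from opmbio import (
    ExecutionConfig,
    Outcome,
    classify_process,
    model_statistics,
    run,
    show_all_appearances,
    validate_model,
)
from opmbio.fixtures import (
    build_toy_binding,
    build_transcription_erroneous,
    build_transcription_model,
    random_model,
)
from opmbio.gap_analysis import AssociatedFunction, Detection, GapType
from opmbio.model_core import Role, StructuralKind


def test_builders_are_deterministic():
    from opmbio.model_io import dumps_model
    assert dumps_model(build_transcription_model()) == dumps_model(
        build_transcription_model())
    assert dumps_model(build_transcription_erroneous()) == dumps_model(
        build_transcription_erroneous())


def test_transcription_statistics_match_published_counts(transcription):
    assert model_statistics(transcription).as_dict() == {
        "objects": 50, "processes": 37, "higher_level_processes": 13,
        "leaf_processes": 24, "tree_depth": 7}


def test_transcription_validates_clean(transcription):
    assert validate_model(transcription) == []


def test_mrna_appears_in_nine_diagrams(transcription):
    assert len(show_all_appearances(transcription, "mRNA")) == 9


def test_polymerase_declares_twelve_protein_parts(transcription):
    protein_parts = [
        l.target for l in transcription.parts_of("Polymerase II")
        if transcription.object(l.target).role is Role.PROTEIN
    ]
    assert len(protein_parts) == 12
    assert "Rpb1" in protein_parts


def test_ctd_aggregates_26_repeat_sets(transcription):
    assert [l.target for l in transcription.parts_of("Rpb1")] == ["CTD"]
    (edge,) = transcription.parts_of("CTD")
    assert edge.target == "Repeat Set"
    assert edge.multiplicity_lower() == 26


def test_every_leaf_classifies_to_a_molecular_function(transcription):
    classes = {
        classify_process(transcription, p.name)
        for p in transcription.processes() if not p.children
    }
    assert classes <= {"binding", "dissociation", "catalyzing_substrate_changed",
                       "catalyzing_substrate_consumed", "transporting"}
    # the three top-level families are all represented
    assert {"binding", "catalyzing_substrate_changed", "transporting"} <= classes


def test_environmental_tfiih(transcription):
    from opmbio.model_core import Affiliation
    assert transcription.object("TFIIH").affiliation is Affiliation.ENVIRONMENTAL
    assert transcription.object("TFIIB Kinase").conjecture is True


def test_corrected_model_completes_and_matures_mrna(transcription):
    trace = run(transcription, ExecutionConfig(
        mode="halt", seed=1, environmental_overrides={"TFIIH": True}))
    assert trace.outcome is Outcome.COMPLETED
    assert trace.final_runtime.current_state["mRNA"] == "mRNP"
    assert trace.final_runtime.current_state["RNA Location"] == "cytoplasm"
    assert trace.errors == []


def test_erroneous_variant_is_structurally_valid(erroneous):
    # the flaw is temporal, not structural
    assert validate_model(erroneous) == []
    assert model_statistics(erroneous).as_dict() == \
        model_statistics(build_transcription_model()).as_dict()


def test_erroneous_halt_reproduces_the_two_errors(erroneous):
    trace = run(erroneous, ExecutionConfig(
        mode="halt", seed=1, environmental_overrides={"TFIIH": True}))
    assert trace.outcome is Outcome.HALTED
    assert [e.process for e in trace.errors] == [
        "Pol II.CTD.Serine 5 Phosphorylation"] * 2
    assert [(e.kind.value, e.object) for e in trace.errors] == [
        ("missing_object", "Pol II-TFIIH"),
        ("incorrect_state", "Serine 5"),
    ]


def test_erroneous_skip_mode_skips_and_completes(erroneous):
    trace = run(erroneous, ExecutionConfig(
        mode="skip", seed=1, environmental_overrides={"TFIIH": True}))
    assert trace.outcome is Outcome.COMPLETED
    skipped = [e.element for e in trace.events_of("process_skipped")]
    assert "Pol II.CTD.Serine 5 Phosphorylation" in skipped


def test_gap_ledger_reproduces_published_rows(transcription):
    gaps = transcription.gaps
    assert len(gaps) == 17
    by_type = {
        GapType.UNKNOWN_TEMPORAL_ORDER: 8,
        GapType.UNKNOWN_OBJECT: 8,
        GapType.UNKNOWN_MOLECULAR_FUNCTION: 1,
    }
    for gtype, n in by_type.items():
        assert sum(1 for g in gaps if g.gap_type is gtype) == n
    by_function = {
        AssociatedFunction.BINDING: 12,
        AssociatedFunction.CATALYZING: 3,
        AssociatedFunction.TRANSPORTING: 1,
        AssociatedFunction.MISSING_MOLECULAR_FUNCTION: 1,
    }
    for func, n in by_function.items():
        assert sum(1 for g in gaps if g.associated_function is func) == n
    # only the TFIIB serine 65 dephosphorylation gap was execution-detected
    execution_detected = [g for g in gaps if g.detection is Detection.EXECUTION]
    assert [g.id for g in execution_detected] == [11]
    assert execution_detected[0].question == \
        "What molecule dephosphorylates TFIIB serine 65?"
    # a few verbatim rows
    questions = {g.id: g.question for g in gaps}
    assert questions[1] == "When is Rpb4/7 recruited to RNA Polymerase II?"
    assert questions[12] == "How is Fcp1 inhibited?"
    assert questions[14] == "What is the Ser7 kinase?"


def test_fact_ledger_has_32_entries(transcription):
    assert len(transcription.facts) == 32
    assert all(f.citation for f in transcription.facts)
    stubs = [f for f in transcription.facts if f.reconstructed]
    assert stubs and all(not f.statement for f in stubs)


def test_toy_binding_executes_to_complex():
    m = build_toy_binding()
    trace = run(m, ExecutionConfig(mode="halt", seed=0))
    assert trace.outcome is Outcome.COMPLETED
    assert trace.final_runtime.exists["A-B Complex"]
    assert trace.final_runtime.exists["A-to-B Link Set"]


@pytest.mark.parametrize("seed", range(8))
def test_random_model_always_valid(seed):
    m = random_model(seed)
    assert validate_model(m) == []
    s = model_statistics(m)
    assert s.higher_level_processes + s.leaf_processes == s.processes


def test_aggregation_forest_is_acyclic(transcription):
    import networkx as nx
    g = nx.DiGraph()
    for l in transcription.structural_links:
        if l.kind is StructuralKind.AGGREGATION:
            g.add_edge(l.source, l.target)
    assert nx.is_directed_acyclic_graph(g)
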