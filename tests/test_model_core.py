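"""Unit and property tests for the core model types and queries."""

import random

import pytest

from opmbio import (
    Model,
    ModelError,
    ObjectDef,
    ProceduralKind,
    ProceduralLink,
    ProcessDef,
    StructuralKind,
    StructuralLink,
    add_object,
    add_process,
    find,
    in_zoom,
    link,
    model_statistics,
    show_all_appearances,
    validate_model,
)
from opmbio.fixtures import random_model
from opmbio.model_core import OPD


def test_add_object_with_states():
    m = Model()
    add_object(m, ObjectDef("mRNA", states=("capped", "elongated", "mRNP")))
    assert m.object("mRNA").states == ("capped", "elongated", "mRNP")


def test_duplicate_name_rejected():
    m = Model()
    add_object(m, ObjectDef("X"))
    with pytest.raises(ModelError, match="duplicate-name"):
        add_object(m, ObjectDef("X"))
    with pytest.raises(ModelError, match="duplicate-name"):
        add_process(m, ProcessDef("X"))  # objects and processes share a namespace


def test_link_endpoint_and_state_checks():
    m = Model()
    add_object(m, ObjectDef("A", states=("on", "off")))
    add_process(m, ProcessDef("P"))
    with pytest.raises(ModelError, match="dangling-endpoint"):
        link(m, ProceduralLink(ProceduralKind.CONSUMPTION, "missing", "P"))
    with pytest.raises(ModelError, match="state-qualifier-unknown"):
        link(m, ProceduralLink(ProceduralKind.CONSUMPTION, "A", "P", state_qualifier="nope"))
    link(m, ProceduralLink(ProceduralKind.CONSUMPTION, "A", "P", state_qualifier="on"))
    assert len(m.procedural_links) == 1


def test_aggregation_cycle_rejected_and_detected():
    m = Model()
    for name in "AB":
        add_object(m, ObjectDef(name))
    link(m, StructuralLink(StructuralKind.AGGREGATION, "A", "B"))
    with pytest.raises(ModelError, match="aggregation-cycle"):
        link(m, StructuralLink(StructuralKind.AGGREGATION, "B", "A"))
    # force the cycle past the guarded constructor: the validator reports it
    m.structural_links.append(StructuralLink(StructuralKind.AGGREGATION, "B", "A"))
    assert any(v.rule == "aggregation-cycle" for v in validate_model(m))


def test_random_valid_inserts_validate_clean():
    rng = random.Random(7)
    m = Model()
    add_process(m, ProcessDef("Root"))
    names = []
    for i in range(100):
        name = f"Obj{i}"
        add_object(m, ObjectDef(name))
        names.append(name)
        if names[:-1] and rng.random() < 0.4:
            link(m, ProceduralLink(
                rng.choice([ProceduralKind.CONSUMPTION, ProceduralKind.INSTRUMENT,
                            ProceduralKind.RESULT]),
                name, "Root"))
    assert validate_model(m) == []


def test_dropped_endpoint_is_violation():
    for seed in range(5):
        m = random_model(seed)
        assert validate_model(m) == []
        # mutate: point one link at a non-existent thing
        rng = random.Random(seed)
        lnk = rng.choice(m.procedural_links)
        lnk.object_end = "Ghost Molecule"
        assert any(v.rule == "dangling-endpoint" for v in validate_model(m))


def test_in_zoom_creates_ordered_children_and_dotted_ids():
    m = Model()
    add_process(m, ProcessDef("Cycle"))
    m.opds["SD"] = OPD("SD", visible_things=["Cycle"])
    opd = in_zoom(m, "Cycle", [("First", 0), ("Second", 1), ("Third", 2)])
    assert opd.id == "SD1"
    assert m.process("Cycle").children == ["First", "Second", "Third"]
    assert m.process("Second").rank == 1


def test_in_zoom_empty_children():
    m = Model()
    add_process(m, ProcessDef("P"))
    m.opds["SD"] = OPD("SD", visible_things=["P"])
    opd = in_zoom(m, "P", [])
    assert opd.visible_things == ["P"]


def test_repeated_in_zoom_depth():
    m = Model()
    add_process(m, ProcessDef("L1"))
    m.opds["SD"] = OPD("SD", visible_things=["L1"])
    for level in range(2, 8):
        in_zoom(m, f"L{level - 1}", [(f"L{level}", 0)])
    assert model_statistics(m).tree_depth == 7
    assert "SD1.1.1.1.1.1" in m.opds


def test_find_on_empty_model():
    assert find(Model(), "anything") == []


def test_invalid_regex_pattern():
    with pytest.raises(ModelError, match="invalid-pattern"):
        find(Model(), "([", regex=True)


@pytest.mark.parametrize("seed", range(4))
def test_find_matches_bruteforce_enumeration(seed):
    m = random_model(seed)
    hits = find(m, ".*", {"object", "process"}, regex=True)
    expected = sum(
        sum(1 for t in opd.visible_things if t in m.things)
        for opd in m.opds.values()
    )
    assert len(hits) == expected


def test_show_all_appearances_consistent_with_find(transcription):
    for thing in ("mRNA", "Polymerase II", "Elongation"):
        appearances = show_all_appearances(transcription, thing)
        exact = [o for t, o in find(transcription, f"^{thing}$", regex=True)]
        assert appearances == exact


def test_show_all_appearances_unknown_thing(transcription):
    with pytest.raises(ModelError, match="thing-not-found"):
        show_all_appearances(transcription, "Mediator")


def test_statistics_empty_model():
    s = model_statistics(Model())
    assert s.as_dict() == {"objects": 0, "processes": 0,
                           "higher_level_processes": 0, "leaf_processes": 0,
                           "tree_depth": 0}


@pytest.mark.parametrize("seed", range(6))
def test_statistics_partition_identity(seed):
    s = model_statistics(random_model(seed))
    assert s.higher_level_processes + s.leaf_processes == s.processes


def test_conjecture_flag_is_metadata_only(transcription):
    # grey-marking an element never changes validation outcome
    m = transcription
    assert m.object("TFIIB Kinase").conjecture
    assert validate_model(m) == []
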