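"""Template expansion, classification and shape validation."""

import random

import pytest

from opmbio import (
    ExecutionConfig,
    Model,
    ModelError,
    MolecularFunction,
    MolecularFunctionSpec,
    ObjectDef,
    Role,
    StructuralKind,
    StructuralLink,
    add_object,
    classify_process,
    expand_binding,
    expand_catalyzing,
    expand_dissociation,
    expand_transporting,
    run,
    validate_model,
    validate_template,
)
from opmbio.model_core import ProceduralKind, add_process, ProcessDef


def _two_proteins():
    m = Model()
    add_object(m, ObjectDef("A", role=Role.PROTEIN))
    add_object(m, ObjectDef("B", role=Role.PROTEIN))
    return m


def test_expand_binding_flat_counts():
    m = _two_proteins()
    delta = expand_binding(m, "A", "B", "A-B Complex", "A-to-B Link Set")
    assert delta.objects == ["A-B Complex", "A-to-B Link Set"]
    assert len(delta.processes) == 1
    results = [m.procedural_links[i] for i in delta.procedural_links
               if m.procedural_links[i].kind is ProceduralKind.RESULT]
    assert len(results) == 2
    aggs = [m.structural_links[i] for i in delta.structural_links]
    assert len(aggs) == 2  # complex aggregates both partners
    assert {l.target for l in m.parts_of("A-B Complex")} == {"A", "B"}
    assert validate_model(m) == []
    assert validate_template(m, "A-B Complex") == []


def test_expand_binding_zoomed_structure():
    m = _two_proteins()
    delta = expand_binding(m, "A", "B", "A-B Complex", "A-to-B Link Set",
                           detail="zoomed")
    assert len(delta.processes) == 3
    parent = m.process("A and B Binding")
    gen, asm = parent.children
    assert m.process(gen).rank == 0 and m.process(asm).rank == 1
    assert "Link Set Generating" in gen and "Assembling" in asm
    assert validate_model(m) == []


def test_expand_binding_missing_partner_and_clash():
    m = _two_proteins()
    with pytest.raises(ModelError, match="partner-missing"):
        expand_binding(m, "A", "C", "X", "Y")
    expand_binding(m, "A", "B", "A-B Complex", "A-to-B Link Set")
    with pytest.raises(ModelError, match="name-clash"):
        expand_binding(m, "A", "B", "A-B Complex", "Other")


def test_binding_dissociation_roundtrip_restores_existence(toy_binding):
    m = toy_binding
    m.process("A and B Binding").rank = 0
    expand_dissociation(m, "A-B Complex", "A-to-B Link Set", rank=1)
    assert validate_model(m) == []
    trace = run(m, ExecutionConfig(mode="halt", seed=0))
    final = trace.final_runtime.exists
    # complex and link set consumed back to non-existence, partners restored
    assert final == {"A": True, "B": True,
                     "A-B Complex": False, "A-to-B Link Set": False}


def test_dissociation_on_k_partner_complex():
    rng = random.Random(3)
    for k in (2, 3, 5):
        m = Model()
        names = [f"P{i}" for i in range(k)]
        for n in names:
            add_object(m, ObjectDef(n, role=Role.PROTEIN))
        add_object(m, ObjectDef("Big Complex", role=Role.COMPLEX))
        add_object(m, ObjectDef("Big Link Set", role=Role.COMPLEX_LINK_SET))
        for n in names:
            m.structural_links.append(
                StructuralLink(StructuralKind.AGGREGATION, "Big Complex", n))
        delta = expand_dissociation(m, "Big Complex", "Big Link Set")
        results = [m.procedural_links[i] for i in delta.procedural_links
                   if m.procedural_links[i].kind is ProceduralKind.RESULT]
        assert len(results) == k


def test_catalyzing_same_state_rejected():
    m = Model()
    add_object(m, ObjectDef("S", states=("x", "y")))
    add_object(m, ObjectDef("E", role=Role.PROTEIN))
    with pytest.raises(ModelError, match="missing-state"):
        expand_catalyzing(m, MolecularFunctionSpec(
            MolecularFunction.CATALYZING_SUBSTRATE_CHANGED, "P",
            enzyme="E", substrates=("S",), from_state="x", to_state="x"))


def test_catalyzing_requires_enzyme():
    with pytest.raises(ModelError, match="missing-enzyme"):
        MolecularFunctionSpec(
            MolecularFunction.CATALYZING_SUBSTRATE_CHANGED, "P",
            substrates=("S",), from_state="x", to_state="y").validate()


@pytest.mark.parametrize("seed", range(3))
def test_classify_roundtrips_expanded_templates(seed):
    """Classification recovers the template used for the expansion, for a
    randomized batch of each template kind."""
    rng = random.Random(seed)
    m = Model()
    expected = {}
    for i in range(40):
        kind = rng.choice(["binding", "changed", "consumed", "transport"])
        if kind == "binding":
            a, b = f"A{i}", f"B{i}"
            add_object(m, ObjectDef(a, role=Role.PROTEIN))
            add_object(m, ObjectDef(b, role=Role.PROTEIN))
            expand_binding(m, a, b, f"C{i}", f"L{i}")
            expected[f"{a} and {b} Binding"] = "binding"
        elif kind == "changed":
            s, e = f"S{i}", f"E{i}"
            add_object(m, ObjectDef(s, states=("u", "v"), initial_state="u"))
            add_object(m, ObjectDef(e, role=Role.PROTEIN))
            expand_catalyzing(m, MolecularFunctionSpec(
                MolecularFunction.CATALYZING_SUBSTRATE_CHANGED, f"Chg{i}",
                enzyme=e, substrates=(s,), from_state="u", to_state="v"))
            expected[f"Chg{i}"] = "catalyzing_substrate_changed"
        elif kind == "consumed":
            s, e, p = f"F{i}", f"Z{i}", f"Q{i}"
            for n, r in ((s, Role.OTHER), (e, Role.PROTEIN), (p, Role.OTHER)):
                add_object(m, ObjectDef(n, role=r))
            expand_catalyzing(m, MolecularFunctionSpec(
                MolecularFunction.CATALYZING_SUBSTRATE_CONSUMED, f"Cons{i}",
                enzyme=e, substrates=(s,), products=(p,)))
            expected[f"Cons{i}"] = "catalyzing_substrate_consumed"
        else:
            c = f"G{i}"
            add_object(m, ObjectDef(c, role=Role.PROTEIN))
            expand_transporting(m, c, "nucleus", "cytoplasm", process_name=f"Mv{i}")
            expected[f"Mv{i}"] = "transporting"
    for name, want in expected.items():
        proc = m.process(name)
        if proc.children:
            assert classify_process(m, name) == "composite"
            for child in proc.children:
                assert classify_process(m, child) == want
        else:
            assert classify_process(m, name) == want


def test_classification_invariant_under_link_reordering(transcription):
    import copy
    m = copy.deepcopy(transcription)
    rng = random.Random(11)
    before = {p.name: classify_process(m, p.name) for p in m.processes()}
    rng.shuffle(m.procedural_links)
    after = {p.name: classify_process(m, p.name) for p in m.processes()}
    assert before == after


def test_process_with_no_links_unclassified():
    m = Model()
    add_process(m, ProcessDef("Idle"))
    assert classify_process(m, "Idle") == "unclassified"


def test_expand_transporting_same_compartment_rejected():
    m = Model()
    add_object(m, ObjectDef("X", role=Role.PROTEIN))
    with pytest.raises(ModelError, match="same-compartment"):
        expand_transporting(m, "X", "nucleus", "nucleus")


def test_transport_execution_moves_cargo():
    m = Model()
    add_object(m, ObjectDef("mRNP", role=Role.COMPLEX))
    expand_transporting(m, "mRNP", "nucleus", "cytoplasm")
    trace = run(m, ExecutionConfig(mode="halt", seed=0))
    assert trace.final_runtime.current_state["mRNP Location"] == "cytoplasm"


def test_polymerase_structure_template(transcription):
    assert validate_template(transcription, "Polymerase II") == []
    assert validate_template(transcription, "Rpb1") == []
    assert validate_template(transcription, "CTD") == []


def test_link_with_identical_endpoints_violates():
    m = Model()
    add_object(m, ObjectDef("L", role=Role.LINK))
    add_object(m, ObjectDef("Site", role=Role.BINDING_SITE))
    m.structural_links.append(
        StructuralLink(StructuralKind.UNIDIRECTIONAL, "L", "Site"))
    m.structural_links.append(
        StructuralLink(StructuralKind.UNIDIRECTIONAL, "L", "Site"))
    assert any(v.rule == "link-endpoints" for v in validate_template(m, "L"))


def test_complex_with_only_link_set_part_violates():
    m = Model()
    add_object(m, ObjectDef("C", role=Role.COMPLEX))
    add_object(m, ObjectDef("LS", role=Role.COMPLEX_LINK_SET))
    m.structural_links.append(StructuralLink(StructuralKind.AGGREGATION, "C", "LS"))
    assert any(v.rule == "template-empty-complex" for v in validate_template(m, "C"))


def test_tfiif_tfiib_link_hierarchy(tfiif_tfiib):
    m = tfiif_tfiib
    assert validate_model(m) == []
    for element in m.things:
        assert validate_template(m, element) == []
    # the complex link set decomposes into the protein-domain link set
    parts = [l.target for l in m.parts_of("TFIIF-to-TFIIB Complex Link Set")]
    assert parts == ["Tfg1-to-B-finger Protein-Domain Link Set"]


def test_deleting_aggregation_edge_breaks_template(tfiif_tfiib):
    import copy
    m = copy.deepcopy(tfiif_tfiib)
    # orphan the complex: drop all its molecular parts, keep the link set
    m.structural_links = [
        l for l in m.structural_links
        if not (l.source == "TFIIF-TFIIB Complex" and l.target in ("TFIIF", "TFIIB"))
    ]
    assert any(v.rule == "template-empty-complex"
               for v in validate_template(m, "TFIIF-TFIIB Complex"))
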