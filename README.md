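# opmbio

Qualitative, executable object-process models of molecular biology systems.

Molecular biologists accumulate mechanistic facts — "TFIIB binds Fcp1",
"TFIIH phosphorylates serine 5 of the Pol II CTD" — faster than anyone can
assemble them into a coherent picture. `opmbio` is a conceptual-modeling
engine for unifying such facts into one hierarchical, executable model: a
single description that carries both the system's **structure** (molecules,
complexes, domains, binding sites, and explicit association objects) and
its **behaviour** (processes that create, consume, and change the states of
those objects). Executing the model checks its temporal coherence and
surfaces what is still unknown as typed **knowledge gaps** — open questions
that point at the next experiment.

## The model

An object-process model is built from two primitives:

* **objects** — stateful things that exist: `mRNA` with states
  `{capped, elongated, mRNP}`, `Serine 5` with
  `{dephosphorylated, phosphorylated}`, an explicit `Pol II-TFIIH` link-set
  object recording a non-covalent association;
* **processes** — things that happen to objects, refined recursively by
  *in-zooming* into ordered sub-processes. The diagram tree this produces
  (`SD`, `SD1`, `SD1.1.1`, …) spans from a whole-cell function down to the
  leaves, where every process is one of three molecular functions:
  **catalyzing** (substrate consumed or substrate changed),
  **binding / dissociation**, and **transporting**.

Execution is synchronous, discrete and qualitative (one instance per
object). Within each in-zoomed frame, children run in ascending rank order;
equal ranks run concurrently. Each process has a precondition — its
preprocess object set: every consumed or enabling object must exist, some
at specific states, combined with AND/OR/XOR logic. In **halt** mode an
unsatisfied precondition stops the run and reports *missing object* /
*incorrect state* errors; in **skip** mode the process is skipped and the
run continues, which is how perturbations (a missing factor, a mutation)
are analysed. Environmental objects are randomly existent at
initialization, modelling external intervention.

Every model is also rendered deterministically into Object-Process Language
(OPL), a controlled subset of English, one sentence per link.

The package ships a worked reconstruction of the **mRNA transcription
cycle**: RNA polymerase II cycling through re-initiation, elongation and
termination, with pre-initiation complex assembly from the general
transcription factors, CTD serine 2/5/7 phosphorylation switches, nascent
RNA processing, Rpb4/7 recruitment and mRNP export — 50 objects and 37
processes (13 higher-level, 24 leaves) in a 7-level process tree, together
with its 17-row knowledge-gap ledger and a 32-entry fact ledger.

## Worked example

```bash
opmbio fixture transcription -o transcription.model
opmbio stats transcription.model
```

```
objects 50
processes       37
higher_level_processes  13
leaf_processes  24
tree_depth      7
```

Generate the natural-language view of the top-level diagram:

```bash
opmbio opl transcription.model --opd SD1
```

```
# SD1. Transcription Cycle in-zoomed
Nucleotide Set consists of Nascent RNA Builder Subset, Elongators Nucleotide Subset, and Cleaved Nucleotide Subset.
Polymerase II consists of Serine 2.
Re-initiation consumes Nascent RNA Builder Subset.
Re-initiation changes Serine 2 from dephosphorylated to phosphorylated.
Re-initiation yields mRNA at state capped.
Elongation consumes Elongators Nucleotide Subset.
Elongation changes mRNA from capped to elongated.
Elongation changes Spliceosome from free to mRNA-bound.
Elongation yields Cleaved Nucleotide Subset.
Elongation requires Spliceosome, TREX Complex, and phosphorylated Serine 2.
Termination consumes Nucleotide Set.
Termination changes mRNA from elongated to mRNP.
```

Execute the pre-correction variant, in which CTD serine 5 phosphorylation
is placed before TFIIH has been recruited:

```bash
opmbio fixture transcription-erroneous -o erroneous.model
opmbio run erroneous.model --mode halt --seed 1 --force TFIIH=existent
```

```
Process Pol II.CTD.Serine 5 Phosphorylation failed to run (time = 4) for the following reasons:
Instrument link is not satisfied because object Pol II-TFIIH has no instances.
Consumption link is not satisfied because object Serine 5 has no instances at state dephosphorylated.
```

(exit code 2 = halted). The first error is a *missing object* — the
Pol II–TFIIH association does not exist yet, a temporal ordering problem;
the second is an *incorrect state* — nothing has driven serine 5 to its
required dephosphorylated state, a missing molecular function.
`suggest_gaps_from_errors` turns exactly these two error kinds into
candidate knowledge-gap records. The corrected model runs to completion
with the mRNA ending at state `mRNP`:

```bash
opmbio fixture transcription -o transcription.model
opmbio run transcription.model --mode halt --seed 1 --force TFIIH=existent
# completed in 105 events
```

The knowledge-gap ledger:

```bash
opmbio gaps summarize transcription.model
```

```
total   17
type:unknown_molecular_function 1       6%
type:unknown_object     8       47%
type:unknown_temporal_order     8       47%
...
```

Library use mirrors the CLI: `fixtures.build_transcription_model()`,
`run(model, ExecutionConfig(...))`, `generate_opl(model)`,
`summarize(model.gaps)`, `expand_binding(...)` and friends.

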