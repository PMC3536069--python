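# Methods

## The modeling formalism

A model is a single namespace of *things*: objects (stateful, with a
biological role — Complex, Protein, Domain, BindingSite, the four levels of
association objects, NucleotideSet, Other) and processes (ranked,
hierarchically refined). Three structural relations are supported:
aggregation (part-of), exhibition (attribute) and the general
unidirectional relation; generalization links are deliberately omitted and
the loader rejects unknown kinds. Procedural links attach objects to
processes: consumption, result, effect, instrument, condition, invocation.
A state change is written canonically as a state-qualified consumption
paired with a state-qualified result on the same object and process; the
pair is applied atomically when the process finishes, and its from-state is
part of the precondition.

Diagram geometry is replaced by data. The vertical position that orders
execution in a drawn diagram becomes an integer **rank** per in-zoomed
frame (smaller = earlier, equal = concurrent), and each in-zoom appends a
diagram to the tree with the dotted id convention (`SD`, `SD1`,
`SD1.1.1`, …), children numbered in zoom order starting at 1.

### Structural templates

The containment chain Complex → Protein → Domain → BindingSite is mirrored
by a link hierarchy: a Link joins exactly two binding sites; Domain,
Protein and Complex Link Sets aggregate strictly lower link objects.
Selective refinement is first-class: a complex may omit its protein level
and list a domain directly, and a binding may produce only a protein- or
complex-level link set, because the finer structure is often unknown.
Participation counts are carried on aggregation edges as `a..b`
cardinalities (`m` = unbounded); the packaged model's CTD aggregates its
26 repeat sets as one Repeat Set object with cardinality 26, which is the
only reading consistent with the model's printed 50-object total.
Aggregation is required to be acyclic but *not* single-parent: the same
Polymerase II legitimately appears inside the pre-initiation complex and
inside the Pol II–Rpb4/7 complex, which are transient wholes.

### Molecular-function templates and classification

The three leaf-level function classes are written by `expand_*` helpers
(binding creates a complex plus a link-set object, enabled by its
partners; dissociation is its inverse and re-establishes the free
partners; catalyzing needs an enzyme instrument and either consumes
substrates into products or switches one substrate between two states;
transporting is a state change of an exhibited location attribute).
`classify_process` recovers the class from link shape alone — it inspects
effect pairs, enabler/consumption/result links and the roles of the
objects involved — so a hand-built model can be cross-checked against the
template it claims (`validate_template` compares declared annotation with
inferred shape). Precedence: transporting (changed object is an exhibited
attribute) before substrate-changed, dissociation before binding (a
dissociation re-creating complex-role partners would otherwise look like a
binding).

## Execution semantics

One instance per object; quantitative multiplicities are out of scope.
Initialization: systemic objects that no process creates start existent;
objects with an incoming (unpaired) result link start non-existent; an
explicit per-object `initially_existent` flag overrides the derivation
(used when a cyclic model both requires and re-creates an object — e.g. a
dissociation that re-establishes partners which clearly pre-exist).
Stateful existent objects take their declared initial state, else a seeded
random one. Environmental objects are existent with probability ½ (seeded
coin), unless forced by a config override; sampling happens once at
initialization (a per-cycle resampling flag exists but defaults off).

Execution walks the root process tree. A parent's consumptions apply at
its start, its results and state-change pairs at its end, children in
between along the rank timeline; a concurrent (equal-rank) group evaluates
all preconditions against the state at the start of the step before any
member fires (reads before writes), and validation rejects two same-rank
siblings consuming the same object. In halt mode a failing precondition
raises missing-object / incorrect-state errors, renders the canonical
report ("Process P failed to run (time = t) for the following reasons: …")
and stops; in skip mode the failing process is skipped *wholesale* —
its children are not individually attempted — and execution continues.
Enabler links are stored as authored; the halt/skip distinction is a
runtime policy, not a rewrite of the model. Invocation links re-enter the
target's slot in its frame's timeline, bounded by `max_cycles`; exhausting
the budget is a distinct outcome. The engine re-verifies every effect it
applied (postcondition self-check) and the structural invariant that a
non-existent object carries no state.

The `time = t` value in the error report is the engine's tick counter
(one tick per process attempt); the printed format is fixed, the value is
model-dependent.

Logic groups: ungrouped pre-side links combine by AND; OR needs ≥ 1
member, XOR exactly 1. A failing group reports its unsatisfied members;
an over-satisfied XOR (≥ 2 true) reports incorrect-state errors on the
extra members, since the two error kinds are exhaustive and halt mode
must print a reason.

## Natural-language (OPL) rendering

Sentences are emitted per diagram in tree order, structure before
behaviour, with the Oxford comma and fixed templates ("X consists of …",
"P consumes X.", "P changes X from s1 to s2.", "P requires …", with
state-qualified enablers as preposed adjectives: "phosphorylated
Serine 2"). Aggregation collapses to the visible level: a whole lists its
nearest visible transitive parts, so an abstracted diagram truthfully says
"Polymerase II consists of Serine 2" while the detailed diagrams spell out
the Rpb1 → CTD → Repeat Set chain. Transformation links are lifted to the
deepest visible ancestor of their process; enabler links render only where
their own process is visible (lifting them would pollute a parent's
"requires" sentence with its children's local enzymes). "P yields X at
state s." is an extrapolated template for state-specified creation — the
source material draws that state graphically without printing a sentence.
Rendering is deterministic and idempotent.

## Knowledge gaps

Gap records carry a question, a type from the breadth hierarchy
unknown mechanism > unknown molecular function > unknown object > unknown
temporal order, an associated molecular function, how they were detected
(manual while modeling, or from execution errors) and optionally a
grey-marked conjecture object standing in for the unknown (recording a gap
against a conjecture requires the model element to carry the conjecture
flag). `suggest_gaps_from_errors` maps the two execution error kinds to
candidates — missing object → recruitment-order (temporal) gap;
incorrect state → unmodelled molecular function / unknown object — with
provenance back to the trace; candidates are suggestions, never
auto-recorded. Summaries use nearest-integer percentages (8 of 17 → 47%).
The unknown-mechanism type does not occur in the packaged ledger (it
arises in wider systems); it is included for the hierarchy.

## The packaged reconstruction

The transcription-cycle builders are the package's test and acceptance
surface. The published totals — 50 objects, 37 processes (13 higher,
24 leaves), tree depth 7, 9 diagram appearances of mRNA, the 17-row gap
ledger with its type and function distribution, 12 Pol II protein
subunits, 26 CTD repeat sets — are treated as binding constraints, and the
five quoted OPL sentences must appear verbatim in the generated document.
The full element-by-element enumeration of the original model is not
published, so sub-process splits and auxiliary objects (the intermediate
link sets, the two location attributes, the Promoter) are reconstruction
choices, named systematically ("X-to-Y Link Set") and documented in the
fixture source; fact-ledger entries whose statements are not reproducible
are kept as citation-slot stubs flagged `reconstructed`, preserving the
32-entry count without inventing biology. Two deliberate coarsenings keep
the object count at the printed 50: spliceosome recruitment and mRNP
assembly are modeled as state switches (catalyzing-substrate-changed
shape) rather than explicit link-set bindings, and the serine 2 kinase is
approximated by TFIIH. The erroneous variant moves serine 5
phosphorylation ahead of pre-initiation complex formation and initializes
serine 5 phosphorylated, reproducing the published two-error halt; runs
that must be deterministic force the environmental TFIIH existent through
the config override.

What the fixtures do **not** emulate: quantitative kinetics, multiple
instances per molecule, chromatin/Mediator regulation, the first
(pioneering) transcription round, and real stochastic timing — passing
tests show the engine's qualitative semantics and the reconstruction's
consistency with the published counts, not kinetic fidelity. The random
model generator used by the property suites composes template expansions
under a bounded-depth process tree, so it exercises exactly the shapes the
expanders can produce.

## Numerical and procedural choices

* Seeding: every random draw goes through `random.Random(config.seed)`;
  fixed (model, config) gives byte-identical traces.
* Problem sizes in the test and acceptance runs: the full 50/37 fixture
  executes in ~100 events; property suites use 1000 seeds for the
  environmental-sampling binomial check (3σ band) and exhaustive 2^n
  enumeration for logic groups of n ≤ 4.
* Document format: YAML with a canonical key order; save → load → save is
  byte-identical. Serialized fixture documents are generated on demand
  (`opmbio fixture NAME -o …`) rather than shipped, so builders and
  documents cannot drift.
* Graph export: DOT emitted directly, GraphML through networkx; conjecture
  nodes are grey-filled, environmental objects double-bordered.

## Known limitations

Skip-mode semantics skip a failing parent's subtree wholesale; whether the
children should be attempted individually is genuinely underdetermined and
the other choice would change which downstream processes run. Effect pairs
apply at process end, so a concurrent sibling never observes a half-applied
state change, but a long-running parent's state change is not visible to
its own children. The find query matches substrings (or regexes) of thing
names per diagram, so name design matters for counting appearances.
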