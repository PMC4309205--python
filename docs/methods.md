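# Methods

## The modeling framework

`logimc` implements the multivalued logical (Thomas) formalism for
regulatory and signaling networks.  A model is a **logical regulatory
graph**: components `s_1 … s_n`, each with a discrete level in
`{0, …, max_i}` (Boolean when `max_i = 1`), connected by interactions
`(source, target, θ)` that are *effective* when `source ≥ θ` (with
`1 ≤ θ ≤ max_source`).  Each non-input component carries a logical rule
`K_i` mapping any combination of its regulators' levels to a target level.
**Input components** have no regulators and no rule; they stand for
environmental cues (cytokines, antigen presentation, …) whose value is
imposed from outside.

Rules are stored as explicit tables over the declared regulators.  The
table form makes the three operations the rest of the package needs cheap
and exact: evaluation at a state, enumeration of decision rows, and
substitution of one rule into another (the reduction primitive).  At the
scale this package targets (desk-scale networks and reduced versions of
larger ones) the explicit representation is never the bottleneck; a
decision-diagram backend could be substituted behind the same interface
without touching any caller.

### Dynamics

The semantics is the **fully asynchronous, unitary** update: in state `s`,
every internal component `i` with `K_i(s) ≠ s_i` may fire independently,
moving one level toward the target value.  Unitary stepping is the standard
multivalued convention (as in GINsim): a rule that calls a ternary
component from 0 to 2 produces the transition `0 → 1`, never a jump.  A
synchronous scheme (all called components step at once, one successor per
state) is also provided for comparison; all analysis modules use the
asynchronous scheme.

Stable states have out-degree zero in state transition graphs.  The
totalization that temporal-logic semantics usually applies to deadlocked
states is *not* done at the graph level; it is handled in the model-checking
module's deadlock conventions (below), which keeps the two concerns
separate.

Attractors are the terminal strongly connected components of the STG,
computed from the SCC condensation (networkx's iterative algorithm; SCC
ids follow reverse topological order so output is deterministic).  A
one-state terminal SCC without a self-transition is a stable state;
anything larger is a cyclic attractor.  Explicit graph construction is
guarded by a configurable cap (default `2^22` states); beyond that, the
stable-state enumerator and the labeled-transition-system route are the
supported paths.

### Interaction and circuit functionality

An interaction `(s_i, s_j, θ)` is **functional** if the target's rule
output differs between `s_i = θ` and `s_i = θ − 1` for at least one
combination of the remaining regulators.  Comparing exactly at the
threshold (rather than arbitrary effective/ineffective level pairs) is
sound here because the package enforces at most one interaction per
ordered component pair; multi-threshold multi-edges are rejected at
validation.  The derived sign is *activation* if every witnessed difference
raises the target, *inhibition* if every one lowers it, *dual* if both
occur.  Declared interactions that are functional in no context are
tolerated with a warning (documented interactions are often kept in curated
models even when the rules ignore them).

A regulatory circuit (elementary cycle) is *positive* or *negative*
according to the parity of inhibitions along it; positive circuits underlie
multistability, negative ones sustained oscillations.  Its **functionality
context** is computed edge-wise: for each circuit edge, the witnessing
contexts are projected onto the regulators external to the circuit
(existentially over circuit-internal regulators), and the per-edge external
contexts are then intersected over the union of external regulators.  An
empty context means the circuit never shapes the dynamics — the package
returns the empty context rather than raising, so callers can sweep all
circuits uniformly.

### Perturbations

Perturbations rewrite rules and return a new model: knock-out (constant
0), ectopic expression (constant level; applied to an input it becomes an
ordinary constant node), range restriction (outputs capped at a level),
and interaction suppression (the target's rule sees the source clamped to
`θ − 1`, leaving the source's own dynamics untouched).  Knock-out and
ectopic expression are idempotent; at most one perturbation may touch a
component per application.

### Model reduction

A non-self-regulated component is eliminated by substituting its rule into
every rule that mentions it, then re-deriving regulator lists from the
rewritten tables' support (vestigial dependencies vanish).  This conserves
the set of stable states exactly — the reduced model's fixed points are
the one-to-one projections of the original's — and, when only output
components are removed, attractor reachability as well.  Cyclic attractors
may in general be split or isolated by reduction; the package makes no
attempt to detect affected oscillations.  Removal proceeds in the order
given; a component that is (or has become, through earlier substitutions)
self-regulated aborts with a message naming it.  A used input cannot be
removed directly — fix it to a level first (`fix_inputs`), which partially
evaluates all rules and drops it.

## Input-labeled model checking

For networks driven by environmental inputs, every fixed input combination
confines the dynamics to its own disconnected region of the state space.
Instead of multiplying the state space by all input combinations, the
package builds one **labeled transition system** over internal states
only: each asynchronous transition carries the set of input valuations
enabling it.

Properties are expressed in **ARCTL** (action-restricted CTL): each
temporal operator takes an input restriction `α`, a propositional formula
over input atoms, and its path quantifier ranges over paths all of whose
transitions are enabled under `α`.  Two points of the semantics matter in
practice:

* `α` constrains transitions, not states, and the enabling valuation may
  differ from one transition to the next — so `EAF(true)(φ)` quantifies
  over trajectories in a freely varying environment, which is what makes
  "is there *any* (constant or varying) input schedule" queries
  expressible.
* **Deadlock convention:** at a state with no outgoing `α`-transition, an
  A-quantified next is vacuously true, an E-quantified next is false, and
  maximal finite `α`-paths are admitted for the G-operators.  Hence
  `AAG(e)(c)` holds at a stable state satisfying `c` — required for
  stability queries, since attractor states have no outgoing transitions
  under the fixed environment.  This is the natural totalization for
  these queries; operator-level agreement with other checkers on
  pathological deadlock cases is not guaranteed.

Satisfaction sets are computed by standard least/greatest fixpoints on the
`α`-restricted edge set (`EAF` as backward reachability, `AAG` by duality,
`EAG` as a greatest fixpoint admitting `α`-deadlocks, and the until
operators analogously).  A **whole-initial-set convention** governs
verdicts: a property holds iff *every* state satisfying the initial
predicate is in the satisfaction set; the counterexample is the set of
initial states outside it.  An empty initial set is reported as a vacuous
property, distinct from false.

## Stable states and phenotype classification

Stable states across *all* input combinations are enumerated without
building any STG: each internal component contributes the constraint
`K_i = s_i` (a set of satisfying assignments over the component and its
regulators), and the constraints are conjoined by a progressive join.
Stability is required of internal components only; inputs are free
parameters.  Identical internal profiles are grouped into one record with
the disjunction of their input contexts; an expansion flag flattens the
records to one row per (profile, input valuation) pair, which is the
"context-dependent stable state" count.  An independent brute-force sweep
over full states (`logimc.exhaustive`) cross-checks the enumerator in the
test batteries.

Stable profiles are classified against named **phenotype patterns**
(partial level assignments) by constraint subsumption, and annotated with
their active **master regulators** (level ≥ 1 — masters are Boolean in the
motivating models); a profile expressing two or more masters is a hybrid.

## Reprogramming graphs and strategies

The **reprogramming graph** abstracts plasticity: nodes are phenotype
patterns, and an arc `c1 —e→ c2` exists whenever
`EAF(e)(c2 ∧ AAG(e)(c2))` holds from every `c1`-state — under environment
`e`, every cell in pattern `c1` can reach pattern `c2` and be held there.
Self-arcs are computed and kept (they witness maintained stability; a
pattern lacking its own self-arc under its "own" environment is a real,
representable phenomenon).  Environments fix only their listed inputs;
unlisted inputs vary freely.  Patterns matching no state are reported and
kept as isolated nodes.

Multi-step **strategies** — sequences of (environment, intermediate
target) phases — compile to nested `EAF` operators, with `AAG` stability
required of the final target; the phase switch is modeled purely by
changing `α` between nesting levels, with no explicit switching-time
state.  `search_environments` enumerates all assignments of a candidate
input set over one or two phases (guarded), after a free-restriction
pre-check (`EAF(true)(c2)` from every source state) that short-circuits
hopeless searches.

## File formats and interfaces

* **mnet** — a line-oriented rule format: `input NAME : MAX` /
  `NAME : MAX` declarations and first-match clause rules
  `NAME := { cond : level ; … ; default : level }`.  Interactions and
  their thresholds/signs are derived from the rules' tables, so files
  carry no redundant edge list.  Metadata travels in `#!` annotation
  lines.
* **SBML-qual** — the community interchange format, read and written with
  lxml.  Function terms are interpreted first-match in document order
  only; models relying on SBML-qual's tolerance for multiple
  simultaneously-true terms are out of scope.  Declared thresholds and
  signs on transition inputs are honored when present.
* Component names are restricted to `[A-Za-z0-9_]`; names with Greek or
  special characters should be transliterated (e.g. RORGT, NFKB).
* Patterns, environments, and strategies are JSON side files; formulas use
  the text grammar (`EAF({IL12_e=1})(…)`, named patterns/environments,
  `INIT pred; formula` prefix).  GINsim's native XML is not parsed; models
  curated there can be exported to SBML-qual and loaded.

The command-line tool (`logimc`) is a thin layer over the library:
`validate`, `stable-states`, `attractors`, `reduce`, `perturb`, `check`,
`reprogram`, `strategies`, `fixtures`; exit codes 0 = success/true,
1 = property false, 2 = usage/parse error, 3 = resource guard.

## Fixtures, the random generator, and what the tests show

The hand-built fixtures have fully known behavior (computed by hand and
frozen in `tests/data/fixture_expected.json`, which a test regenerates
from the brute-force oracle): the input-gated TOGGLE switch (the worked
example), a two-node negative circuit (one cyclic attractor), a ternary
STEP component (unitary updating), and degenerate one-node models.
`th_demo` is a ten-node, hand-built, *synthetic* caricature of Th1/Th2
cross-regulation — antigen presentation plus the IL-12/Stat4/Tbet and
IL-4/Stat6/Gata3 branches with mutual master-regulator inhibition — useful
for demonstrations; it is not a published, curated model of T-helper
differentiation.

`random_model(n_components, n_inputs, max_levels, seed)` draws regulator
sets and rule tables uniformly at random (rules pruned to their support,
so derived interactions are exact) and is reproducible per seed.  It is
guarded to at most 2^12 binary-equivalent states so that every efficient
computation can be checked against exhaustive enumeration.  The test
batteries sweep ~200 such models per property at sizes of 2–4 internal
components, 0–2 inputs, and levels up to 2 — chosen so the exhaustive
oracles (full-state sweeps, all-pairs reachability, explicit path
enumeration with lasso detection) stay trivially cheap while still
exercising multivalued levels, unused regulators, deadlocked states, and
input-labeled edges.  What a green battery shows is *algorithmic
correctness on the covered model class*; random tables are not
biologically realistic wiring (no scale-free structure, no curated rule
shapes), and agreement on them says nothing about the biological adequacy
of any particular model.

## Numerical and design choices

* All enumerations (states, contexts, valuations) follow component
  declaration order; ties and output orders are fixed (lexicographic
  profiles, sorted arcs), so every run of every routine is deterministic.
* Set computation is explicit throughout; there are no floating-point
  quantities anywhere, so "agreement" in all cross-checks means set
  equality, not approximate equality.
* Range restriction caps a rule's *output*; the component keeps its
  declared maximum level.
* Known limitations: no hierarchical transition graphs, priority classes,
  timed or stochastic semantics; no cyclic-attractor detection without
  explicit STG construction; no fairness or full LTL; no automatic choice
  of reduction candidates; strategies searched exhaustively only up to two
  phases.
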