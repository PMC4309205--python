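# logimc

Multivalued logical regulatory models and the machinery to ask them
plasticity questions: asynchronous dynamics and attractors, exhaustive
stable-state enumeration across input combinations, stable-state-preserving
model reduction, action-restricted CTL (ARCTL) model checking over
input-labeled transition systems, and the synthesis of *reprogramming
graphs* connecting phenotype patterns under environmental conditions.

## Who this is for

Systems biologists working with discrete logical models of signaling and
transcriptional networks — the model class curated in tools like GINsim —
who want a scriptable way to answer questions such as: *which stable
expression patterns does this network support under each cytokine
environment?*  *Can a committed cell type be converted into another one,
and under which (constant or varying, one-step or two-step) input
conditions?*  *Which interactions and feedback circuits actually shape
the dynamics?*

## The formalism in brief

A model is a logical regulatory graph: components `s_i` with discrete
levels in `{0, …, max_i}`, interactions `(s_i, s_j, θ)` effective when
`s_i ≥ θ`, and one logical rule `K_j` per non-input component giving the
level the component is called toward in any state.  Input components
carry environmental cues and have no rules.  Dynamics are fully
asynchronous and unitary (one component, one level, per transition);
attractors are the terminal SCCs of the state transition graph.

Rather than folding inputs into the state vector, transitions are labeled
with the input valuations enabling them, giving a single transition
system over internal states.  Reachability questions are then ARCTL
formulas whose operators carry an input restriction `α`, e.g. the
reach-and-hold property behind every reprogramming-graph arc:

    INIT c1;  EAF(e)( c2 & AAG(e)(c2) )

— from every state matching pattern `c1`, some path using only
transitions enabled under environment `e` reaches a state matching `c2`
from which no `e`-path ever leaves `c2`.

See `docs/methods.md` for the full account (semantics, deadlock
conventions, reduction guarantees, limitations).

## Worked example

The built-in TOGGLE fixture is a mutual-inhibition switch gated by one
input: components `I` (input), `A`, `B`, with `K_A = I=1 & B=0` and
`K_B = A=0`.

    $ logimc fixtures --name toggle -o toggle.mnet
    $ logimc stable-states toggle.mnet
    A       B       input_context
    0       1       I=0 | I=1
    1       0       I=1

Two internal stable profiles, three context-dependent stable states: the
`B`-on state is stable under both input values, the `A`-on state only
while the input is present.

Reprogramming between the two phenotype patterns `PA = {A:1, B:0}` and
`PB = {A:0, B:1}` under the two environments `e0 = {I:0}`, `e1 = {I:1}`:

    $ cat p.json
    {"PA": {"A": 1, "B": 0}, "PB": {"A": 0, "B": 1}}
    $ cat e.json
    {"e0": {"I": 0}, "e1": {"I": 1}}
    $ logimc reprogram toggle.mnet --patterns p.json --envs e.json
    digraph reprograming {
      node [shape=ellipse];
      "PA";
      "PB";
      "PA" -> "PB" [label="e0"];
      "PA" -> "PA" [label="e1"];
      "PB" -> "PB" [label="e0"];
      "PB" -> "PB" [label="e1"];
    }

Withdrawing the input (`e0`) reprograms `PA` into `PB`; `PB` is stable
under both environments and can never be converted back — exactly the
asymmetry the single check confirms:

    $ logimc check toggle.mnet --patterns p.json --envs e.json \
        --formula "INIT PB; EAF(true)(PA)"
    {
      "holds": false,
      "initial_states": [
        {
          "A": 0,
          "B": 1
        }
      ],
      "counterexample": [
        {
          "A": 0,
          "B": 1
        }
      ]
    }

(exit status 1: the property is false; the deadlocked `PB` state is the
counterexample).

The same analyses are available as library calls
(`logimc.enumerate_stable_patterns`, `logimc.build_lts`, `logimc.check`,
`logimc.build_graph`, `logimc.search_environments`, …), which is the
convenient route for scripted sweeps.

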