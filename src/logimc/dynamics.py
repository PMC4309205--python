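"""State transition graphs, SCC condensation, and attractors.

States are tuples of levels over the model's *internal* components (in
declaration order); the input valuation is fixed per graph.  Under the fully
asynchronous scheme every component whose rule disagrees with its current
level may step independently, one unit toward the rule's target value
(unitary updating); under the synchronous scheme all such components step at
once.  Stable states have out-degree 0 — totalization needed by temporal
logic semantics is handled in :mod:`logimc.arctl`, not here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .model import LogicalModel

ASYNCHRONOUS = "asynchronous"
SYNCHRONOUS = "synchronous"

#: Explicit STG construction aborts beyond this many states; symbolic
#: routes (stable-state enumeration, ARCTL fixpoints) are the supported
#: path for larger models.
DEFAULT_STATE_CAP = 2**22

State = tuple[int, ...]

__all__ = [
    "State",
    "StateTransitionGraph",
    "Attractor",
    "StateCapExceeded",
    "successors",
    "build_stg",
    "full_stg",
    "condensation",
    "attractors",
    "state_from_dict",
    "state_to_dict",
    "stg_to_dot",
    "condensation_to_dot",
    "ASYNCHRONOUS",
    "SYNCHRONOUS",
    "DEFAULT_STATE_CAP",
]


class StateCapExceeded(RuntimeError):
    """Raised when explicit graph construction would exceed the state cap."""


def state_from_dict(model: LogicalModel, levels: Mapping[str, int]) -> State:
    return tuple(levels[n] for n in model.internal_names)

def state_to_dict(model: LogicalModel, state: State) -> dict[str, int]:
    return dict(zip(model.internal_names, state))


def _check_ranges(
    model: LogicalModel, state: State, inputs: Mapping[str, int]
) -> None:
    max_levels = model.max_levels
    for name, level in zip(model.internal_names, state):
        if not 0 <= level <= max_levels[name]:
            raise ValueError(f"level {level} out of range for {name}")
    for name in model.input_names:
        if name not in inputs:
            raise ValueError(f"missing input valuation for {name}")
        if not 0 <= inputs[name] <= max_levels[name]:
            raise ValueError(f"level {inputs[name]} out of range for input {name}")


def successors(
    model: LogicalModel,
    state: State | Mapping[str, int],
    inputs: Mapping[str, int],
    scheme: str = ASYNCHRONOUS,
) -> set[State]:
    """Successor states of ``state`` under the fixed input valuation.

    Asynchronous: one successor per internal component whose rule target
    differs from its current level, moving that component one unit toward
    the target.  Synchronous: a single successor moving all such components
    simultaneously.  A fixed point has no successors.
    """
    names = model.internal_names
    if isinstance(state, Mapping):
        state = tuple(state[n] for n in names)
    _check_ranges(model, state, inputs)
    env = dict(zip(names, state))
    env.update({n: inputs[n] for n in model.input_names})
    calls: list[tuple[int, int]] = []
    for i, name in enumerate(names):
        target = model.rules[name](env)
        if target != state[i]:
            step = 1 if target > state[i] else -1
            calls.append((i, step))
    if not calls:
        return set()
    if scheme == ASYNCHRONOUS:
        out = set()
        for i, step in calls:
            succ = list(state)
            succ[i] += step
            out.add(tuple(succ))
        return out
    if scheme == SYNCHRONOUS:
        succ = list(state)
        for i, step in calls:
            succ[i] += step
        return {tuple(succ)}
    raise ValueError(f"unknown updating scheme {scheme!r}")


@dataclass
class StateTransitionGraph:
    """An explicit STG over internal states for one input valuation."""

    graph: nx.DiGraph
    names: tuple[str, ...]
    input_context: dict[str, int]
    scheme: str

    @property
    def states(self) -> set[State]:
        return set(self.graph.nodes)

    @property
    def transitions(self) -> list[tuple[State, State]]:
        return sorted(self.graph.edges)


@dataclass(frozen=True)
class Attractor:
    """A terminal SCC: a single stable state or a cyclic attractor."""

    states: frozenset[State]
    kind: str  # "stable_state" | "cyclic"

    def __len__(self) -> int:
        return len(self.states)


def build_stg(
    model: LogicalModel,
    initial: Iterable[State | Mapping[str, int]],
    inputs: Mapping[str, int],
    scheme: str = ASYNCHRONOUS,
    state_cap: int = DEFAULT_STATE_CAP,
) -> StateTransitionGraph:
    """Explore the states reachable from ``initial`` under fixed inputs."""
    names = model.internal_names
    frontier: list[State] = []
    for s in initial:
        if isinstance(s, Mapping):
            s = tuple(s[n] for n in names)
        frontier.append(s)
    g = nx.DiGraph()
    g.add_nodes_from(frontier)
    seen = set(frontier)
    while frontier:
        state = frontier.pop()
        for succ in sorted(successors(model, state, inputs, scheme)):
            g.add_edge(state, succ)
            if succ not in seen:
                seen.add(succ)
                if len(seen) > state_cap:
                    raise StateCapExceeded(
                        f"state space too large (> {state_cap} states)"
                    )
                frontier.append(succ)
    return StateTransitionGraph(g, names, dict(inputs), scheme)


def full_stg(
    model: LogicalModel,
    inputs: Mapping[str, int],
    scheme: str = ASYNCHRONOUS,
    state_cap: int = DEFAULT_STATE_CAP,
) -> StateTransitionGraph:
    """STG over the complete internal state space for one input valuation."""
    names = model.internal_names
    max_levels = model.max_levels
    size = 1
    for n in names:
        size *= max_levels[n] + 1
    if size > state_cap:
        raise StateCapExceeded(f"state space too large (> {state_cap} states)")
    all_states = itertools.product(*(range(max_levels[n] + 1) for n in names))
    return build_stg(model, all_states, inputs, scheme, state_cap)


def condensation(stg: StateTransitionGraph) -> nx.DiGraph:
    """SCC condensation of the STG.

    Nodes carry ``members`` (frozenset of states) and a ``terminal`` flag;
    node ids follow reverse topological order for determinism.
    """
    sccs = sorted(
        (sorted(c) for c in nx.strongly_connected_components(stg.graph)),
        key=lambda c: c[0],
    )
    cond = nx.condensation(stg.graph, scc=sccs)
    order = list(reversed(list(nx.topological_sort(cond))))
    relabel = {old: new for new, old in enumerate(order)}
    cond = nx.relabel_nodes(cond, relabel)
    for node in cond.nodes:
        cond.nodes[node]["members"] = frozenset(cond.nodes[node]["members"])
        cond.nodes[node]["terminal"] = cond.out_degree(node) == 0
    return cond


def attractors(stg: StateTransitionGraph) -> list[Attractor]:
    """Terminal SCCs of the STG, classified stable versus cyclic."""
    cond = condensation(stg)
    out = []
    for node in sorted(cond.nodes):
        if not cond.nodes[node]["terminal"]:
            continue
        members = cond.nodes[node]["members"]
        if len(members) == 1:
            (state,) = members
            kind = (
                "stable_state" if stg.graph.out_degree(state) == 0 else "cyclic"
            )
        else:
            kind = "cyclic"
        out.append(Attractor(members, kind))
    out.sort(key=lambda a: sorted(a.states)[0])
    return out


def _state_label(names: Sequence[str], state: State) -> str:
    return "".join(str(v) for v in state) if len(names) > 1 else str(state[0])


def stg_to_dot(stg: StateTransitionGraph) -> str:
    """DOT rendering; stable states are double-circled."""
    lines = ["digraph STG {", '  node [shape=circle];']
    for state in sorted(stg.graph.nodes):
        label = _state_label(stg.names, state)
        shape = "doublecircle" if stg.graph.out_degree(state) == 0 else "circle"
        lines.append(f'  "{label}" [shape={shape}];')
    for a, b in stg.transitions:
        lines.append(
            f'  "{_state_label(stg.names, a)}" -> "{_state_label(stg.names, b)}";'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def condensation_to_dot(stg: StateTransitionGraph) -> str:
    """DOT rendering of the SCC graph; terminal SCCs are shaded."""
    cond = condensation(stg)
    lines = ["digraph SCC {", "  node [shape=box];"]
    for node in sorted(cond.nodes):
        members = sorted(cond.nodes[node]["members"])
        label = ",".join(_state_label(stg.names, s) for s in members)
        style = ' style=filled fillcolor=gray80' if cond.nodes[node]["terminal"] else ""
        lines.append(f'  {node} [label="{label}"{style}];')
    for a, b in sorted(cond.edges):
        lines.append(f"  {a} -> {b};")
    lines.append("}")
    return "\n".join(lines) + "\n"
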