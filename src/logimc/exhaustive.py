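"""Exhaustive cross-check routines.

Deliberately naive, independent implementations of the core computations:
fixed points by sweeping the full state space, attractors by all-pairs
reachability, and temporal-operator satisfaction by explicit path
enumeration with lasso detection.  They exist to validate the efficient
implementations on small models and are exercised by the test suite and the
acceptance batteries; they are not the supported route for real models.
"""

from __future__ import annotations

import itertools
from typing import TYPE_CHECKING, Mapping

from .dynamics import State, successors
from .model import LogicalModel

if TYPE_CHECKING:  # pragma: no cover
    from .arctl import LabeledTransitionSystem

__all__ = [
    "stable_full_states",
    "attractors_by_reachability",
    "eaf_by_paths",
    "eag_by_paths",
    "eau_by_paths",
]


def stable_full_states(model: LogicalModel) -> set[tuple[int, ...]]:
    """All fixed points as full states (internal + input levels).

    A full state is stable iff every internal rule returns the component's
    current level.  Returned tuples follow the model's declaration order.
    """
    names = model.names
    max_levels = model.max_levels
    out: set[tuple[int, ...]] = set()
    for combo in itertools.product(*(range(max_levels[n] + 1) for n in names)):
        env = dict(zip(names, combo))
        if all(model.rules[n](env) == env[n] for n in model.internal_names):
            out.add(combo)
    return out


def attractors_by_reachability(
    model: LogicalModel, inputs: Mapping[str, int]
) -> list[frozenset[State]]:
    """Terminal SCCs of the full asynchronous STG via reachable-set algebra.

    A state belongs to an attractor iff every state it can reach can reach
    it back; attractors are the equivalence classes of that relation.
    """
    names = model.internal_names
    max_levels = model.max_levels
    states = list(
        itertools.product(*(range(max_levels[n] + 1) for n in names))
    )
    succ = {s: successors(model, s, inputs) for s in states}
    reach: dict[State, frozenset[State]] = {}
    for s in states:
        seen = {s}
        frontier = [s]
        while frontier:
            t = frontier.pop()
            for u in succ[t]:
                if u not in seen:
                    seen.add(u)
                    frontier.append(u)
        reach[s] = frozenset(seen)
    out: set[frozenset[State]] = set()
    for s in states:
        if all(s in reach[t] for t in reach[s]):
            out.add(reach[s])
    return sorted(out, key=lambda a: sorted(a)[0])


# ---------------------------------------------------------------------------
# Path-enumeration oracles for ARCTL operators
# ---------------------------------------------------------------------------


def _alpha_succ(
    lts: "LabeledTransitionSystem", alpha_vals: frozenset
) -> dict[State, list[State]]:
    succ: dict[State, list[State]] = {s: [] for s in lts.states}
    for (a, b), label in lts.edges.items():
        if label & alpha_vals:
            succ[a].append(b)
    return succ


def eaf_by_paths(
    lts: "LabeledTransitionSystem", alpha_vals: frozenset, phi: set[State]
) -> set[State]:
    """States with some path over alpha-edges reaching phi (zero-length
    paths count)."""
    succ = _alpha_succ(lts, alpha_vals)
    out = set()
    for s in lts.states:
        seen = {s}
        frontier = [s]
        hit = False
        while frontier and not hit:
            t = frontier.pop()
            if t in phi:
                hit = True
                break
            for u in succ[t]:
                if u not in seen:
                    seen.add(u)
                    frontier.append(u)
        if hit:
            out.add(s)
    return out


def eag_by_paths(
    lts: "LabeledTransitionSystem", alpha_vals: frozenset, phi: set[State]
) -> set[State]:
    """States with some maximal alpha-path staying in phi forever.

    A witnessing path is either a lasso inside phi or a finite path inside
    phi ending at an alpha-deadlocked state.  Found by depth-first
    enumeration of simple paths through phi-states.
    """
    succ = _alpha_succ(lts, alpha_vals)

    def search(s: State, on_path: list[State]) -> bool:
        if s not in phi:
            return False
        if s in on_path:  # lasso closed within phi
            return True
        if not succ[s]:  # maximal finite path
            return True
        on_path.append(s)
        try:
            return any(search(u, on_path) for u in succ[s])
        finally:
            on_path.pop()

    return {s for s in lts.states if search(s, [])}


def eau_by_paths(
    lts: "LabeledTransitionSystem",
    alpha_vals: frozenset,
    phi: set[State],
    psi: set[State],
) -> set[State]:
    """States with some alpha-path through phi-states reaching psi."""
    succ = _alpha_succ(lts, alpha_vals)
    out = set()
    for s in lts.states:
        if s in psi:
            out.add(s)
            continue
        if s not in phi:
            continue
        seen = {s}
        frontier = [s]
        hit = False
        while frontier and not hit:
            t = frontier.pop()
            for u in succ[t]:
                if u in psi:
                    hit = True
                    break
                if u in phi and u not in seen:
                    seen.add(u)
                    frontier.append(u)
        if hit:
            out.add(s)
    return out
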