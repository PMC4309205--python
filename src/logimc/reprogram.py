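"""Reprogramming graphs and multi-step environment strategies.

A reprogramming graph abstracts the dynamics down to named phenotype
patterns: there is an arc from pattern ``c1`` to pattern ``c2`` labeled with
environment ``e`` whenever, from *every* state matching ``c1``, some path
using only transitions enabled under ``e`` reaches a state matching ``c2``
from which no ``e``-path can ever leave ``c2`` — i.e. the ARCTL property
``EAF(e)(c2 & AAG(e)(c2))`` holds on the whole initial set.

A strategy is a sequence of phases, each fixing an environment constraint
(unlisted inputs stay free) and an intermediate target; it compiles to
nested ``EAF`` operators with a stability requirement (``AAG``) on the
final phase.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .arctl import (
    Alpha,
    And,
    ATrue,
    CheckResult,
    Formula,
    LabeledTransitionSystem,
    Modal,
    TrueF,
    alpha_environment,
    atom_pattern,
    check,
    sat_set,
)
from .stable import PhenotypePattern

__all__ = [
    "ReprogramingGraph",
    "Strategy",
    "StrategyPhase",
    "build_graph",
    "check_strategy",
    "search_environments",
    "arc_property",
]


@dataclass(frozen=True)
class StrategyPhase:
    """One phase: an environment constraint and an intermediate target.

    ``environment`` fixes only the listed inputs; the rest vary freely
    within the phase.  ``target`` is a pattern constraint dict, or ``None``
    for "just apply the environment" (target true).
    """

    environment: Mapping[str, int]
    target: Mapping[str, int] | None = None


@dataclass(frozen=True)
class Strategy:
    phases: tuple[StrategyPhase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("a strategy needs at least one phase")


@dataclass
class ReprogramingGraph:
    """Nodes are phenotype-pattern names; arcs carry environment names."""

    nodes: tuple[str, ...]
    arcs: tuple[tuple[str, str, str], ...]  # (c1, environment, c2)
    empty_patterns: tuple[str, ...] = ()

    def aggregated(self) -> dict[tuple[str, str], tuple[str, ...]]:
        """One entry per (c1, c2) with all satisfying environments."""
        agg: dict[tuple[str, str], list[str]] = {}
        for c1, env, c2 in self.arcs:
            agg.setdefault((c1, c2), []).append(env)
        return {k: tuple(v) for k, v in sorted(agg.items())}

    def to_dot(self, include_self_arcs: bool = True) -> str:
        """Flat DOT export: one edge per (source, environment, target) arc."""
        lines = ["digraph reprograming {", "  node [shape=ellipse];"]
        for name in self.nodes:
            lines.append(f'  "{name}";')
        for c1, env, c2 in self.arcs:
            if c1 == c2 and not include_self_arcs:
                continue
            lines.append(f'  "{c1}" -> "{c2}" [label="{env}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        payload = {
            "nodes": list(self.nodes),
            "arcs": [
                {"from": c1, "environment": env, "to": c2}
                for c1, env, c2 in self.arcs
            ],
            "aggregated": [
                {"from": c1, "to": c2, "environments": list(envs)}
                for (c1, c2), envs in self.aggregated().items()
            ],
            "empty_patterns": list(self.empty_patterns),
        }
        return json.dumps(payload, indent=2) + "\n"

    def in_degree(self, node: str, count_self: bool = False) -> int:
        pairs = {
            (c1, c2)
            for c1, _, c2 in self.arcs
            if c2 == node and (count_self or c1 != c2)
        }
        return len(pairs)

    def out_degree(self, node: str, count_self: bool = False) -> int:
        pairs = {
            (c1, c2)
            for c1, _, c2 in self.arcs
            if c1 == node and (count_self or c1 != c2)
        }
        return len(pairs)


def _as_constraints(
    pattern: PhenotypePattern | Mapping[str, int]
) -> Mapping[str, int]:
    if isinstance(pattern, PhenotypePattern):
        return pattern.constraints
    return pattern


def arc_property(
    environment: Mapping[str, int] | Alpha, target: Mapping[str, int]
) -> Formula:
    """``EAF(e)(c2 & AAG(e)(c2))`` — reach the target and stay there."""
    alpha: Alpha = (
        alpha_environment(environment)
        if isinstance(environment, Mapping)
        else environment
    )
    goal = atom_pattern(target)
    return Modal("EAF", alpha, And(goal, Modal("AAG", alpha, goal)))


def build_graph(
    lts: LabeledTransitionSystem,
    patterns: Iterable[PhenotypePattern],
    environments: Mapping[str, Mapping[str, int]],
) -> ReprogramingGraph:
    """Evaluate the arc property for every ordered pattern pair and every
    environment (self-arcs included: they witness maintained stability)."""
    patterns = list(patterns)
    empty = []
    matchable = []
    for pat in patterns:
        states = sat_set(lts, atom_pattern(pat.constraints))
        if states:
            matchable.append(pat)
        else:
            empty.append(pat.name)
    arcs = []
    for c1 in matchable:
        init = atom_pattern(c1.constraints)
        for env_name in sorted(environments):
            env = environments[env_name]
            for c2 in matchable:
                result = check(lts, init, arc_property(env, c2.constraints))
                if result.holds:
                    arcs.append((c1.name, env_name, c2.name))
    arcs.sort()
    return ReprogramingGraph(
        tuple(p.name for p in patterns), tuple(arcs), tuple(empty)
    )


def compile_strategy(strategy: Strategy) -> Formula:
    """Nested ARCTL formula: each phase ``EAF(e_k)(target_k & <next>)``;
    the final phase requires ``AAG(e_n)(target_n)`` stability."""
    formula: Formula | None = None
    for k in reversed(range(len(strategy.phases))):
        phase = strategy.phases[k]
        alpha = alpha_environment(phase.environment)
        last = k == len(strategy.phases) - 1
        if phase.target is None:
            if last:
                raise ValueError("the final phase must name a target pattern")
            body: Formula = TrueF()
        else:
            body = atom_pattern(phase.target)
            if last:
                body = And(body, Modal("AAG", alpha, body))
        if formula is not None:
            body = formula if isinstance(body, TrueF) else And(body, formula)
        formula = Modal("EAF", alpha, body)
    assert formula is not None
    return formula


def check_strategy(
    lts: LabeledTransitionSystem,
    init: PhenotypePattern | Mapping[str, int],
    strategy: Strategy,
) -> tuple[CheckResult, list[frozenset]]:
    """Evaluate a strategy from ``init``; also report, per phase, the states
    from which the remaining phases can still succeed (phase witnesses)."""
    constraints = _as_constraints(init)
    suffixes = [
        compile_strategy(Strategy(strategy.phases[k:]))
        for k in range(len(strategy.phases))
    ]
    witnesses = [frozenset(sat_set(lts, f)) for f in suffixes]
    result = check(lts, atom_pattern(constraints), suffixes[0])
    return result, witnesses


def search_environments(
    lts: LabeledTransitionSystem,
    c1: PhenotypePattern | Mapping[str, int],
    c2: PhenotypePattern | Mapping[str, int],
    candidate_inputs: Sequence[str],
    max_phases: int = 1,
    guard: int = 4096,
) -> list[Strategy]:
    """Exhaustively test candidate-input assignments over 1 or 2 phases.

    Returns the strategies whose compiled formula holds from every
    ``c1``-state.  A free-restriction existence pre-check (can ``c2`` be
    reached and held at all, with inputs varying arbitrarily?) short-circuits
    the enumeration when it already fails.
    """
    if max_phases not in (1, 2):
        raise ValueError("max_phases must be 1 or 2")
    for name in candidate_inputs:
        if name not in lts.input_names:
            raise KeyError(f"unknown input {name}")
    src = _as_constraints(c1)
    dst = _as_constraints(c2)

    free = check(lts, atom_pattern(src), Modal("EAF", ATrue(), atom_pattern(dst)))
    if not free.holds:
        return []

    ranges = [
        range(lts.input_ranges[lts.input_names.index(n)] + 1)
        for n in candidate_inputs
    ]
    assignments = [
        dict(zip(candidate_inputs, combo))
        for combo in itertools.product(*ranges)
    ]
    n_strategies = len(assignments) ** max_phases
    if n_strategies > guard:
        raise RuntimeError(
            f"enumeration guard exceeded ({n_strategies} > {guard} strategies)"
        )
    out = []
    if max_phases == 1:
        candidates = [Strategy((StrategyPhase(a, dst),)) for a in assignments]
    else:
        candidates = [
            Strategy((StrategyPhase(a1, None), StrategyPhase(a2, dst)))
            for a1 in assignments
            for a2 in assignments
        ]
    for strategy in candidates:
        result, _ = check_strategy(lts, src, strategy)
        if result.holds:
            out.append(strategy)
    return out
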