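"""Stable-state enumeration across all input combinations, and phenotype
classification.

Stability is required only of internal components: inputs carry no rules and
act as free parameters.  Enumeration does not sweep the full state space;
instead the per-component stability conditions ``K_i = s_i`` (each a set of
cubes over the component and its regulators) are conjoined by a progressive
join, so the cost tracks the constraint structure rather than the product of
all level ranges.  A brute-force sweep lives in :mod:`logimc.exhaustive` as
the independent cross-check.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import LogicalModel

__all__ = [
    "StablePattern",
    "PhenotypePattern",
    "Classification",
    "enumerate_stable_patterns",
    "count_context_dependent",
    "expand_stable_states",
    "classify",
    "stable_patterns_to_tsv",
    "classification_to_json",
]

Cube = tuple[tuple[str, int], ...]  # sorted (input name, level) pairs


@dataclass(frozen=True)
class StablePattern:
    """One internal fixed-point profile with its stability input contexts.

    ``internal_levels`` follows the model's internal component order.
    ``input_contexts`` is a tuple of cubes: assignments over the inputs that
    appear in some rule.  Inputs regulating nothing are unconstrained and
    are only materialized by :func:`expand_stable_states`.
    """

    names: tuple[str, ...]
    internal_levels: tuple[int, ...]
    input_contexts: tuple[Cube, ...]

    def levels(self) -> dict[str, int]:
        return dict(zip(self.names, self.internal_levels))

    def context_expression(self) -> str:
        """Human-readable disjunction of the stability contexts."""
        if not self.input_contexts:
            return "false"
        if self.input_contexts == ((),):
            return "true"
        terms = []
        for cube in self.input_contexts:
            terms.append(" & ".join(f"{n}={v}" for n, v in cube) or "true")
        return " | ".join(terms)


@dataclass(frozen=True)
class PhenotypePattern:
    """A named partial state assignment (a phenotype marker pattern)."""

    name: str
    constraints: Mapping[str, int]

    def matches(self, levels: Mapping[str, int]) -> bool:
        return all(levels.get(n) == v for n, v in self.constraints.items())


def _stability_cubes(
    model: LogicalModel, component: str
) -> tuple[tuple[str, ...], list[tuple[int, ...]]]:
    """Assignments over {component} ∪ regulators satisfying K_i = s_i."""
    rule = model.rules[component]
    max_levels = model.max_levels
    vars_ = (component,) + tuple(r for r in rule.regulators if r != component)
    cubes = []
    for combo in itertools.product(*(range(max_levels[v] + 1) for v in vars_)):
        env = dict(zip(vars_, combo))
        if rule(env) == env[component]:
            cubes.append(combo)
    return vars_, cubes


def enumerate_stable_patterns(model: LogicalModel) -> list[StablePattern]:
    """All context-dependent stable states, grouped by internal profile.

    Complete and exact: a full state is covered iff every internal rule
    fixes its component, for the input levels recorded in the contexts.
    """
    internal = model.internal_names
    if not internal:
        return []
    # progressive join of per-component stability constraints
    solutions: list[dict[str, int]] = [{}]
    for comp in internal:
        vars_, cubes = _stability_cubes(model, comp)
        joined: list[dict[str, int]] = []
        for sol in solutions:
            for combo in cubes:
                row = dict(zip(vars_, combo))
                if all(sol.get(k, v) == v for k, v in row.items()):
                    merged = dict(sol)
                    merged.update(row)
                    joined.append(merged)
        solutions = joined
        if not solutions:
            return []
    used_inputs = tuple(
        n for n in model.input_names if any(n in s for s in solutions)
    )
    grouped: dict[tuple[int, ...], set[Cube]] = {}
    for sol in solutions:
        profile = tuple(sol[n] for n in internal)
        cube: Cube = tuple((n, sol[n]) for n in used_inputs if n in sol)
        grouped.setdefault(profile, set()).add(cube)
    out = [
        StablePattern(internal, profile, tuple(sorted(cubes)))
        for profile, cubes in grouped.items()
    ]
    out.sort(key=lambda p: p.internal_levels)
    return out


def expand_stable_states(
    model: LogicalModel, patterns: Iterable[StablePattern]
) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Flatten to one row per (internal profile, full input valuation)."""
    input_names = model.input_names
    max_levels = model.max_levels
    rows = []
    for pat in patterns:
        seen: set[tuple[int, ...]] = set()
        for cube in pat.input_contexts:
            fixed = dict(cube)
            free = [n for n in input_names if n not in fixed]
            for combo in itertools.product(
                *(range(max_levels[n] + 1) for n in free)
            ):
                val = dict(zip(free, combo))
                val.update(fixed)
                full = tuple(val[n] for n in input_names)
                if full not in seen:
                    seen.add(full)
                    rows.append((pat.internal_levels, full))
    rows.sort()
    return rows


def count_context_dependent(model: LogicalModel) -> int:
    """Number of (internal profile, input valuation) stable pairs."""
    return len(expand_stable_states(model, enumerate_stable_patterns(model)))


@dataclass
class Classification:
    pattern: StablePattern
    phenotypes: tuple[str, ...]  # names of matching phenotype patterns
    active_masters: tuple[str, ...]
    hybrid_order: int

    @property
    def unclassified(self) -> bool:
        return not self.phenotypes

    @property
    def hybrid(self) -> bool:
        return self.hybrid_order >= 2


def classify(
    stable: Iterable[StablePattern],
    patterns: Iterable[PhenotypePattern],
    masters: Iterable[str] = (),
) -> list[Classification]:
    """Annotate stable patterns with matching phenotypes and active masters.

    A phenotype matches by constraint subsumption; a master regulator counts
    as active at level >= 1; a hybrid expresses two or more masters.
    """
    patterns = list(patterns)
    masters = tuple(masters)
    out = []
    for sp in stable:
        levels = sp.levels()
        hits = tuple(p.name for p in patterns if p.matches(levels))
        active = tuple(m for m in masters if levels.get(m, 0) >= 1)
        out.append(Classification(sp, hits, active, len(active)))
    return out


def stable_patterns_to_tsv(
    model: LogicalModel,
    patterns: Sequence[StablePattern],
    expand_contexts: bool = False,
) -> str:
    """TSV table: one row per stable pattern (or per input valuation)."""
    internal = model.internal_names
    if expand_contexts:
        header = list(internal) + list(model.input_names)
        lines = ["\t".join(header)]
        for profile, inputs in expand_stable_states(model, patterns):
            lines.append("\t".join(str(v) for v in profile + inputs))
    else:
        header = list(internal) + ["input_context"]
        lines = ["\t".join(header)]
        for pat in patterns:
            row = [str(v) for v in pat.internal_levels]
            row.append(pat.context_expression())
            lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def classification_to_json(rows: Sequence[Classification]) -> str:
    payload = []
    for row in rows:
        payload.append(
            {
                "levels": row.pattern.levels(),
                "input_context": row.pattern.context_expression(),
                "phenotypes": list(row.phenotypes) or ["unclassified"],
                "active_masters": list(row.active_masters),
                "hybrid_order": row.hybrid_order,
            }
        )
    return json.dumps(payload, indent=2) + "\n"
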