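"""Multivalued logical regulatory graphs.

A logical regulatory graph (LRG) is a set of components, each carrying a
discrete activity level in ``{0, ..., max_level}``, connected by thresholded
interactions.  Every non-input component owns a logical rule giving the level
it is called toward in any state.  Input components have no regulators and no
rule: their value is imposed by the environment.

This module covers model definition and validation, perturbations (knock-out,
ectopic expression, range restriction, interaction suppression), and the
static functionality analysis of interactions and regulatory circuits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import networkx as nx

ACTIVATION = "activation"
INHIBITION = "inhibition"
DUAL = "dual"
NONE = "none"
UNKNOWN = "unknown"

__all__ = [
    "Component",
    "Interaction",
    "LogicalRule",
    "LogicalModel",
    "Perturbation",
    "FunctionalityReport",
    "ValidationReport",
    "validate_model",
    "apply_perturbation",
    "interaction_functionality",
    "circuit_functionality",
    "regulatory_circuits",
    "derive_interactions",
    "fix_inputs",
    "ACTIVATION",
    "INHIBITION",
    "DUAL",
    "NONE",
    "UNKNOWN",
]


@dataclass(frozen=True)
class Component:
    """A regulatory component with levels ``0..max_level``.

    ``is_input`` marks environment-controlled components: they have no
    regulators and no rule, and their value is fixed per environmental
    condition (or carried on transition labels, see :mod:`logimc.arctl`).
    """

    name: str
    max_level: int = 1
    is_input: bool = False

    @property
    def levels(self) -> range:
        return range(self.max_level + 1)


@dataclass(frozen=True)
class Interaction:
    """A regulatory interaction, effective when ``source >= threshold``."""

    source: str
    target: str
    threshold: int = 1
    declared_sign: str = UNKNOWN

    def __str__(self) -> str:  # pragma: no cover - display only
        return f"{self.source}->{self.target}@{self.threshold}"


class LogicalRule:
    """Total mapping from regulator-level combinations to a target level.

    Stored as an explicit table keyed by tuples of regulator levels in
    declared regulator order.  The table form supports the three contract
    operations: evaluation at a state, enumeration of decision rows, and
    substitution of a regulator by another rule (used by model reduction).
    """

    __slots__ = ("target", "regulators", "table")

    def __init__(
        self,
        target: str,
        regulators: Sequence[str],
        table: Mapping[tuple[int, ...], int],
    ) -> None:
        self.target = target
        self.regulators = tuple(regulators)
        self.table = dict(table)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_function(
        cls,
        target: str,
        regulators: Sequence[str],
        max_levels: Mapping[str, int],
        fn: Callable[[Mapping[str, int]], int],
    ) -> "LogicalRule":
        """Tabulate ``fn`` over all combinations of regulator levels."""
        regulators = tuple(regulators)
        ranges = [range(max_levels[r] + 1) for r in regulators]
        table = {}
        for combo in itertools.product(*ranges):
            table[combo] = int(fn(dict(zip(regulators, combo))))
        return cls(target, regulators, table)

    @classmethod
    def constant(cls, target: str, level: int) -> "LogicalRule":
        return cls(target, (), {(): int(level)})

    # -- evaluation -------------------------------------------------------

    def __call__(self, state: Mapping[str, int]) -> int:
        key = tuple(state[r] for r in self.regulators)
        return self.table[key]

    def rows(self) -> Iterator[tuple[dict[str, int], int]]:
        """Iterate decision rows as ``(regulator assignment, level)``."""
        for combo in sorted(self.table):
            yield dict(zip(self.regulators, combo)), self.table[combo]

    # -- rewriting --------------------------------------------------------

    def restricted(self, assignment: Mapping[str, int]) -> "LogicalRule":
        """Partially evaluate the rule, dropping the fixed regulators."""
        fixed = {r: assignment[r] for r in self.regulators if r in assignment}
        if not fixed:
            return self
        keep = [r for r in self.regulators if r not in fixed]
        idx = [self.regulators.index(r) for r in keep]
        table: dict[tuple[int, ...], int] = {}
        for combo, value in self.table.items():
            if all(combo[self.regulators.index(r)] == v for r, v in fixed.items()):
                table[tuple(combo[i] for i in idx)] = value
        return LogicalRule(self.target, keep, table)

    def with_source_clamped(self, regulator: str, cap: int) -> "LogicalRule":
        """Evaluate as if ``regulator`` never exceeded ``cap``.

        This models suppression of the interaction with threshold ``cap+1``:
        the target's rule sees the source clamped below its threshold while
        the source's own dynamics are untouched.
        """
        if regulator not in self.regulators:
            return self
        i = self.regulators.index(regulator)
        table = {}
        for combo in self.table:
            key = list(combo)
            key[i] = min(key[i], cap)
            table[combo] = self.table[tuple(key)]
        return LogicalRule(self.target, self.regulators, table)

    def with_output(self, fn: Callable[[int], int]) -> "LogicalRule":
        return LogicalRule(
            self.target, self.regulators, {k: int(fn(v)) for k, v in self.table.items()}
        )

    def substituted(
        self, regulator: str, inner: "LogicalRule", max_levels: Mapping[str, int]
    ) -> "LogicalRule":
        """Replace ``regulator`` by ``inner``'s target value.

        The rewritten rule ranges over the former regulators (minus the
        substituted one) joined with ``inner``'s regulators; this is the core
        step of component elimination in model reduction.
        """
        if regulator not in self.regulators:
            return self
        new_regs = [r for r in self.regulators if r != regulator]
        for r in inner.regulators:
            if r not in new_regs:
                new_regs.append(r)
        ranges = [range(max_levels[r] + 1) for r in new_regs]
        table = {}
        for combo in itertools.product(*ranges):
            env = dict(zip(new_regs, combo))
            env[regulator] = inner(env)
            table[combo] = self(env)
        return LogicalRule(self.target, new_regs, table)

    def support(self) -> tuple[str, ...]:
        """Regulators the table actually depends on, in declared order."""
        keep = []
        for i, reg in enumerate(self.regulators):
            groups: dict[tuple[int, ...], set[int]] = {}
            for combo, value in self.table.items():
                rest = combo[:i] + combo[i + 1 :]
                groups.setdefault(rest, set()).add(value)
            if any(len(vs) > 1 for vs in groups.values()):
                keep.append(reg)
        return tuple(keep)

    def pruned(self) -> "LogicalRule":
        """Drop regulators outside the support."""
        keep = self.support()
        if keep == self.regulators:
            return self
        idx = [self.regulators.index(r) for r in keep]
        table: dict[tuple[int, ...], int] = {}
        for combo, value in self.table.items():
            table[tuple(combo[i] for i in idx)] = value
        return LogicalRule(self.target, keep, table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LogicalRule):
            return NotImplemented
        return (
            self.target == other.target
            and self.regulators == other.regulators
            and self.table == other.table
        )

    def __hash__(self) -> int:
        return hash((self.target, self.regulators, tuple(sorted(self.table.items()))))

    def __repr__(self) -> str:  # pragma: no cover - display only
        return f"LogicalRule({self.target!r}, regulators={self.regulators!r})"


class LogicalModel:
    """A multivalued logical regulatory graph.

    Holds an ordered collection of components, the thresholded interactions,
    and one rule per non-input component.  Declaration order of components is
    the canonical iteration order for all enumerations, so every downstream
    computation is deterministic.
    """

    def __init__(
        self,
        components: Sequence[Component],
        rules: Iterable[LogicalRule],
        interactions: Sequence[Interaction] | None = None,
        metadata: Mapping[str, object] | None = None,
    ) -> None:
        self.components: tuple[Component, ...] = tuple(components)
        self.rules: dict[str, LogicalRule] = {r.target: r for r in rules}
        if interactions is None:
            interactions = derive_interactions(self.components, self.rules)
        self.interactions: tuple[Interaction, ...] = tuple(interactions)
        self.metadata: dict[str, object] = dict(metadata or {})

    # -- views ------------------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components if c.is_input)

    @property
    def internal_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components if not c.is_input)

    @property
    def max_levels(self) -> dict[str, int]:
        return {c.name: c.max_level for c in self.components}

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def rule(self, name: str) -> LogicalRule:
        return self.rules[name]

    def state_space_size(self) -> int:
        size = 1
        for c in self.components:
            size *= c.max_level + 1
        return size

    def iter_input_valuations(self) -> Iterator[dict[str, int]]:
        names = self.input_names
        ranges = [range(self.component(n).max_level + 1) for n in names]
        for combo in itertools.product(*ranges):
            yield dict(zip(names, combo))

    def iter_full_states(self) -> Iterator[dict[str, int]]:
        ranges = [c.levels for c in self.components]
        for combo in itertools.product(*ranges):
            yield dict(zip(self.names, combo))

    def interaction(self, source: str, target: str) -> Interaction:
        for i in self.interactions:
            if i.source == source and i.target == target:
                return i
        raise KeyError(f"{source}->{target}")

    def regulators_of(self, target: str) -> tuple[str, ...]:
        rule = self.rules.get(target)
        return rule.regulators if rule is not None else ()

    # -- equality ---------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LogicalModel):
            return NotImplemented
        return (
            self.components == other.components
            and set(self.interactions) == set(other.interactions)
            and self.rules == other.rules
        )

    def __hash__(self) -> int:  # models are mutable in principle; id-hash
        return id(self)

    def __repr__(self) -> str:  # pragma: no cover - display only
        return (
            f"LogicalModel({len(self.components)} components, "
            f"{len(self.interactions)} interactions)"
        )

    def replace(
        self,
        components: Sequence[Component] | None = None,
        rules: Iterable[LogicalRule] | None = None,
        interactions: Sequence[Interaction] | None = None,
        metadata: Mapping[str, object] | None = None,
    ) -> "LogicalModel":
        return LogicalModel(
            self.components if components is None else components,
            self.rules.values() if rules is None else rules,
            interactions,
            self.metadata if metadata is None else metadata,
        )


def derive_interactions(
    components: Sequence[Component], rules: Mapping[str, LogicalRule]
) -> tuple[Interaction, ...]:
    """Recover the interactions implied by the rules.

    A regulator contributes an interaction iff the rule output changes when
    it crosses some level; the threshold is the smallest such level and the
    sign is read off the direction of the changes (activation, inhibition, or
    dual when both directions occur).
    """
    max_levels = {c.name: c.max_level for c in components}
    out: list[Interaction] = []
    order = {c.name: i for i, c in enumerate(components)}
    for target in sorted(rules, key=lambda t: order.get(t, len(order))):
        rule = rules[target]
        for reg in rule.regulators:
            i = rule.regulators.index(reg)
            threshold = None
            rises = falls = False
            for combo, value in rule.table.items():
                if combo[i] == 0:
                    continue
                below = list(combo)
                below[i] -= 1
                prev = rule.table[tuple(below)]
                if value != prev:
                    if threshold is None or combo[i] < threshold:
                        threshold = combo[i]
                    if value > prev:
                        rises = True
                    else:
                        falls = True
            if threshold is None:
                continue
            if rises and falls:
                sign = DUAL
            elif rises:
                sign = ACTIVATION
            else:
                sign = INHIBITION
            out.append(Interaction(reg, target, threshold, sign))
    return tuple(out)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_model(model: LogicalModel) -> ValidationReport:
    """Structural validation: thresholds, rule totality, declared-vs-used
    regulators, duplicate names, out-of-range rule outputs."""
    report = ValidationReport()
    names = [c.name for c in model.components]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            report.errors.append(f"duplicate component name: {n}")
        seen.add(n)
    max_levels = {c.name: c.max_level for c in model.components}

    for c in model.components:
        if c.max_level < 1:
            report.errors.append(f"component {c.name}: max_level must be >= 1")
        if c.is_input and c.name in model.rules:
            report.errors.append(f"input component {c.name} must not carry a rule")
        if not c.is_input and c.name not in model.rules:
            report.errors.append(f"component {c.name} has no rule")

    pairs: set[tuple[str, str]] = set()
    triples: set[tuple[str, str, int]] = set()
    for i in model.interactions:
        if i.source not in seen:
            report.errors.append(f"interaction {i}: unknown source {i.source}")
            continue
        if i.target not in seen:
            report.errors.append(f"interaction {i}: unknown target {i.target}")
            continue
        if not 1 <= i.threshold <= max_levels[i.source]:
            report.errors.append(
                f"interaction {i}: threshold exceeds source max "
                f"(threshold {i.threshold}, max_{i.source} = {max_levels[i.source]})"
            )
        if (i.source, i.target, i.threshold) in triples:
            report.errors.append(f"duplicate interaction {i}")
        triples.add((i.source, i.target, i.threshold))
        if (i.source, i.target) in pairs:
            report.errors.append(
                f"multiple interactions {i.source}->{i.target}: "
                "at most one threshold per ordered pair is supported"
            )
        pairs.add((i.source, i.target))

    declared_in: dict[str, set[str]] = {}
    for i in model.interactions:
        declared_in.setdefault(i.target, set()).add(i.source)

    for target, rule in model.rules.items():
        if target not in seen:
            report.errors.append(f"rule for unknown component {target}")
            continue
        for reg in rule.regulators:
            if reg not in seen:
                report.errors.append(
                    f"rule for {target} uses non-regulator {reg} (unknown component)"
                )
            elif reg not in declared_in.get(target, set()):
                report.errors.append(
                    f"rule for {target} uses non-regulator {reg} "
                    "(no declared interaction)"
                )
        known = [r for r in rule.regulators if r in seen]
        if len(known) == len(rule.regulators):
            expected = 1
            for r in rule.regulators:
                expected *= max_levels[r] + 1
            if len(rule.table) != expected:
                report.errors.append(
                    f"rule for {target} is not total over its regulators"
                )
            bad = {v for v in rule.table.values() if not 0 <= v <= max_levels[target]}
            if bad:
                report.errors.append(
                    f"rule for {target} returns out-of-range level(s) {sorted(bad)}"
                )

    # Non-functional declared interactions are legal but suspicious; the
    # sweep only makes sense once the structure is sound.
    if not report.errors:
        for i in model.interactions:
            rep = interaction_functionality(model, i)
            if not rep.functional:
                report.warnings.append(f"interaction {i} is not functional")
    return report


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Perturbation:
    """A model modification expressed as a rewrite of one logical rule.

    * ``knock_out``: the rule becomes the constant 0.
    * ``ectopic``: the rule becomes the constant ``level`` (knock-in).
    * ``range_restriction``: the rule output is capped at ``level``.
    * ``edge_suppression``: the target of ``edge`` is made insensitive to it
      (the source is clamped below the edge threshold inside the rule).
    """

    kind: str
    target: str = ""
    level: int = 0
    edge: Interaction | None = None

    @classmethod
    def knock_out(cls, target: str) -> "Perturbation":
        return cls("knock_out", target)

    @classmethod
    def ectopic(cls, target: str, level: int) -> "Perturbation":
        return cls("ectopic", target, level)

    @classmethod
    def range_restriction(cls, target: str, level: int) -> "Perturbation":
        return cls("range_restriction", target, level)

    @classmethod
    def edge_suppression(cls, edge: Interaction) -> "Perturbation":
        return cls("edge_suppression", edge.target, edge=edge)


def apply_perturbation(
    model: LogicalModel, perturbations: Iterable[Perturbation] | Perturbation
) -> LogicalModel:
    """Return a new model with the perturbations applied; the original is
    untouched.  At most one perturbation may touch any given component."""
    if isinstance(perturbations, Perturbation):
        perturbations = [perturbations]
    perturbations = list(perturbations)
    names = set(model.names)
    touched: set[str] = set()
    for p in perturbations:
        if p.target not in names:
            raise KeyError(f"perturbation targets unknown component {p.target}")
        if p.target in touched:
            raise ValueError(f"conflicting perturbations on component {p.target}")
        touched.add(p.target)

    components = list(model.components)
    rules = dict(model.rules)
    interactions = list(model.interactions)
    for p in perturbations:
        comp = model.component(p.target)
        if p.kind in ("knock_out", "ectopic"):
            level = 0 if p.kind == "knock_out" else int(p.level)
            if not 0 <= level <= comp.max_level:
                raise ValueError(
                    f"ectopic level {level} out of range for {comp.name}"
                )
            rules[p.target] = LogicalRule.constant(p.target, level)
            if comp.is_input:  # a clamped input becomes an ordinary constant node
                components[components.index(comp)] = Component(
                    comp.name, comp.max_level, is_input=False
                )
        elif p.kind == "range_restriction":
            if comp.is_input:
                raise ValueError("range restriction applies to internal components")
            cap = int(p.level)
            rules[p.target] = rules[p.target].with_output(lambda v: min(v, cap))
        elif p.kind == "edge_suppression":
            edge = p.edge
            assert edge is not None
            if edge.target not in rules:
                raise ValueError(f"cannot suppress edge into input {edge.target}")
            rules[edge.target] = rules[edge.target].with_source_clamped(
                edge.source, edge.threshold - 1
            )
            interactions = [
                i
                for i in interactions
                if not (
                    i.source == edge.source
                    and i.target == edge.target
                    and i.threshold == edge.threshold
                )
            ]
        else:
            raise ValueError(f"unknown perturbation kind {p.kind}")
    meta = dict(model.metadata)
    meta.setdefault("perturbations", []).extend(
        f"{p.kind}:{p.target}" for p in perturbations
    )
    return LogicalModel(components, rules.values(), interactions, meta)


def fix_inputs(model: LogicalModel, assignment: Mapping[str, int]) -> LogicalModel:
    """Restrict input components to fixed levels and drop them from the model.

    Rules are partially evaluated, so a fixed input disappears from every
    regulator list.  Useful before circuit analysis or reduction.
    """
    for name, level in assignment.items():
        comp = model.component(name)
        if not comp.is_input:
            raise ValueError(f"{name} is not an input component")
        if not 0 <= level <= comp.max_level:
            raise ValueError(f"level {level} out of range for input {name}")
    components = [c for c in model.components if c.name not in assignment]
    rules = [r.restricted(assignment) for r in model.rules.values()]
    return LogicalModel(components, rules, metadata=dict(model.metadata))


# ---------------------------------------------------------------------------
# Functionality analysis
# ---------------------------------------------------------------------------


@dataclass
class FunctionalityReport:
    interaction: Interaction
    functional: bool
    derived_sign: str
    context: tuple[dict[str, int], ...]


def interaction_functionality(
    model: LogicalModel, interaction: Interaction
) -> FunctionalityReport:
    """Compare the target rule with the source at ``threshold`` versus
    ``threshold - 1`` over all combinations of the remaining regulators.

    The interaction is functional iff some context shows a difference; the
    sign is activation if every difference raises the target level,
    inhibition if every difference lowers it, dual if both occur.
    """
    if interaction.target not in model.rules:
        raise KeyError(f"unknown interaction {interaction} (target has no rule)")
    rule = model.rules[interaction.target]
    if interaction.source not in rule.regulators:
        return FunctionalityReport(interaction, False, NONE, ())
    max_levels = model.max_levels
    others = [r for r in rule.regulators if r != interaction.source]
    theta = interaction.threshold
    contexts: list[dict[str, int]] = []
    rises = falls = False
    for combo in itertools.product(*(range(max_levels[r] + 1) for r in others)):
        env = dict(zip(others, combo))
        env[interaction.source] = theta
        high = rule(env)
        env[interaction.source] = theta - 1
        low = rule(env)
        if high != low:
            contexts.append(dict(zip(others, combo)))
            if high > low:
                rises = True
            else:
                falls = True
    if not contexts:
        sign = NONE
    elif rises and falls:
        sign = DUAL
    elif rises:
        sign = ACTIVATION
    else:
        sign = INHIBITION
    return FunctionalityReport(interaction, bool(contexts), sign, tuple(contexts))


def regulatory_circuits(
    model: LogicalModel, max_length: int | None = None
) -> list[tuple[Interaction, ...]]:
    """Enumerate elementary regulatory circuits as ordered interaction tuples.

    Plumbing for :func:`circuit_functionality`; uses Johnson's algorithm via
    networkx on the interaction graph.
    """
    g = nx.DiGraph()
    edges = {(i.source, i.target): i for i in model.interactions}
    g.add_edges_from(edges)
    out: list[tuple[Interaction, ...]] = []
    for cycle in nx.simple_cycles(g):
        if max_length is not None and len(cycle) > max_length:
            continue
        pivot = cycle.index(min(cycle))  # canonical rotation
        cycle = cycle[pivot:] + cycle[:pivot]
        circuit = tuple(
            edges[(cycle[k], cycle[(k + 1) % len(cycle)])] for k in range(len(cycle))
        )
        out.append(circuit)
    out.sort(key=lambda c: tuple((e.source, e.target) for e in c))
    return out


def circuit_functionality(
    model: LogicalModel, circuit: Sequence[Interaction]
) -> tuple[str, tuple[dict[str, int], ...]]:
    """Sign and functionality context of an elementary regulatory circuit.

    The sign is the parity of inhibitions along the cycle (even = positive,
    odd = negative).  The context is the set of level combinations of
    regulators *external* to the circuit under which every circuit edge is
    functional; an empty context means the circuit is never functional.
    """
    circuit = list(circuit)
    if not circuit:
        raise ValueError("empty circuit")
    nodes = [e.source for e in circuit]
    if len(set(nodes)) != len(nodes):
        raise ValueError("interactions do not form an elementary cycle")
    for k, edge in enumerate(circuit):
        if edge.target != circuit[(k + 1) % len(circuit)].source:
            raise ValueError("interactions do not form an elementary cycle")
    circuit_nodes = set(nodes)
    max_levels = model.max_levels

    inhibitions = 0
    per_edge_external: list[tuple[tuple[str, ...], set[tuple[int, ...]]]] = []
    for edge in circuit:
        rep = interaction_functionality(model, edge)
        if rep.derived_sign == DUAL:
            raise ValueError(f"edge {edge} has a dual sign; circuit sign undefined")
        if rep.derived_sign == INHIBITION:
            inhibitions += 1
        rule = model.rules[edge.target]
        external = tuple(
            r
            for r in rule.regulators
            if r != edge.source and r not in circuit_nodes
        )
        witnessed = {
            tuple(ctx[r] for r in external)
            for ctx in rep.context
        }
        per_edge_external.append((external, witnessed))

    all_external: list[str] = []
    for external, _ in per_edge_external:
        for r in external:
            if r not in all_external:
                all_external.append(r)

    contexts: list[dict[str, int]] = []
    for combo in itertools.product(
        *(range(max_levels[r] + 1) for r in all_external)
    ):
        env = dict(zip(all_external, combo))
        if all(
            tuple(env[r] for r in external) in witnessed
            for external, witnessed in per_edge_external
        ):
            contexts.append(env)
    sign = "positive" if inhibitions % 2 == 0 else "negative"
    return sign, tuple(contexts)
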