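"""Action-restricted CTL over input-labeled transition systems.

Instead of folding environmental inputs into the state vector, each
asynchronous transition is labeled with the input valuations that enable
it.  The state space then ranges over internal components only, and a
single transition system covers every environment.  ARCTL operators pair a
path quantifier with an input restriction ``alpha``: path quantifiers range
over paths whose every transition is enabled by some valuation satisfying
``alpha`` (the restriction constrains transitions, not states, and the
valuation may differ from one transition to the next).

Deadlock convention: at a state with no outgoing ``alpha``-transition, an
A-quantified next is vacuously true and an E-quantified next is false;
maximal finite ``alpha``-paths are admitted for the G-operators.  In
particular ``AAG(e)(c)`` holds at a stable state satisfying ``c``, which is
what reprogramming-graph queries rely on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

from .dynamics import DEFAULT_STATE_CAP, State, StateCapExceeded, successors
from .model import LogicalModel

__all__ = [
    "LabeledTransitionSystem",
    "build_lts",
    "sat_set",
    "check",
    "CheckResult",
    "VacuousPropertyError",
    "FormulaTypeError",
    # formula AST
    "TrueF",
    "FalseF",
    "Atom",
    "Not",
    "And",
    "Or",
    "Modal",
    "ATrue",
    "AAtom",
    "ANot",
    "AAnd",
    "AOr",
    "atom_pattern",
    "alpha_environment",
]

Valuation = tuple[int, ...]  # input levels in input-name order

MODAL_OPS = ("EAX", "AAX", "EAF", "AAF", "EAG", "AAG", "EAU", "AAU")


class FormulaTypeError(ValueError):
    """A state atom names a non-internal component, or alpha a non-input."""


class VacuousPropertyError(ValueError):
    """The initial predicate selects no state of the transition system."""


# ---------------------------------------------------------------------------
# Formula AST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueF:
    def __str__(self) -> str:
        return "true"


@dataclass(frozen=True)
class FalseF:
    def __str__(self) -> str:
        return "false"


@dataclass(frozen=True)
class Atom:
    """Comparison of an internal component's level: ``name op value``."""

    name: str
    op: str  # "=", ">=", "<="
    value: int

    def __str__(self) -> str:
        return f"{self.name}{self.op}{self.value}"


@dataclass(frozen=True)
class Not:
    arg: "Formula"

    def __str__(self) -> str:
        return f"!({self.arg})"


@dataclass(frozen=True)
class And:
    left: "Formula"
    right: "Formula"

    def __str__(self) -> str:
        return f"({self.left} & {self.right})"


@dataclass(frozen=True)
class Or:
    left: "Formula"
    right: "Formula"

    def __str__(self) -> str:
        return f"({self.left} | {self.right})"


@dataclass(frozen=True)
class Modal:
    """Temporal operator with input restriction ``alpha``.

    ``EAU``/``AAU`` use both ``phi`` and ``psi`` (phi until psi); the other
    operators ignore ``psi``.
    """

    op: str
    alpha: "Alpha"
    phi: "Formula"
    psi: "Formula | None" = None

    def __post_init__(self) -> None:
        if self.op not in MODAL_OPS:
            raise ValueError(f"unknown temporal operator {self.op}")
        if (self.psi is not None) != (self.op in ("EAU", "AAU")):
            raise ValueError(f"{self.op} takes {'two' if self.op in ('EAU', 'AAU') else 'one'} state argument(s)")

    def __str__(self) -> str:
        if self.psi is not None:
            return f"{self.op}({self.alpha})[{self.phi} U {self.psi}]"
        return f"{self.op}({self.alpha})({self.phi})"


Formula = TrueF | FalseF | Atom | Not | And | Or | Modal


@dataclass(frozen=True)
class ATrue:
    def __str__(self) -> str:
        return "true"


@dataclass(frozen=True)
class AAtom:
    """Comparison of an input component's level."""

    name: str
    op: str
    value: int

    def __str__(self) -> str:
        return f"{self.name}{self.op}{self.value}"


@dataclass(frozen=True)
class ANot:
    arg: "Alpha"

    def __str__(self) -> str:
        return f"!({self.arg})"


@dataclass(frozen=True)
class AAnd:
    left: "Alpha"
    right: "Alpha"

    def __str__(self) -> str:
        return f"({self.left} & {self.right})"


@dataclass(frozen=True)
class AOr:
    left: "Alpha"
    right: "Alpha"

    def __str__(self) -> str:
        return f"({self.left} | {self.right})"


Alpha = ATrue | AAtom | ANot | AAnd | AOr


def atom_pattern(constraints: Mapping[str, int]) -> Formula:
    """Conjunction of equality atoms for a (partial) state pattern."""
    out: Formula = TrueF()
    for name in constraints:
        atom = Atom(name, "=", constraints[name])
        out = atom if isinstance(out, TrueF) else And(out, atom)
    return out


def alpha_environment(assignment: Mapping[str, int]) -> Alpha:
    """Conjunction of input equalities for a (partial) environment."""
    out: Alpha = ATrue()
    for name in assignment:
        atom = AAtom(name, "=", assignment[name])
        out = atom if isinstance(out, ATrue) else AAnd(out, atom)
    return out


# ---------------------------------------------------------------------------
# Labeled transition system
# ---------------------------------------------------------------------------


@dataclass
class LabeledTransitionSystem:
    """Asynchronous transitions over internal states, labeled by the set of
    input valuations enabling each of them."""

    names: tuple[str, ...]  # internal component order
    input_names: tuple[str, ...]
    input_ranges: tuple[int, ...]  # max level per input
    states: tuple[State, ...]
    edges: dict[tuple[State, State], frozenset[Valuation]]

    @property
    def valuations(self) -> tuple[Valuation, ...]:
        return tuple(
            itertools.product(*(range(m + 1) for m in self.input_ranges))
        )

    def alpha_valuations(self, alpha: Alpha) -> frozenset[Valuation]:
        """Input valuations satisfying the restriction ``alpha``."""
        return frozenset(
            v for v in self.valuations if _eval_alpha(self, alpha, v)
        )


def _eval_alpha(
    lts: LabeledTransitionSystem, alpha: Alpha, valuation: Valuation
) -> bool:
    if isinstance(alpha, ATrue):
        return True
    if isinstance(alpha, AAtom):
        if alpha.name not in lts.input_names:
            raise FormulaTypeError(
                f"input restriction mentions non-input {alpha.name}"
            )
        level = valuation[lts.input_names.index(alpha.name)]
        if alpha.op == "=":
            return level == alpha.value
        if alpha.op == ">=":
            return level >= alpha.value
        if alpha.op == "<=":
            return level <= alpha.value
        raise ValueError(f"unknown comparison {alpha.op}")
    if isinstance(alpha, ANot):
        return not _eval_alpha(lts, alpha.arg, valuation)
    if isinstance(alpha, AAnd):
        return _eval_alpha(lts, alpha.left, valuation) and _eval_alpha(
            lts, alpha.right, valuation
        )
    if isinstance(alpha, AOr):
        return _eval_alpha(lts, alpha.left, valuation) or _eval_alpha(
            lts, alpha.right, valuation
        )
    raise TypeError(f"not an input restriction: {alpha!r}")


def build_lts(
    model: LogicalModel, state_cap: int = DEFAULT_STATE_CAP
) -> LabeledTransitionSystem:
    """Complete labeled transition system over the internal state space.

    An edge enabled by several input valuations carries them all; an edge's
    label is the full set of valuations under which the asynchronous step
    exists.
    """
    names = model.internal_names
    max_levels = model.max_levels
    size = 1
    for n in names:
        size *= max_levels[n] + 1
    if size > state_cap:
        raise StateCapExceeded(f"state space too large (> {state_cap} states)")
    input_names = model.input_names
    input_ranges = tuple(max_levels[n] for n in input_names)
    states = tuple(
        itertools.product(*(range(max_levels[n] + 1) for n in names))
    )
    edges: dict[tuple[State, State], set[Valuation]] = {}
    for valuation in itertools.product(*(range(m + 1) for m in input_ranges)):
        inputs = dict(zip(input_names, valuation))
        for s in states:
            for t in successors(model, s, inputs):
                edges.setdefault((s, t), set()).add(valuation)
    frozen = {k: frozenset(v) for k, v in edges.items()}
    return LabeledTransitionSystem(names, input_names, input_ranges, states, frozen)


# ---------------------------------------------------------------------------
# Fixpoint semantics
# ---------------------------------------------------------------------------


def _eval_atom(lts: LabeledTransitionSystem, atom: Atom, state: State) -> bool:
    if atom.name not in lts.names:
        if atom.name in lts.input_names:
            raise FormulaTypeError(
                f"state atom mentions input component {atom.name}; inputs "
                "live on transition labels"
            )
        raise FormulaTypeError(f"unknown atom {atom.name}")
    level = state[lts.names.index(atom.name)]
    if atom.op == "=":
        return level == atom.value
    if atom.op == ">=":
        return level >= atom.value
    if atom.op == "<=":
        return level <= atom.value
    raise ValueError(f"unknown comparison {atom.op}")


def _alpha_adjacency(
    lts: LabeledTransitionSystem, alpha: Alpha
) -> tuple[dict[State, list[State]], dict[State, list[State]]]:
    allowed = lts.alpha_valuations(alpha)
    succ: dict[State, list[State]] = {s: [] for s in lts.states}
    pred: dict[State, list[State]] = {s: [] for s in lts.states}
    for (a, b), label in lts.edges.items():
        if label & allowed:
            succ[a].append(b)
            pred[b].append(a)
    return succ, pred


def _modal_sat(
    lts: LabeledTransitionSystem, node: Modal, phi: set[State], psi: set[State] | None
) -> set[State]:
    succ, pred = _alpha_adjacency(lts, node.alpha)
    states = set(lts.states)
    deadlocks = {s for s in states if not succ[s]}

    def eax(x: set[State]) -> set[State]:
        return {s for s in states if any(t in x for t in succ[s])}

    def aax(x: set[State]) -> set[State]:
        return {s for s in states if all(t in x for t in succ[s])}

    op = node.op
    if op == "EAX":
        return eax(phi)
    if op == "AAX":
        return aax(phi)
    if op == "EAF":
        # least fixpoint of phi ∪ EAX(·); zero-length paths count
        x = set(phi)
        frontier = set(phi)
        while frontier:
            new = {
                s
                for t in frontier
                for s in pred[t]
                if s not in x
            }
            x |= new
            frontier = new
        return x
    if op == "AAG":
        # complement of EAF(alpha)(¬phi): no alpha-path may ever leave phi
        x = states - phi
        frontier = set(x)
        while frontier:
            new = {s for t in frontier for s in pred[t] if s not in x}
            x |= new
            frontier = new
        return states - x
    if op == "AAF":
        # least fixpoint of phi ∪ (AAX(·) ∩ non-deadlocked)
        x = set(phi)
        while True:
            new = (aax(x) - deadlocks) | phi
            if new == x:
                return x
            x = new
    if op == "EAG":
        # greatest fixpoint of phi ∩ (EAX(·) ∪ deadlocks)
        x = set(phi)
        while True:
            new = phi & (eax(x) | deadlocks)
            if new == x:
                return x
            x = new
    if op == "EAU":
        assert psi is not None
        x = set(psi)
        while True:
            new = psi | (phi & eax(x))
            if new == x:
                return x
            x = new
    if op == "AAU":
        assert psi is not None
        x = set(psi)
        while True:
            new = psi | (phi & aax(x) - deadlocks)
            if new == x:
                return x
            x = new
    raise ValueError(f"unknown temporal operator {op}")


def sat_set(lts: LabeledTransitionSystem, formula: Formula) -> set[State]:
    """States of the transition system satisfying ``formula``."""
    if isinstance(formula, TrueF):
        return set(lts.states)
    if isinstance(formula, FalseF):
        return set()
    if isinstance(formula, Atom):
        return {s for s in lts.states if _eval_atom(lts, formula, s)}
    if isinstance(formula, Not):
        return set(lts.states) - sat_set(lts, formula.arg)
    if isinstance(formula, And):
        return sat_set(lts, formula.left) & sat_set(lts, formula.right)
    if isinstance(formula, Or):
        return sat_set(lts, formula.left) | sat_set(lts, formula.right)
    if isinstance(formula, Modal):
        phi = sat_set(lts, formula.phi)
        psi = sat_set(lts, formula.psi) if formula.psi is not None else None
        return _modal_sat(lts, formula, phi, psi)
    raise TypeError(f"not a formula: {formula!r}")


@dataclass
class CheckResult:
    """Verdict of a whole-initial-set check.

    The property holds iff *every* initial state satisfies the formula;
    ``counterexample`` collects the initial states outside the satisfaction
    set, ``witness`` those inside.
    """

    holds: bool
    initial: frozenset[State]
    witness: frozenset[State]
    counterexample: frozenset[State]

    def __bool__(self) -> bool:
        return self.holds


def check(
    lts: LabeledTransitionSystem,
    init: Formula | Mapping[str, int] | Iterable[State],
    formula: Formula,
) -> CheckResult:
    """Check ``formula`` against every state selected by ``init``.

    ``init`` may be a state predicate, a partial level assignment, or an
    explicit state collection.  An empty initial set is rejected as a
    vacuous property rather than reported true or false.
    """
    if isinstance(init, Mapping):
        init = atom_pattern(init)
    if isinstance(
        init, (TrueF, FalseF, Atom, Not, And, Or, Modal)
    ):
        init_states = frozenset(sat_set(lts, init))
    else:
        init_states = frozenset(init)
        unknown = init_states - set(lts.states)
        if unknown:
            raise ValueError(f"initial states outside the system: {sorted(unknown)}")
    if not init_states:
        raise VacuousPropertyError("initial predicate selects no state")
    sat = sat_set(lts, formula)
    witness = frozenset(init_states & sat)
    counter = frozenset(init_states - sat)
    return CheckResult(not counter, init_states, witness, counter)
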