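"""Hand-built toy models with fully known behavior, and a seeded
random-model generator for property testing.

The TOGGLE model is the minimal mutual-inhibition master-regulator motif
with one environmental input: two Boolean components repressing each other,
the first also requiring the input signal.  It exhibits the canonical
positive-circuit bistability and is the worked example throughout the
package.
"""

from __future__ import annotations

import random

from .model import Component, LogicalModel, LogicalRule

__all__ = [
    "toggle",
    "negative_circuit",
    "step",
    "constant",
    "self_activator",
    "th_demo",
    "random_model",
    "FIXTURES",
]

#: Guard for the random generator: state spaces stay within this many
#: binary-equivalent variables so brute-force oracles remain cheap.
MAX_BINARY_EQUIVALENT = 12


def toggle() -> LogicalModel:
    """Boolean toggle switch gated by an input.

    Components I (input), A, B with ``K_A = I=1 & B=0`` and ``K_B = A=0``.
    Three context-dependent stable states: (A=0,B=1) under both input
    values and (A=1,B=0) under I=1 only.
    """
    maxes = {"I": 1, "A": 1, "B": 1}
    return LogicalModel(
        [Component("I", 1, True), Component("A", 1), Component("B", 1)],
        [
            LogicalRule.from_function(
                "A", ("I", "B"), maxes, lambda s: int(s["I"] == 1 and s["B"] == 0)
            ),
            LogicalRule.from_function(
                "B", ("A",), maxes, lambda s: int(s["A"] == 0)
            ),
        ],
    )


def negative_circuit() -> LogicalModel:
    """Two Boolean components in a negative circuit: ``K_A = B=0``,
    ``K_B = A=1``.  No stable state; one cyclic attractor through all four
    states under asynchronous updating."""
    maxes = {"A": 1, "B": 1}
    return LogicalModel(
        [Component("A", 1), Component("B", 1)],
        [
            LogicalRule.from_function("A", ("B",), maxes, lambda s: int(s["B"] == 0)),
            LogicalRule.from_function("B", ("A",), maxes, lambda s: int(s["A"] == 1)),
        ],
    )


def step() -> LogicalModel:
    """A ternary component M driven to 2 by the Boolean input J, to 0
    otherwise; exercises unitary (one-level-per-transition) updating."""
    maxes = {"J": 1, "M": 2}
    return LogicalModel(
        [Component("J", 1, True), Component("M", 2)],
        [
            LogicalRule.from_function(
                "M", ("J",), maxes, lambda s: 2 if s["J"] == 1 else 0
            )
        ],
    )


def constant() -> LogicalModel:
    """Single Boolean component with the constant rule 0."""
    return LogicalModel([Component("C", 1)], [LogicalRule.constant("C", 0)])


def self_activator() -> LogicalModel:
    """Single Boolean self-activating component: ``K_C = C=1``; the
    simplest positive circuit, functional with no external context."""
    return LogicalModel(
        [Component("C", 1)],
        [LogicalRule.from_function("C", ("C",), {"C": 1}, lambda s: s["C"])],
    )


def th_demo() -> LogicalModel:
    """Illustrative miniature of the Th1/Th2 cross-regulation circuitry.

    A ten-node Boolean caricature — antigen presentation (APC) plus the
    IL-12/Stat4/Tbet and IL-4/Stat6/Gata3 branches with mutual master-
    regulator inhibition and autocrine IFNg/IL-4 feedback.  Synthetic and
    didactic: hand-built for demonstrations and NOT a published model of
    T-helper differentiation.
    """
    maxes = {
        "APC": 1, "IL12_e": 1, "IL4_e": 1,
        "Stat1": 1, "Stat4": 1, "Stat6": 1,
        "Tbet": 1, "Gata3": 1, "IFNG": 1, "IL4": 1,
    }

    def rule(name, regs, fn):
        return LogicalRule.from_function(name, regs, maxes, fn)

    return LogicalModel(
        [
            Component("APC", 1, True),
            Component("IL12_e", 1, True),
            Component("IL4_e", 1, True),
            Component("Stat1", 1),
            Component("Stat4", 1),
            Component("Stat6", 1),
            Component("Tbet", 1),
            Component("Gata3", 1),
            Component("IFNG", 1),
            Component("IL4", 1),
        ],
        [
            rule("Stat1", ("IFNG",), lambda s: s["IFNG"]),
            rule(
                "Stat4",
                ("APC", "IL12_e", "Gata3"),
                lambda s: int(s["APC"] == 1 and s["IL12_e"] == 1 and s["Gata3"] == 0),
            ),
            rule(
                "Stat6",
                ("APC", "IL4_e", "IL4"),
                lambda s: int(s["APC"] == 1 and (s["IL4_e"] == 1 or s["IL4"] == 1)),
            ),
            rule(
                "Tbet",
                ("Stat1", "Tbet", "Gata3"),
                lambda s: int((s["Stat1"] == 1 or s["Tbet"] == 1) and s["Gata3"] == 0),
            ),
            rule(
                "Gata3",
                ("Stat6", "Tbet", "Gata3"),
                lambda s: int((s["Stat6"] == 1 or s["Gata3"] == 1) and s["Tbet"] == 0),
            ),
            rule(
                "IFNG",
                ("Stat4", "Tbet"),
                lambda s: int(s["Stat4"] == 1 or s["Tbet"] == 1),
            ),
            rule("IL4", ("Stat1", "Gata3"), lambda s: int(s["Gata3"] == 1 and s["Stat1"] == 0)),
        ],
    )


FIXTURES = {
    "toggle": toggle,
    "negative_circuit": negative_circuit,
    "step": step,
    "constant": constant,
    "self_activator": self_activator,
    "th_demo": th_demo,
}


def random_model(
    n_components: int,
    n_inputs: int = 0,
    max_levels: int = 1,
    seed: int = 0,
) -> LogicalModel:
    """Reproducible random model for oracle batteries.

    ``n_components`` internal components (X1..Xn) and ``n_inputs`` inputs
    (U1..Um), each with a maximum level drawn from ``1..max_levels``.
    Rules are random tables over randomly chosen regulator sets (pruned to
    their support, so derived interactions are exact); declared signs are
    left unknown.  Guarded to at most ``2**MAX_BINARY_EQUIVALENT`` full
    states so brute-force cross-checks stay cheap.
    """
    rng = random.Random(seed)
    names = [f"X{i + 1}" for i in range(n_components)] + [
        f"U{i + 1}" for i in range(n_inputs)
    ]
    maxes = {n: rng.randint(1, max_levels) for n in names}
    size = 1
    for n in names:
        size *= maxes[n] + 1
    if size > 2**MAX_BINARY_EQUIVALENT:
        raise ValueError(
            f"state space of {size} states exceeds the brute-force guard "
            f"(2^{MAX_BINARY_EQUIVALENT})"
        )
    components = [Component(f"X{i + 1}", maxes[f"X{i + 1}"]) for i in range(n_components)]
    components += [
        Component(f"U{i + 1}", maxes[f"U{i + 1}"], True) for i in range(n_inputs)
    ]
    rules = []
    for i in range(n_components):
        target = f"X{i + 1}"
        k = rng.randint(1, min(3, len(names)))
        chosen = set(rng.sample(names, k))
        regulators = [n for n in names if n in chosen]
        rule = LogicalRule.from_function(
            target,
            regulators,
            maxes,
            lambda s: rng.randint(0, maxes[target]),
        ).pruned()
        rules.append(rule)
    return LogicalModel(components, rules)
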