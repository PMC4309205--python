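"""Model reduction by component elimination.

Removing a component rewrites the rules of its targets, substituting the
removed component's rule for its occurrences, so the indirect effect of its
regulators is preserved.  The transformation conserves the stable states
(the reduced model's fixed points are exactly the projections of the
original's) and, when only output components are removed, also attractor
reachability.  Self-regulated components cannot be removed this way.
"""

from __future__ import annotations

import hashlib
from typing import Sequence

from .model import LogicalModel

__all__ = ["reduce_model", "SelfRegulatedError"]


class SelfRegulatedError(ValueError):
    """Raised when attempting to remove a self-regulated component."""


def _model_digest(model: LogicalModel) -> str:
    parts = []
    for c in model.components:
        parts.append(f"{c.name}:{c.max_level}:{int(c.is_input)}")
    for name in sorted(model.rules):
        rule = model.rules[name]
        parts.append(f"{name}<{','.join(rule.regulators)}>")
        parts.append(",".join(str(v) for _, v in sorted(rule.table.items())))
    return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


def reduce_model(model: LogicalModel, remove: Sequence[str]) -> LogicalModel:
    """Eliminate ``remove`` (in order) from the model.

    Each step substitutes the removed component's rule into every rule that
    mentions it, then recomputes regulator lists from the rewritten rules'
    support, so vestigial interactions vanish.  Removal of a used input is
    rejected (fix it with :func:`logimc.model.fix_inputs` first); removal of
    a component that is — or has become, through earlier substitutions —
    self-regulated raises :class:`SelfRegulatedError`.
    """
    if not remove:
        return model.replace()
    digest = _model_digest(model)
    components = list(model.components)
    rules = {name: rule.pruned() for name, rule in model.rules.items()}
    max_levels = model.max_levels
    for name in remove:
        comp = next((c for c in components if c.name == name), None)
        if comp is None:
            raise KeyError(f"unknown component {name}")
        if comp.is_input:
            if any(name in r.regulators for r in rules.values()):
                raise ValueError(
                    f"input {name} is still used by a rule; fix it to a level "
                    "before reduction"
                )
            components.remove(comp)
            continue
        inner = rules[name]
        if name in inner.regulators:
            raise SelfRegulatedError(
                f"component {name} is self-regulated and cannot be removed"
            )
        for target in list(rules):
            if target == name:
                continue
            if name in rules[target].regulators:
                rules[target] = rules[target].substituted(
                    name, inner, max_levels
                ).pruned()
        del rules[name]
        components.remove(comp)

    meta = dict(model.metadata)
    if remove:
        meta["reduced_from"] = digest
        meta["removed_components"] = list(
            meta.get("removed_components", [])
        ) + list(remove)
    return LogicalModel(components, rules.values(), metadata=meta)
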