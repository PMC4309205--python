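"""Reading and writing models, side files, and ARCTL formula text.

Two model formats are supported:

* ``mnet`` — a human-writable multivalued rule format.  One declaration
  line per component (``input NAME : MAX`` or ``NAME : MAX``) and one rule
  per non-input component::

      NAME := { <condition> : <level> ; ... ; default : <level> }

  Conditions are boolean expressions over regulator comparisons
  (``REG=2``, ``REG>=1``, ``REG<=0``) combined with ``& | ! ( )``; the
  first matching clause wins.

* ``sbml_qual`` — the SBML Level 3 qualitative-models package, the
  community interchange format for this model class.  Function terms are
  interpreted first-match in document order (SBML-qual tolerates multiple
  matching terms; only the deterministic first-match reading is supported).

Side files (phenotype patterns, environments, strategies) are JSON; ARCTL
queries use the text grammar parsed by :func:`parse_query`.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping

from lxml import etree

from . import arctl
from .model import Component, Interaction, LogicalModel, LogicalRule, validate_model
from .reprogram import Strategy, StrategyPhase
from .stable import PhenotypePattern

__all__ = [
    "read_model",
    "write_model",
    "reads_mnet",
    "dumps_mnet",
    "reads_sbml_qual",
    "dumps_sbml_qual",
    "load_patterns",
    "load_environments",
    "load_strategies",
    "parse_formula",
    "parse_query",
    "ParseError",
]

NAME_RE = re.compile(r"[A-Za-z][A-Za-z0-9_]*\Z")


class ParseError(ValueError):
    """Syntax or typing error in a model file or formula, with position."""

    def __init__(self, message: str, pos: int | None = None, line: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line})"
        elif pos is not None:
            loc = f" (column {pos})"
        super().__init__(message + loc)
        self.pos = pos
        self.line = line


# ---------------------------------------------------------------------------
# Tokenizer (shared by rule conditions and formula text)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<name>[A-Za-z][A-Za-z0-9_]*)|(?P<int>\d+)"
    r"|(?P<op>:=|>=|<=|=|!|&|\||\(|\)|\{|\}|\[|\]|,|;|:))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ParseError(
                    f"unexpected character {text[pos:].strip()[0]!r}", pos=pos
                )
            break
        if m.group("name"):
            tokens.append(("name", m.group("name"), m.start("name")))
        elif m.group("int"):
            tokens.append(("int", m.group("int"), m.start("int")))
        else:
            tokens.append(("op", m.group("op"), m.start("op")))
        pos = m.end()
    return tokens


class _TokenStream:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of input", pos=-1)
        self.i += 1
        return tok

    def expect(self, value: str) -> tuple[str, str, int]:
        tok = self.next()
        if tok[1] != value:
            raise ParseError(f"expected {value!r}, found {tok[1]!r}", pos=tok[2])
        return tok

    def at_end(self) -> bool:
        return self.i >= len(self.tokens)


# ---------------------------------------------------------------------------
# Boolean condition expressions over component comparisons (mnet rules)
# ---------------------------------------------------------------------------


def _parse_bool_expr(ts: _TokenStream, atom):
    """Precedence: ! binds tighter than &, which binds tighter than |."""

    def parse_or():
        node = parse_and()
        while (tok := ts.peek()) and tok[1] == "|":
            ts.next()
            node = ("or", node, parse_and())
        return node

    def parse_and():
        node = parse_unary()
        while (tok := ts.peek()) and tok[1] == "&":
            ts.next()
            node = ("and", node, parse_unary())
        return node

    def parse_unary():
        tok = ts.peek()
        if tok is None:
            raise ParseError("unexpected end of expression", pos=-1)
        if tok[1] == "!":
            ts.next()
            return ("not", parse_unary())
        if tok[1] == "(":
            ts.next()
            node = parse_or()
            ts.expect(")")
            return node
        return atom()

    return parse_or()


def _parse_comparison(ts: _TokenStream):
    tok = ts.next()
    if tok[0] != "name":
        raise ParseError(f"expected a component name, found {tok[1]!r}", pos=tok[2])
    name = tok[1]
    if name == "true":
        return ("true",)
    if name == "false":
        return ("false",)
    nxt = ts.peek()
    if nxt and nxt[1] in ("=", ">=", "<="):
        op = ts.next()[1]
        val = ts.next()
        if val[0] != "int":
            raise ParseError(f"expected a level, found {val[1]!r}", pos=val[2])
        return ("cmp", name, op, int(val[1]))
    raise ParseError(
        f"expected comparison operator after {name!r}",
        pos=nxt[2] if nxt else -1,
    )


def _eval_condition(node, env: Mapping[str, int]) -> bool:
    kind = node[0]
    if kind == "true":
        return True
    if kind == "false":
        return False
    if kind == "cmp":
        _, name, op, value = node
        level = env[name]
        return (
            level == value if op == "=" else level >= value if op == ">=" else level <= value
        )
    if kind == "not":
        return not _eval_condition(node[1], env)
    if kind == "and":
        return _eval_condition(node[1], env) and _eval_condition(node[2], env)
    if kind == "or":
        return _eval_condition(node[1], env) or _eval_condition(node[2], env)
    raise ValueError(kind)


def _condition_names(node) -> set[str]:
    kind = node[0]
    if kind == "cmp":
        return {node[1]}
    if kind == "not":
        return _condition_names(node[1])
    if kind in ("and", "or"):
        return _condition_names(node[1]) | _condition_names(node[2])
    return set()


# ---------------------------------------------------------------------------
# mnet format
# ---------------------------------------------------------------------------


def reads_mnet(text: str) -> LogicalModel:
    """Parse an mnet document into a validated model."""
    components: list[Component] = []
    rule_sources: list[tuple[int, str, str]] = []  # (line no, target, body)
    metadata: dict[str, object] = {}

    # Rules may span lines; join physical lines until braces balance.
    logical_lines: list[tuple[int, str]] = []
    buffer = ""
    buffer_start = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#!"):
            key, _, value = line[2:].partition("=")
            try:
                metadata[key.strip()] = json.loads(value.strip())
            except json.JSONDecodeError:
                metadata[key.strip()] = value.strip()
            continue
        if not line or line.startswith("#"):
            continue
        if not buffer:
            buffer_start = lineno
        buffer = (buffer + " " + line).strip()
        if buffer.count("{") == buffer.count("}"):
            logical_lines.append((buffer_start, buffer))
            buffer = ""
    if buffer:
        raise ParseError("unterminated rule block", line=buffer_start)

    for lineno, line in logical_lines:
        if ":=" in line:
            target, _, body = line.partition(":=")
            rule_sources.append((lineno, target.strip(), body.strip()))
            continue
        is_input = False
        decl = line
        if decl.split(maxsplit=1)[0] == "input":
            is_input = True
            decl = decl.split(maxsplit=1)[1]
        name, sep, max_part = decl.partition(":")
        name = name.strip()
        if not NAME_RE.match(name):
            raise ParseError(f"invalid component name {name!r}", line=lineno)
        max_level = 1
        if sep:
            try:
                max_level = int(max_part.strip())
            except ValueError:
                raise ParseError(
                    f"invalid max level {max_part.strip()!r}", line=lineno
                ) from None
        components.append(Component(name, max_level, is_input))

    max_levels = {c.name: c.max_level for c in components}
    known = set(max_levels)
    rules = []
    for lineno, target, body in rule_sources:
        if target not in known:
            raise ParseError(f"rule for undeclared component {target!r}", line=lineno)
        if not (body.startswith("{") and body.endswith("}")):
            raise ParseError(f"rule body for {target} must be braced", line=lineno)
        clauses: list[tuple[object, int]] = []
        default: int | None = None
        for part in _split_clauses(body[1:-1]):
            cond_text, _, level_text = part.rpartition(":")
            cond_text = cond_text.strip()
            try:
                level = int(level_text.strip())
            except ValueError:
                raise ParseError(
                    f"invalid level {level_text.strip()!r} in rule for {target}",
                    line=lineno,
                ) from None
            if cond_text == "default":
                default = level
                continue
            ts = _TokenStream(cond_text)
            try:
                node = _parse_bool_expr(ts, lambda: _parse_comparison(ts))
            except ParseError as exc:
                raise ParseError(
                    f"in rule for {target}: {exc.args[0]}", line=lineno
                ) from None
            if not ts.at_end():
                raise ParseError(
                    f"trailing tokens in rule for {target}", line=lineno
                )
            clauses.append((node, level))
        if default is None:
            raise ParseError(f"rule for {target} lacks a default clause", line=lineno)
        used = {n for node, _ in clauses for n in _condition_names(node)}
        # regulator order follows component declaration order
        regulators = [c.name for c in components if c.name in used]
        used -= set(regulators)
        regulators += sorted(used)
        unknown = [n for n in regulators if n not in known]
        if unknown:
            raise ParseError(
                f"rule for {target} uses undeclared component(s) {unknown}",
                line=lineno,
            )

        def evaluate(env, clauses=clauses, default=default):
            for node, level in clauses:
                if _eval_condition(node, env):
                    return level
            return default

        rules.append(
            LogicalRule.from_function(target, regulators, max_levels, evaluate)
        )

    model = LogicalModel(components, rules, metadata=metadata)
    report = validate_model(model)
    if not report.ok:
        raise ParseError("invalid model: " + "; ".join(report.errors))
    return model


def _split_clauses(body: str) -> list[str]:
    parts = [p.strip() for p in body.split(";")]
    return [p for p in parts if p]


def dumps_mnet(model: LogicalModel) -> str:
    """Serialize to mnet text.

    Rules are written one clause per non-default level, the clause being the
    disjunction of the table rows producing that level.  Reading the result
    back yields a semantically identical model.
    """
    lines = ["# logimc multivalued logical model"]
    for key in sorted(model.metadata):
        lines.append(f"#! {key} = {json.dumps(model.metadata[key])}")
    for c in model.components:
        prefix = "input " if c.is_input else ""
        lines.append(f"{prefix}{c.name} : {c.max_level}")
    for name in model.internal_names:
        rule = model.rules[name]
        by_level: dict[int, list[str]] = {}
        for assignment, level in rule.rows():
            term = " & ".join(f"{r}={assignment[r]}" for r in rule.regulators)
            by_level.setdefault(level, []).append(term or "true")
        default = max(
            by_level, key=lambda lv: (len(by_level[lv]), -lv)
        ) if by_level else 0
        clauses = []
        for level in sorted(by_level):
            if level == default:
                continue
            terms = by_level[level]
            cond = " | ".join(
                f"({t})" if len(terms) > 1 and "&" in t else t for t in terms
            )
            clauses.append(f"{cond} : {level}")
        clauses.append(f"default : {default}")
        lines.append(f"{name} := {{ " + " ; ".join(clauses) + " }")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SBML-qual
# ---------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
_MATH_NS = "http://www.w3.org/1998/Math/MathML"
_NSMAP = {None: _SBML_NS, "qual": _QUAL_NS}


def _q(tag: str) -> str:
    return f"{{{_QUAL_NS}}}{tag}"


def _m(tag: str) -> str:
    return f"{{{_MATH_NS}}}{tag}"


def dumps_sbml_qual(model: LogicalModel) -> str:
    sbml = etree.Element(f"{{{_SBML_NS}}}sbml", nsmap=_NSMAP)
    sbml.set("level", "3")
    sbml.set("version", "1")
    sbml.set(_q("required"), "true")
    sbml_model = etree.SubElement(sbml, f"{{{_SBML_NS}}}model")
    sbml_model.set("id", str(model.metadata.get("id", "logical_model")))

    species_list = etree.SubElement(sbml_model, _q("listOfQualitativeSpecies"))
    for c in model.components:
        sp = etree.SubElement(species_list, _q("qualitativeSpecies"))
        sp.set(_q("id"), c.name)
        sp.set(_q("maxLevel"), str(c.max_level))
        sp.set(_q("constant"), "true" if c.is_input else "false")

    sign_names = {"activation": "positive", "inhibition": "negative", "dual": "dual"}
    transitions = etree.SubElement(sbml_model, _q("listOfTransitions"))
    for name in model.internal_names:
        rule = model.rules[name]
        tr = etree.SubElement(transitions, _q("transition"))
        tr.set(_q("id"), f"tr_{name}")
        if rule.regulators:
            inputs = etree.SubElement(tr, _q("listOfInputs"))
            for reg in rule.regulators:
                inp = etree.SubElement(inputs, _q("input"))
                inp.set(_q("id"), f"in_{name}_{reg}")
                inp.set(_q("qualitativeSpecies"), reg)
                inp.set(_q("transitionEffect"), "none")
                try:
                    edge = model.interaction(reg, name)
                    inp.set(_q("thresholdLevel"), str(edge.threshold))
                    if edge.declared_sign in sign_names:
                        inp.set(_q("sign"), sign_names[edge.declared_sign])
                except KeyError:
                    pass
        outputs = etree.SubElement(tr, _q("listOfOutputs"))
        out = etree.SubElement(outputs, _q("output"))
        out.set(_q("id"), f"out_{name}")
        out.set(_q("qualitativeSpecies"), name)
        out.set(_q("transitionEffect"), "assignmentLevel")

        terms = etree.SubElement(tr, _q("listOfFunctionTerms"))
        by_level: dict[int, list[dict[str, int]]] = {}
        for assignment, level in rule.rows():
            by_level.setdefault(level, []).append(assignment)
        default = (
            max(by_level, key=lambda lv: (len(by_level[lv]), -lv)) if by_level else 0
        )
        dt = etree.SubElement(terms, _q("defaultTerm"))
        dt.set(_q("resultLevel"), str(default))
        for level in sorted(by_level):
            if level == default:
                continue
            ft = etree.SubElement(terms, _q("functionTerm"))
            ft.set(_q("resultLevel"), str(level))
            math = etree.SubElement(ft, _m("math"))
            math.append(_rows_to_mathml(rule.regulators, by_level[level]))

    return etree.tostring(
        sbml, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


def _rows_to_mathml(regulators, rows: list[dict[str, int]]):
    def eq(name: str, value: int):
        apply_ = etree.Element(_m("apply"))
        etree.SubElement(apply_, _m("eq"))
        ci = etree.SubElement(apply_, _m("ci"))
        ci.text = f" {name} "
        cn = etree.SubElement(apply_, _m("cn"))
        cn.set("type", "integer")
        cn.text = f" {value} "
        return apply_

    def row(assignment: dict[str, int]):
        if not regulators:
            return etree.Element(_m("true"))
        if len(regulators) == 1:
            return eq(regulators[0], assignment[regulators[0]])
        apply_ = etree.Element(_m("apply"))
        etree.SubElement(apply_, _m("and"))
        for r in regulators:
            apply_.append(eq(r, assignment[r]))
        return apply_

    if len(rows) == 1:
        return row(rows[0])
    apply_ = etree.Element(_m("apply"))
    etree.SubElement(apply_, _m("or"))
    for assignment in rows:
        apply_.append(row(assignment))
    return apply_


def _eval_mathml(node, env: Mapping[str, int]):
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise ParseError("math element must contain one expression")
        return _eval_mathml(children[0], env)
    if tag == "true":
        return True
    if tag == "false":
        return False
    if tag == "ci":
        name = (node.text or "").strip()
        if name not in env:
            raise ParseError(f"unknown symbol {name!r} in function term")
        return env[name]
    if tag == "cn":
        return int(float((node.text or "").strip()))
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [_eval_mathml(c, env) for c in children[1:]]
        if op == "and":
            return all(args)
        if op == "or":
            return any(args)
        if op == "not":
            return not args[0]
        if op == "eq":
            return args[0] == args[1]
        if op == "neq":
            return args[0] != args[1]
        if op == "geq":
            return args[0] >= args[1]
        if op == "leq":
            return args[0] <= args[1]
        if op == "gt":
            return args[0] > args[1]
        if op == "lt":
            return args[0] < args[1]
        raise ParseError(f"unsupported MathML operator {op!r}")
    raise ParseError(f"unsupported MathML element {tag!r}")


def reads_sbml_qual(text: str | bytes) -> LogicalModel:
    """Parse an SBML-qual document (deterministic first-match function
    terms) into a validated model."""
    if isinstance(text, str):
        text = text.encode()
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"not well-formed XML: {exc}") from None
    species = root.findall(f".//{_q('listOfQualitativeSpecies')}/{_q('qualitativeSpecies')}")
    if not species:
        raise ParseError("no qualitativeSpecies found (is this SBML-qual?)")
    max_levels = {}
    order = []
    constant = {}
    for sp in species:
        name = sp.get(_q("id"))
        if name is None:
            raise ParseError("qualitativeSpecies without qual:id")
        order.append(name)
        max_levels[name] = int(sp.get(_q("maxLevel"), "1"))
        constant[name] = sp.get(_q("constant"), "false") == "true"

    rules = []
    has_rule = set()
    interactions: list[Interaction] = []
    sign_names = {"positive": "activation", "negative": "inhibition", "dual": "dual"}
    for tr in root.findall(f".//{_q('listOfTransitions')}/{_q('transition')}"):
        outputs = tr.findall(f"{_q('listOfOutputs')}/{_q('output')}")
        if len(outputs) != 1:
            raise ParseError(
                f"transition {tr.get(_q('id'))!r}: exactly one output is supported"
            )
        target = outputs[0].get(_q("qualitativeSpecies"))
        if target not in max_levels:
            raise ParseError(f"transition output references unknown species {target!r}")
        regulators = []
        for inp in tr.findall(f"{_q('listOfInputs')}/{_q('input')}"):
            reg = inp.get(_q("qualitativeSpecies"))
            if reg not in max_levels:
                raise ParseError(f"transition input references unknown species {reg!r}")
            regulators.append(reg)
            threshold = int(inp.get(_q("thresholdLevel"), "1"))
            sign = sign_names.get(inp.get(_q("sign"), ""), "unknown")
            interactions.append(Interaction(reg, target, threshold, sign))
        term_list = tr.find(_q("listOfFunctionTerms"))
        if term_list is None:
            raise ParseError(f"transition for {target} lacks function terms")
        default_el = term_list.find(_q("defaultTerm"))
        if default_el is None:
            raise ParseError(f"transition for {target} lacks a default term")
        default = int(default_el.get(_q("resultLevel")))
        clauses = []
        for ft in term_list.findall(_q("functionTerm")):
            level = int(ft.get(_q("resultLevel")))
            math = ft.find(_m("math"))
            if math is None:
                raise ParseError(f"function term for {target} lacks math")
            clauses.append((math, level))
        for level in [default] + [lv for _, lv in clauses]:
            if not 0 <= level <= max_levels[target]:
                raise ParseError(
                    f"result level {level} exceeds maxLevel of {target}"
                )

        def evaluate(env, clauses=clauses, default=default):
            for math, level in clauses:
                if _eval_mathml(math, env):
                    return level
            return default

        rules.append(
            LogicalRule.from_function(target, regulators, max_levels, evaluate)
        )
        has_rule.add(target)

    components = [
        Component(name, max_levels[name], is_input=name not in has_rule)
        for name in order
    ]
    # species without a transition behave as inputs regardless of their
    # constant flag; `constant` is accepted but not otherwise interpreted
    del constant
    model = LogicalModel(components, rules, interactions or None)
    report = validate_model(model)
    if not report.ok:
        raise ParseError("invalid model: " + "; ".join(report.errors))
    return model


# ---------------------------------------------------------------------------
# File-level entry points
# ---------------------------------------------------------------------------

_FORMATS = ("mnet", "sbml_qual")


def _infer_format(path: Path) -> str:
    if path.suffix in (".sbml", ".xml"):
        return "sbml_qual"
    return "mnet"


def read_model(path: str | Path, format: str | None = None) -> LogicalModel:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}")
    text = path.read_text()
    return reads_mnet(text) if fmt == "mnet" else reads_sbml_qual(text)


def write_model(
    model: LogicalModel, path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}")
    text = dumps_mnet(model) if fmt == "mnet" else dumps_sbml_qual(model)
    path.write_text(text)


def load_patterns(path: str | Path) -> dict[str, PhenotypePattern]:
    """JSON mapping pattern name -> {component: level}."""
    data = json.loads(Path(path).read_text())
    return {
        name: PhenotypePattern(name, {k: int(v) for k, v in constraints.items()})
        for name, constraints in data.items()
    }


def load_environments(path: str | Path) -> dict[str, dict[str, int]]:
    """JSON mapping environment name -> {input: level} (partial)."""
    data = json.loads(Path(path).read_text())
    return {
        name: {k: int(v) for k, v in assignment.items()}
        for name, assignment in data.items()
    }


def load_strategies(path: str | Path) -> list[Strategy]:
    """JSON array of strategies; each strategy is an array of phases
    ``{"env": {...}, "target": name-or-constraints-or-true}``."""
    data = json.loads(Path(path).read_text())
    out = []
    for phases in data:
        built = []
        for phase in phases:
            target = phase.get("target", True)
            if target is True or target == "true":
                target_c = None
            elif isinstance(target, Mapping):
                target_c = {k: int(v) for k, v in target.items()}
            else:
                raise ValueError(
                    "phase target must be true or a constraint object; "
                    "resolve pattern names before loading"
                )
            built.append(StrategyPhase(dict(phase.get("env", {})), target_c))
        out.append(Strategy(tuple(built)))
    return out


# ---------------------------------------------------------------------------
# ARCTL formula text
# ---------------------------------------------------------------------------

_MODAL_UNARY = ("EAX", "AAX", "EAF", "AAF", "EAG", "AAG")
_MODAL_UNTIL = ("EAU", "AAU")


def _check_atom(model: LogicalModel | None, name: str, value: int, where: str, pos: int):
    if model is None:
        return
    try:
        comp = model.component(name)
    except KeyError:
        raise ParseError(f"unknown component {name!r}", pos=pos) from None
    if not 0 <= value <= comp.max_level:
        raise ParseError(
            f"level out of range: {name}={value} (max {comp.max_level})", pos=pos
        )
    if where == "state" and comp.is_input:
        raise ParseError(
            f"state atom mentions input component {name!r}", pos=pos
        )
    if where == "alpha" and not comp.is_input:
        raise ParseError(
            f"input restriction mentions non-input {name!r}", pos=pos
        )


def _parse_alpha(
    ts: _TokenStream,
    environments: Mapping[str, Mapping[str, int]],
    model: LogicalModel | None,
) -> arctl.Alpha:
    def parse_or():
        node = parse_and()
        while (tok := ts.peek()) and tok[1] == "|":
            ts.next()
            node = arctl.AOr(node, parse_and())
        return node

    def parse_and():
        node = parse_unary()
        while (tok := ts.peek()) and tok[1] == "&":
            ts.next()
            node = arctl.AAnd(node, parse_unary())
        return node

    def parse_unary():
        tok = ts.peek()
        if tok is None:
            raise ParseError("unexpected end of input restriction", pos=-1)
        if tok[1] == "!":
            ts.next()
            return arctl.ANot(parse_unary())
        if tok[1] == "(":
            ts.next()
            node = parse_or()
            ts.expect(")")
            return node
        if tok[1] == "{":
            ts.next()
            node: arctl.Alpha = arctl.ATrue()
            first = True
            while True:
                tok2 = ts.peek()
                if tok2 and tok2[1] == "}":
                    ts.next()
                    break
                if not first:
                    ts.expect(",")
                first = False
                name_tok = ts.next()
                if name_tok[0] != "name":
                    raise ParseError(
                        f"expected input name, found {name_tok[1]!r}", pos=name_tok[2]
                    )
                op_tok = ts.next()
                if op_tok[1] not in ("=", ">=", "<="):
                    raise ParseError(
                        f"expected comparison, found {op_tok[1]!r}", pos=op_tok[2]
                    )
                val_tok = ts.next()
                if val_tok[0] != "int":
                    raise ParseError(
                        f"expected level, found {val_tok[1]!r}", pos=val_tok[2]
                    )
                _check_atom(model, name_tok[1], int(val_tok[1]), "alpha", name_tok[2])
                atom = arctl.AAtom(name_tok[1], op_tok[1], int(val_tok[1]))
                node = atom if isinstance(node, arctl.ATrue) else arctl.AAnd(node, atom)
            return node
        if tok[0] == "name":
            ts.next()
            if tok[1] == "true":
                return arctl.ATrue()
            if tok[1] in environments:
                node: arctl.Alpha = arctl.ATrue()
                for name, level in environments[tok[1]].items():
                    _check_atom(model, name, level, "alpha", tok[2])
                    atom = arctl.AAtom(name, "=", level)
                    node = (
                        atom if isinstance(node, arctl.ATrue) else arctl.AAnd(node, atom)
                    )
                return node
            raise ParseError(f"unknown environment {tok[1]!r}", pos=tok[2])
        raise ParseError(f"unexpected token {tok[1]!r} in input restriction", pos=tok[2])

    return parse_or()


def _parse_state_formula(
    ts: _TokenStream,
    patterns: Mapping[str, PhenotypePattern],
    environments: Mapping[str, Mapping[str, int]],
    model: LogicalModel | None,
) -> arctl.Formula:
    def parse_or():
        node = parse_and()
        while (tok := ts.peek()) and tok[1] == "|":
            ts.next()
            node = arctl.Or(node, parse_and())
        return node

    def parse_and():
        node = parse_unary()
        while (tok := ts.peek()) and tok[1] == "&":
            ts.next()
            node = arctl.And(node, parse_unary())
        return node

    def parse_unary():
        tok = ts.peek()
        if tok is None:
            raise ParseError("unexpected end of formula", pos=-1)
        if tok[1] == "!":
            ts.next()
            return arctl.Not(parse_unary())
        if tok[1] == "(":
            ts.next()
            node = parse_or()
            ts.expect(")")
            return node
        if tok[0] == "name" and tok[1] in _MODAL_UNARY:
            op = ts.next()[1]
            ts.expect("(")
            alpha = _parse_alpha(ts, environments, model)
            ts.expect(")")
            ts.expect("(")
            phi = parse_or()
            ts.expect(")")
            return arctl.Modal(op, alpha, phi)
        if tok[0] == "name" and tok[1] in _MODAL_UNTIL:
            op = ts.next()[1]
            ts.expect("(")
            alpha = _parse_alpha(ts, environments, model)
            ts.expect(")")
            ts.expect("[")
            phi = parse_or()
            u = ts.next()
            if u[1] != "U":
                raise ParseError(f"expected 'U', found {u[1]!r}", pos=u[2])
            psi = parse_or()
            ts.expect("]")
            return arctl.Modal(op, alpha, phi, psi)
        if tok[0] == "name":
            ts.next()
            name = tok[1]
            if name == "true":
                return arctl.TrueF()
            if name == "false":
                return arctl.FalseF()
            nxt = ts.peek()
            if nxt and nxt[1] in ("=", ">=", "<="):
                op = ts.next()[1]
                val = ts.next()
                if val[0] != "int":
                    raise ParseError(
                        f"expected level, found {val[1]!r}", pos=val[2]
                    )
                _check_atom(model, name, int(val[1]), "state", tok[2])
                return arctl.Atom(name, op, int(val[1]))
            if name in patterns:
                return arctl.atom_pattern(patterns[name].constraints)
            raise ParseError(
                f"unknown pattern or incomplete comparison {name!r}", pos=tok[2]
            )
        raise ParseError(f"unexpected token {tok[1]!r}", pos=tok[2])

    return parse_or()


def parse_formula(
    text: str,
    patterns: Mapping[str, PhenotypePattern] | None = None,
    environments: Mapping[str, Mapping[str, int]] | None = None,
    model: LogicalModel | None = None,
) -> arctl.Formula:
    """Parse ARCTL formula text into an AST.

    Pattern names expand to conjunctions of state atoms, environment names
    to conjunctions of input atoms.  If ``model`` is given, atoms are
    type-checked (existence, internal/input placement, level ranges).
    """
    ts = _TokenStream(text)
    formula = _parse_state_formula(ts, patterns or {}, environments or {}, model)
    if not ts.at_end():
        tok = ts.peek()
        raise ParseError(f"trailing tokens after formula: {tok[1]!r}", pos=tok[2])
    return formula


def parse_query(
    text: str,
    patterns: Mapping[str, PhenotypePattern] | None = None,
    environments: Mapping[str, Mapping[str, int]] | None = None,
    model: LogicalModel | None = None,
) -> tuple[arctl.Formula | None, arctl.Formula]:
    """Parse ``INIT <state-pred> ; <formula>`` (the INIT prefix is optional);
    returns ``(init predicate or None, formula)``."""
    ts = _TokenStream(text)
    init = None
    tok = ts.peek()
    if tok and tok[0] == "name" and tok[1] == "INIT":
        ts.next()
        init = _parse_state_formula(ts, patterns or {}, environments or {}, model)
        ts.expect(";")
    formula = _parse_state_formula(ts, patterns or {}, environments or {}, model)
    if not ts.at_end():
        tok = ts.peek()
        raise ParseError(f"trailing tokens after formula: {tok[1]!r}", pos=tok[2])
    return init, formula
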