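"""Model I/O: SBML-qual (XML) and BMA (JSON or XML) readers, SBML-qual
export, and the BMA algebraic expression evaluator.

SBML-qual update functions arrive as ordered lists of boolean terms over
integer propositions on variable levels, with a default output level for
uncovered inputs; overlaps are resolved first-listed-wins.  BMA update
functions are algebraic target functions (``+ - * /``, ``avg``, ``min``,
``max``, ``ceil``, ``floor``) evaluated in exact rational arithmetic,
with inputs rescaled into the target variable's range (half-up rounding)
and the result rounded half-up and clamped into the target domain.
Both formats use 0-based levels throughout.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Callable, Mapping, Sequence

from lxml import etree

from .bdd import BDD, FALSE, TRUE
from .model import MVN, Semantics, parse_native
from .series import BddSeries, OneHotVars, build_onehot

__all__ = [
    "QualTermList",
    "BmaExpression",
    "parse_sbml_qual",
    "terms_to_series",
    "parse_bma",
    "parse_bma_expression",
    "normalize_level",
    "eval_bma",
    "export_sbml_qual",
    "load_model",
]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
MATH_NS = "http://www.w3.org/1998/Math/MathML"


class ModelParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# boolean term formulas (SBML-qual)
# ---------------------------------------------------------------------------
#
# Formula AST (nested tuples):
#   ("const", bool)
#   ("cmp", op, variable, constant)   op in {eq, neq, lt, leq, gt, geq}
#   ("not", f) | ("and", [f..]) | ("or", [f..])

_CMP = {
    "eq": lambda a, b: a == b,
    "neq": lambda a, b: a != b,
    "lt": lambda a, b: a < b,
    "leq": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "geq": lambda a, b: a >= b,
}


def eval_formula(formula, values: Mapping[str, int]) -> bool:
    kind = formula[0]
    if kind == "const":
        return formula[1]
    if kind == "cmp":
        _, op, var, const = formula
        return _CMP[op](values[var], const)
    if kind == "not":
        return not eval_formula(formula[1], values)
    if kind == "and":
        return all(eval_formula(f, values) for f in formula[1])
    if kind == "or":
        return any(eval_formula(f, values) for f in formula[1])
    raise ValueError(f"bad formula node {kind!r}")


def formula_variables(formula) -> set[str]:
    kind = formula[0]
    if kind == "const":
        return set()
    if kind == "cmp":
        return {formula[2]}
    if kind == "not":
        return formula_variables(formula[1])
    return set().union(*(formula_variables(f) for f in formula[1]))


@dataclass(frozen=True)
class QualTermList:
    """Ordered (result level, formula) terms plus a default level."""

    default_level: int
    terms: tuple  # tuple[(int, formula), ...]

    def evaluate(self, values: Mapping[str, int]) -> int:
        for level, formula in self.terms:
            if eval_formula(formula, values):
                return level
        return self.default_level


class _TermFunction:
    """Update function backed by a term list (first-listed term wins)."""

    __slots__ = ("terms", "variables")

    def __init__(self, terms: QualTermList, variables: Sequence[str]):
        self.terms = terms
        self.variables = tuple(variables)

    def __call__(self, state) -> int:
        return self.terms.evaluate(dict(zip(self.variables, state)))


def _formula_bdd(formula, bdd: BDD, onehot: OneHotVars) -> int:
    """Condition BDD of a term formula over one-hot indicators.

    A comparison becomes the disjunction of the indicators of the
    satisfying levels; boolean connectives map directly.  Invalid
    one-hot combinations are don't-cares.
    """
    kind = formula[0]
    if kind == "const":
        return TRUE if formula[1] else FALSE
    if kind == "cmp":
        _, op, var, const = formula
        sat = [i for i in onehot.levels(var) if _CMP[op](i, const)]
        return bdd.disj(bdd.var(onehot.index[(var, i)]) for i in sat)
    if kind == "not":
        return bdd.apply_not(_formula_bdd(formula[1], bdd, onehot))
    parts = [_formula_bdd(f, bdd, onehot) for f in formula[1]]
    return bdd.conj(parts) if kind == "and" else bdd.disj(parts)


def terms_to_series(
    terms: QualTermList,
    mvn: MVN,
    variable: str,
    ordering: OneHotVars | None = None,
) -> BddSeries:
    """Turn a term list into a partition series: each term's condition
    minus all earlier ones, leftovers going to the default level."""
    from .series import _valid_states_bdd

    onehot = ordering if ordering is not None else build_onehot(mvn)
    bdd = BDD(onehot.num_vars)
    valid = _valid_states_bdd(bdd, onehot)
    covered = FALSE
    by_level: dict[int, list[int]] = {}
    for level, formula in terms.terms:
        cond = _formula_bdd(formula, bdd, onehot)
        fresh = bdd.apply_and(cond, bdd.apply_not(covered))
        if bdd.apply_and(fresh, valid) != FALSE:
            by_level.setdefault(level, []).append(fresh)
        covered = bdd.apply_or(covered, cond)
    rest = bdd.apply_not(covered)
    if bdd.apply_and(rest, valid) != FALSE:
        by_level.setdefault(terms.default_level, []).append(rest)
    entries = tuple(
        (level, bdd.disj(by_level[level])) for level in sorted(by_level)
    )
    return BddSeries(bdd, onehot, variable, entries)


# ---------------------------------------------------------------------------
# SBML-qual reading
# ---------------------------------------------------------------------------


def _q(tag: str) -> str:
    return f"{{{QUAL_NS}}}{tag}"


def _m(tag: str) -> str:
    return f"{{{MATH_NS}}}{tag}"


_MATH_OPS = {"eq": "eq", "neq": "neq", "lt": "lt", "leq": "leq",
             "gt": "gt", "geq": "geq"}


def _parse_mathml(node, species: set[str], context: str):
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise ModelParseError(f"{context}: math needs one child")
        return _parse_mathml(children[0], species, context)
    if tag == "true":
        return ("const", True)
    if tag == "false":
        return ("const", False)
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = children[1:]
        if op in ("and", "or"):
            return (op, [_parse_mathml(a, species, context) for a in args])
        if op == "not":
            return ("not", _parse_mathml(args[0], species, context))
        if op in _MATH_OPS:
            if len(args) != 2:
                raise ModelParseError(f"{context}: {op} needs two operands")
            a, b = args
            a_tag, b_tag = etree.QName(a).localname, etree.QName(b).localname
            if a_tag == "ci" and b_tag == "cn":
                var, const = a.text.strip(), int(float(b.text.strip()))
            elif a_tag == "cn" and b_tag == "ci":
                # mirror the comparison so the variable is on the left
                flip = {"lt": "gt", "gt": "lt", "leq": "geq",
                        "geq": "leq", "eq": "eq", "neq": "neq"}
                op = flip[_MATH_OPS[op]]
                var, const = b.text.strip(), int(float(a.text.strip()))
            else:
                raise ModelParseError(
                    f"{context}: comparisons must be variable-vs-integer"
                )
            if var not in species:
                raise ModelParseError(f"{context}: unknown species {var!r}")
            return ("cmp", _MATH_OPS.get(op, op), var, const)
        raise ModelParseError(f"{context}: unsupported MathML operator {op!r}")
    raise ModelParseError(f"{context}: unsupported MathML element {tag!r}")


def parse_sbml_qual(source) -> tuple[MVN, dict[str, QualTermList]]:
    """Read an SBML Level 3 qual model.

    Returns the MVN (one variable per qualitative species, domain
    ``[0, maxLevel]``) together with each variable's term list.  Species
    without a transition become inputs: identity update, or a constant
    at ``initialLevel`` when flagged constant.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        tree = etree.parse(str(source))
    else:
        text = source if isinstance(source, (str, bytes)) else source.read()
        if isinstance(text, str):
            text = text.encode()
        tree = etree.ElementTree(etree.fromstring(text))
    root = tree.getroot()

    species_nodes = root.findall(f".//{_q('qualitativeSpecies')}")
    if not species_nodes:
        raise ModelParseError("no qualitative species found (qual plugin missing?)")
    variables: list[str] = []
    domains: dict[str, tuple[int, int]] = {}
    constant: dict[str, bool] = {}
    initial: dict[str, int] = {}
    for node in species_nodes:
        sid = node.get(_q("id")) or node.get("id")
        if sid is None:
            raise ModelParseError("qualitative species without an id")
        max_level = node.get(_q("maxLevel")) or node.get("maxLevel")
        if max_level is None:
            raise ModelParseError(f"species {sid!r}: missing maxLevel")
        variables.append(sid)
        domains[sid] = (0, int(max_level))
        constant[sid] = (node.get(_q("constant")) or node.get("constant")
                         or "false").lower() == "true"
        init = node.get(_q("initialLevel")) or node.get("initialLevel")
        if init is not None:
            initial[sid] = int(init)
    names = set(variables)

    term_lists: dict[str, QualTermList] = {}
    for tr in root.findall(f".//{_q('transition')}"):
        outputs = tr.findall(f".//{_q('output')}")
        if len(outputs) != 1:
            raise ModelParseError("each transition needs exactly one output")
        target = (outputs[0].get(_q("qualitativeSpecies"))
                  or outputs[0].get("qualitativeSpecies"))
        if target not in names:
            raise ModelParseError(f"transition output {target!r} is not a species")
        lo, hi = domains[target]
        default_level: int | None = None
        terms: list[tuple[int, tuple]] = []
        for ft in tr.findall(f".//{_q('defaultTerm')}"):
            default_level = int(ft.get(_q("resultLevel")) or ft.get("resultLevel"))
        for ft in tr.findall(f".//{_q('functionTerm')}"):
            level = int(ft.get(_q("resultLevel")) or ft.get("resultLevel"))
            if not (lo <= level <= hi):
                raise ModelParseError(
                    f"species {target!r}: result level {level} > maxLevel {hi}"
                )
            math_node = ft.find(_m("math"))
            if math_node is None:
                raise ModelParseError(
                    f"species {target!r}: function term without MathML"
                )
            terms.append(
                (level, _parse_mathml(math_node, names, f"species {target!r}"))
            )
        if default_level is None:
            raise ModelParseError(f"species {target!r}: missing default term")
        if not (lo <= default_level <= hi):
            raise ModelParseError(
                f"species {target!r}: default level {default_level} out of range"
            )
        term_lists[target] = QualTermList(default_level, tuple(terms))

    for v in variables:
        if v not in term_lists:
            if constant[v] and v in initial:
                term_lists[v] = QualTermList(initial[v], ())
            else:
                # input node convention: keep the current value
                terms = tuple(
                    (i, ("cmp", "eq", v, i)) for i in range(1, domains[v][1] + 1)
                )
                term_lists[v] = QualTermList(0, terms)

    functions: dict[str, Callable] = {
        v: _TermFunction(term_lists[v], variables) for v in variables
    }
    return MVN(tuple(variables), domains, functions), term_lists


# ---------------------------------------------------------------------------
# SBML-qual export
# ---------------------------------------------------------------------------


def _level_condition_mathml(series: BddSeries, node_id: int):
    """Render one series condition as MathML: a disjunction, over the
    satisfying BDD paths, of conjunctions of per-variable level
    disjunctions (negative-only constraints expanded to allowed levels)."""
    bdd = series.manager
    onehot = series.onehot
    disjuncts = []
    for path in bdd.sat_paths(node_id):
        positives: dict[str, set[int]] = {}
        negatives: dict[str, set[int]] = {}
        for idx, pol in path.items():
            u, i = onehot.variable_of(idx)
            (positives if pol else negatives).setdefault(u, set()).add(i)
        if any(len(s) > 1 for s in positives.values()):
            continue  # covers no valid state
        conj = []
        dead = False
        for u in sorted(set(positives) | set(negatives)):
            if u in positives:
                allowed = sorted(positives[u])
            else:
                allowed = [i for i in onehot.levels(u) if i not in negatives[u]]
            if not allowed:
                dead = True
                break
            conj.append((u, allowed))
        if not dead:
            disjuncts.append(conj)

    def eq(u, i):
        apply_ = etree.SubElement(parent_stack[-1], _m("apply"))
        etree.SubElement(apply_, _m("eq"))
        ci = etree.SubElement(apply_, _m("ci"))
        ci.text = u
        cn = etree.SubElement(apply_, _m("cn"))
        cn.set("type", "integer")
        cn.text = str(i)

    math = etree.Element(_m("math"))
    parent_stack = [math]
    if not disjuncts:
        etree.SubElement(math, _m("false"))
        return math
    if disjuncts == [[]]:
        etree.SubElement(math, _m("true"))
        return math

    def emit_conj(conj):
        parts = list(conj)
        need_and = len(parts) > 1
        if need_and:
            apply_ = etree.SubElement(parent_stack[-1], _m("apply"))
            etree.SubElement(apply_, _m("and"))
            parent_stack.append(apply_)
        for u, allowed in parts:
            if len(allowed) > 1:
                apply_ = etree.SubElement(parent_stack[-1], _m("apply"))
                etree.SubElement(apply_, _m("or"))
                parent_stack.append(apply_)
                for i in allowed:
                    eq(u, i)
                parent_stack.pop()
            else:
                eq(u, allowed[0])
        if need_and:
            parent_stack.pop()

    if len(disjuncts) > 1:
        top = etree.SubElement(math, _m("apply"))
        etree.SubElement(top, _m("or"))
        parent_stack.append(top)
        for conj in disjuncts:
            if not conj:
                # a path with no constraints: condition is TRUE
                etree.SubElement(parent_stack[-1], _m("true"))
            else:
                emit_conj(conj)
        parent_stack.pop()
    else:
        emit_conj(disjuncts[0])
    return math


def export_sbml_qual(mvn: MVN, series: Mapping[str, BddSeries]) -> str:
    """Serialize as SBML Level 3 + qual: one species per variable
    (``maxLevel`` = domain top) and one function term per series entry,
    the lowest-level entry serving as the default term."""
    for v in mvn.variables:
        if mvn.domains[v][0] != 0:
            raise ModelParseError("SBML-qual export requires 0-based domains")
    nsmap = {None: SBML_NS, "qual": QUAL_NS}
    sbml = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "1")
    sbml.set(_q("required"), "true")
    model = etree.SubElement(sbml, f"{{{SBML_NS}}}model")
    model.set("id", "mvn")
    comps = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    comp = etree.SubElement(comps, f"{{{SBML_NS}}}compartment")
    comp.set("id", "default")
    comp.set("constant", "true")
    lqs = etree.SubElement(model, _q("listOfQualitativeSpecies"))
    for v in mvn.variables:
        sp = etree.SubElement(lqs, _q("qualitativeSpecies"))
        sp.set(_q("id"), v)
        sp.set(_q("compartment"), "default")
        sp.set(_q("constant"), "false")
        sp.set(_q("maxLevel"), str(mvn.domains[v][1]))
    lot = etree.SubElement(model, _q("listOfTransitions"))
    for v in mvn.variables:
        s = series[v]
        tr = etree.SubElement(lot, _q("transition"))
        tr.set(_q("id"), f"tr_{v}")
        from .series import support as series_support

        inputs = sorted(series_support(s) - {v}) + ([v] if v in series_support(s) else [])
        if inputs:
            loi = etree.SubElement(tr, _q("listOfInputs"))
            for n, u in enumerate(sorted(set(inputs))):
                inp = etree.SubElement(loi, _q("input"))
                inp.set(_q("id"), f"in_{v}_{n}")
                inp.set(_q("qualitativeSpecies"), u)
                inp.set(_q("transitionEffect"), "none")
        loo = etree.SubElement(tr, _q("listOfOutputs"))
        out = etree.SubElement(loo, _q("output"))
        out.set(_q("id"), f"out_{v}")
        out.set(_q("qualitativeSpecies"), v)
        out.set(_q("transitionEffect"), "assignmentLevel")
        loft = etree.SubElement(tr, _q("listOfFunctionTerms"))
        default = etree.SubElement(loft, _q("defaultTerm"))
        default.set(_q("resultLevel"), str(s.entries[0][0]))
        for level, node in s.entries[1:]:
            ft = etree.SubElement(loft, _q("functionTerm"))
            ft.set(_q("resultLevel"), str(level))
            ft.append(_level_condition_mathml(s, node))
    return etree.tostring(
        sbml, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


# ---------------------------------------------------------------------------
# BMA expressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BmaExpression:
    """Parsed algebraic target-function tree."""

    tree: tuple

    def variables(self) -> set[str]:
        out: set[str] = set()

        def walk(node):
            if node[0] == "var":
                out.add(node[1])
            elif node[0] in ("num",):
                pass
            else:
                for child in node[1:]:
                    if isinstance(child, tuple):
                        walk(child)
                    elif isinstance(child, list):
                        for c in child:
                            walk(c)

        walk(self.tree)
        return out


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+)|(?P<name>[A-Za-z_]\w*)|(?P<op>[-+*/(),]))"
)
_FUNCS = {"avg", "min", "max", "ceil", "floor"}


def parse_bma_expression(text: str) -> BmaExpression:
    """Recursive-descent parser for the BMA target-function language."""
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise ModelParseError(f"cannot tokenize formula at {text[pos:]!r}")
            break
        tokens.append(m.group("num") or m.group("name") or m.group("op"))
        pos = m.end()
    i = 0

    def peek():
        return tokens[i] if i < len(tokens) else None

    def take(expected=None):
        nonlocal i
        if i >= len(tokens):
            raise ModelParseError("unexpected end of formula")
        tok = tokens[i]
        if expected is not None and tok != expected:
            raise ModelParseError(f"expected {expected!r}, found {tok!r}")
        i += 1
        return tok

    def parse_expr():
        node = parse_term()
        while peek() in ("+", "-"):
            op = take()
            node = ("add" if op == "+" else "sub", node, parse_term())
        return node

    def parse_term():
        node = parse_factor()
        while peek() in ("*", "/"):
            op = take()
            rhs = parse_factor()
            if op == "/" and rhs == ("num", 0):
                raise ModelParseError("division by a zero constant")
            node = ("mul" if op == "*" else "div", node, rhs)
        return node

    def parse_factor():
        tok = peek()
        if tok == "-":
            take()
            return ("sub", ("num", 0), parse_factor())
        if tok == "(":
            take()
            node = parse_expr()
            take(")")
            return node
        if tok is None:
            raise ModelParseError("unexpected end of formula")
        if tok.isdigit():
            take()
            return ("num", int(tok))
        name = take()
        if name in _FUNCS and peek() == "(":
            take("(")
            args = [parse_expr()]
            while peek() == ",":
                take(",")
                args.append(parse_expr())
            take(")")
            if name in ("ceil", "floor") and len(args) != 1:
                raise ModelParseError(f"{name} takes one argument")
            if name in ("min", "max") and len(args) < 2:
                raise ModelParseError(f"{name} needs at least two arguments")
            return (name, args)
        if name == "var":
            take("(")
            ref = take()
            take(")")
            return ("var", ref)
        return ("var", name)

    tree = parse_expr()
    if i != len(tokens):
        raise ModelParseError(f"trailing tokens in formula: {tokens[i:]!r}")
    return BmaExpression(tree)


def _round_half_up(x: Fraction) -> int:
    return math.floor(x + Fraction(1, 2))


def normalize_level(
    value: int, source_range: tuple[int, int], target_range: tuple[int, int]
) -> int:
    """Linear rescale between integer ranges, rounded half-up, clamped."""
    lo_s, hi_s = source_range
    lo_t, hi_t = target_range
    if not (lo_s <= value <= hi_s):
        raise ValueError(f"value {value} outside source range [{lo_s}, {hi_s}]")
    if hi_s == lo_s:
        return lo_t
    scaled = lo_t + Fraction(value - lo_s) * Fraction(hi_t - lo_t, hi_s - lo_s)
    return min(hi_t, max(lo_t, _round_half_up(scaled)))


class BmaDivisionWarning(UserWarning):
    pass


def eval_bma(
    expr: BmaExpression,
    state: Sequence[int],
    target_variable: str,
    mvn: MVN,
) -> int:
    """Evaluate a target function on a state.

    Referenced inputs are first normalized into the target's range;
    arithmetic runs in exact rationals; the result is rounded half-up
    and clamped to the target domain.  Division by zero at evaluation
    time clamps to the domain minimum (with a warning).
    """
    import warnings

    lo, hi = mvn.domains[target_variable]
    values = dict(zip(mvn.variables, state))

    def ev(node) -> Fraction:
        kind = node[0]
        if kind == "num":
            return Fraction(node[1])
        if kind == "var":
            name = node[1]
            if name not in values:
                raise ModelParseError(f"unknown variable {name!r} in formula")
            return Fraction(
                normalize_level(values[name], mvn.domains[name], (lo, hi))
            )
        if kind == "add":
            return ev(node[1]) + ev(node[2])
        if kind == "sub":
            return ev(node[1]) - ev(node[2])
        if kind == "mul":
            return ev(node[1]) * ev(node[2])
        if kind == "div":
            denom = ev(node[2])
            if denom == 0:
                warnings.warn(
                    f"division by zero in {target_variable!r}; clamping to {lo}",
                    BmaDivisionWarning,
                )
                raise ZeroDivisionError
            return ev(node[1]) / denom
        if kind == "avg":
            args = [ev(a) for a in node[1]]
            return sum(args, Fraction(0)) / len(args)
        if kind == "min":
            return min(ev(a) for a in node[1])
        if kind == "max":
            return max(ev(a) for a in node[1])
        if kind == "ceil":
            return Fraction(math.ceil(ev(node[1][0])))
        if kind == "floor":
            return Fraction(math.floor(ev(node[1][0])))
        raise ModelParseError(f"bad expression node {kind!r}")

    try:
        raw = ev(expr.tree)
    except ZeroDivisionError:
        return lo
    return min(hi, max(lo, _round_half_up(raw)))


class _BmaFunction:
    """Update function: full-table evaluation of a BMA expression."""

    __slots__ = ("expr", "target", "mvn_ref")

    def __init__(self, expr: BmaExpression, target: str):
        self.expr = expr
        self.target = target
        self.mvn_ref: MVN | None = None  # set once the MVN exists

    def __call__(self, state) -> int:
        assert self.mvn_ref is not None
        return eval_bma(self.expr, state, self.target, self.mvn_ref)


def _get(d: Mapping, *keys, default=None):
    for k in keys:
        if k in d:
            return d[k]
    return default


def parse_bma(source) -> tuple[MVN, dict[str, BmaExpression]]:
    """Read a BMA model (JSON, or the XML layout with ``Variable`` /
    ``Relationship`` elements).

    Variables without a formula get the BMA-style default target:
    average of activator levels minus average of inhibitor levels (an
    empty side contributes zero).
    """
    if isinstance(source, Path) or (
        isinstance(source, str)
        and "\n" not in source
        and len(source) < 4096
        and not source.lstrip().startswith(("{", "<"))
    ):
        text = Path(source).read_text()
    else:
        text = source if isinstance(source, str) else source.read()
        if isinstance(text, bytes):
            text = text.decode()
    text_stripped = text.lstrip()
    if text_stripped.startswith("<"):
        variables_raw, relationships_raw = _parse_bma_xml(text)
    else:
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"malformed BMA JSON: {exc}") from exc
        model = _get(doc, "Model", "model", default=doc)
        variables_raw = [
            {
                "id": str(_get(v, "Id", "id")),
                "name": _get(v, "Name", "name") or f"v{_get(v, 'Id', 'id')}",
                "lo": int(_get(v, "RangeFrom", "rangeFrom", default=0)),
                "hi": int(_get(v, "RangeTo", "rangeTo", default=1)),
                "formula": (_get(v, "Formula", "formula") or "").strip(),
            }
            for v in _get(model, "Variables", "variables", default=[])
        ]
        relationships_raw = [
            {
                "from": str(_get(r, "FromVariable", "fromVariable", "FromVariableId")),
                "to": str(_get(r, "ToVariable", "toVariable", "ToVariableId")),
                "type": _get(r, "Type", "type", default="Activator"),
            }
            for r in _get(model, "Relationships", "relationships", default=[])
        ]

    if not variables_raw:
        raise ModelParseError("BMA model declares no variables")
    by_id = {v["id"]: v for v in variables_raw}
    names: list[str] = []
    for v in variables_raw:
        name = v["name"]
        if name in names:  # disambiguate duplicates by id
            name = f"{name}_{v['id']}"
            v["name"] = name
        names.append(name)
    id_to_name = {v["id"]: v["name"] for v in variables_raw}

    domains = {}
    for v in variables_raw:
        if v["hi"] < v["lo"]:
            raise ModelParseError(f"variable {v['name']!r}: empty range")
        domains[v["name"]] = (v["lo"], v["hi"])

    incoming: dict[str, list[tuple[str, str]]] = {n: [] for n in names}
    for r in relationships_raw:
        if r["from"] not in by_id or r["to"] not in by_id:
            raise ModelParseError(
                f"relationship references unknown variable id "
                f"{r['from']!r} or {r['to']!r}"
            )
        incoming[id_to_name[r["to"]]].append(
            (id_to_name[r["from"]], str(r["type"]))
        )

    expressions: dict[str, BmaExpression] = {}
    for v in variables_raw:
        name = v["name"]
        if v["formula"]:
            expr = parse_bma_expression(v["formula"])
            # resolve var(id) references to names
            def resolve(node):
                if node[0] == "var":
                    ref = node[1]
                    if ref in id_to_name:
                        return ("var", id_to_name[ref])
                    if ref not in domains:
                        raise ModelParseError(
                            f"formula of {name!r}: unknown variable {ref!r}"
                        )
                    return node
                if node[0] == "num":
                    return node
                if node[0] in ("avg", "min", "max", "ceil", "floor"):
                    return (node[0], [resolve(a) for a in node[1]])
                return (node[0], *[resolve(c) for c in node[1:]])

            expressions[name] = BmaExpression(resolve(expr.tree))
        else:
            activators = [u for u, t in incoming[name]
                          if t.lower().startswith("activ")]
            inhibitors = [u for u, t in incoming[name]
                          if t.lower().startswith("inhib")]
            pos = ("avg", [("var", u) for u in activators]) if activators else ("num", 0)
            neg = ("avg", [("var", u) for u in inhibitors]) if inhibitors else ("num", 0)
            expressions[name] = BmaExpression(("sub", pos, neg))

    functions: dict[str, Callable] = {}
    for v in variables_raw:
        functions[v["name"]] = _BmaFunction(expressions[v["name"]], v["name"])
    mvn = MVN(tuple(names), domains, functions)
    for f in functions.values():
        f.mvn_ref = mvn
    return mvn, expressions


def _parse_bma_xml(text: str):
    root = etree.fromstring(text.encode())

    def local(el):
        return etree.QName(el).localname

    def child_text(el, name):
        for c in el:
            if isinstance(c.tag, str) and local(c) == name:
                return (c.text or "").strip()
        return None

    variables_raw = []
    relationships_raw = []
    for el in root.iter():
        if not isinstance(el.tag, str):
            continue
        if local(el) == "Variable":
            vid = el.get("Id") or child_text(el, "Id")
            variables_raw.append(
                {
                    "id": str(vid),
                    "name": el.get("Name") or child_text(el, "Name") or f"v{vid}",
                    "lo": int(el.get("RangeFrom") or child_text(el, "RangeFrom") or 0),
                    "hi": int(el.get("RangeTo") or child_text(el, "RangeTo") or 1),
                    "formula": (el.get("Function") or child_text(el, "Function")
                                or el.get("Formula") or child_text(el, "Formula")
                                or "").strip(),
                }
            )
        elif local(el) == "Relationship":
            relationships_raw.append(
                {
                    "from": str(el.get("FromVariableId")
                                or child_text(el, "FromVariableId")
                                or el.get("FromVariable")
                                or child_text(el, "FromVariable")),
                    "to": str(el.get("ToVariableId")
                              or child_text(el, "ToVariableId")
                              or el.get("ToVariable")
                              or child_text(el, "ToVariable")),
                    "type": el.get("Type") or child_text(el, "Type") or "Activator",
                }
            )
    return variables_raw, relationships_raw


# ---------------------------------------------------------------------------
# front-door loader
# ---------------------------------------------------------------------------


def load_model(path, fmt: str | None = None) -> MVN:
    """Load a model file, auto-detecting the format from the extension
    and content (``sbml``, ``bmajson``, ``bmaxml`` or ``native``)."""
    path = Path(path)
    text = path.read_text()
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix == ".json":
            fmt = "bmajson"
        elif suffix in {".sbml", ".xml"}:
            fmt = "sbml" if "qualitativeSpecies" in text else "bmaxml"
        else:
            fmt = "native"
    if fmt == "sbml":
        return parse_sbml_qual(text)[0]
    if fmt == "bmajson" or fmt == "bmaxml":
        return parse_bma(text)[0]
    if fmt == "native":
        return parse_native(text)
    raise ModelParseError(f"unknown format {fmt!r}")
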