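"""Expression trees for kinetic laws and rules, with bidirectional
translation between human-readable infix strings and content MathML.

The tree (:class:`Expr`) is the lingua franca of the toolkit: SBML kinetic
laws and rules arrive as content MathML, HMOD files carry the same formulas
as infix text, and the simulator evaluates either.  The supported function
set is deliberately small and closed: what mass-action / Michaelis-Menten
kinetics need, plus ``tanh`` so that compiled neural-network activations are
representable in standard SBML MathML.

Structural round-trip identity is the module's contract:
``parse_infix(write_infix(e)) == e`` and
``parse_mathml(write_mathml(e)) == e`` for every valid tree.  Two
normalizations at parse time keep this exact: ``pow(a, b)`` becomes the
binary ``^`` operator, and unary minus applied directly to a numeric
literal folds into a negative literal.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

from lxml import etree

MATHML_NS = "http://www.w3.org/1998/Math/MathML"

#: unary functions in the closed set
_UNARY_FUNCTIONS = {"exp", "ln", "log10", "sqrt", "tanh", "abs"}
#: n-ary (>= 2) functions
_NARY_FUNCTIONS = {"min", "max"}
#: every callable name accepted by the infix grammar ("pow" normalizes to ^)
FUNCTIONS = _UNARY_FUNCTIONS | _NARY_FUNCTIONS | {"piecewise", "pow"}

BINARY_OPS = {"+", "-", "*", "/", "^", "<", "<=", ">", ">=", "==", "!="}
_RELATIONS = {"<", "<=", ">", ">=", "==", "!="}

IDENTIFIER_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")

NUMBER = "number"
SYMBOL = "symbol"
UNARY = "unary"  # always unary minus
BINARY = "binary"
CALL = "call"


class ExprError(ValueError):
    """Raised for malformed expressions (parse or structural)."""


class ExprSyntaxError(ExprError):
    """Infix syntax error carrying a 1-based column position."""

    def __init__(self, message: str, column: int):
        super().__init__(f"{message} (column {column})")
        self.column = column


class UnboundSymbolError(ExprError):
    def __init__(self, name: str):
        super().__init__(f"unbound symbol '{name}'")
        self.name = name


@dataclass(frozen=True)
class Expr:
    """Immutable expression tree node.

    ``kind`` is one of ``number``, ``symbol``, ``unary`` (minus), ``binary``
    (operator in :data:`BINARY_OPS`), ``call`` (function in the closed set).
    ``name`` holds the symbol/operator/function name; ``value`` the numeric
    literal for number nodes; ``args`` the children.
    """

    kind: str
    name: str = ""
    value: float = 0.0
    args: tuple["Expr", ...] = field(default_factory=tuple)

    # -- constructors -------------------------------------------------------
    @staticmethod
    def num(value: float) -> "Expr":
        return Expr(NUMBER, value=float(value))

    @staticmethod
    def sym(name: str) -> "Expr":
        if not IDENTIFIER_RE.match(name):
            raise ExprError(f"invalid identifier {name!r}")
        return Expr(SYMBOL, name=name)

    @staticmethod
    def neg(operand: "Expr") -> "Expr":
        if operand.kind == NUMBER:
            return Expr.num(-operand.value)
        return Expr(UNARY, name="-", args=(operand,))

    @staticmethod
    def bin(op: str, left: "Expr", right: "Expr") -> "Expr":
        if op not in BINARY_OPS:
            raise ExprError(f"unknown operator {op!r}")
        return Expr(BINARY, name=op, args=(left, right))

    @staticmethod
    def call_fn(name: str, args: Iterable["Expr"]) -> "Expr":
        args = tuple(args)
        if name == "pow":
            if len(args) != 2:
                raise ExprError("pow takes exactly two arguments")
            return Expr.bin("^", *args)
        if name in _UNARY_FUNCTIONS:
            if len(args) != 1:
                raise ExprError(f"{name} takes exactly one argument")
        elif name in _NARY_FUNCTIONS:
            if len(args) < 2:
                raise ExprError(f"{name} takes at least two arguments")
        elif name == "piecewise":
            if not args:
                raise ExprError("piecewise needs at least one argument")
        else:
            raise ExprError(f"unknown function {name!r}")
        return Expr(CALL, name=name, args=args)

    # -- convenience --------------------------------------------------------
    def symbols(self) -> set[str]:
        """All symbol names occurring in the tree."""
        if self.kind == SYMBOL:
            return {self.name}
        out: set[str] = set()
        for a in self.args:
            out |= a.symbols()
        return out

    def depth(self) -> int:
        if not self.args:
            return 1
        return 1 + max(a.depth() for a in self.args)

    def substitute(self, mapping: Mapping[str, "Expr"]) -> "Expr":
        """Return a copy with symbols replaced per ``mapping``."""
        if self.kind == SYMBOL:
            return mapping.get(self.name, self)
        if not self.args:
            return self
        return Expr(self.kind, self.name, self.value, tuple(a.substitute(mapping) for a in self.args))

    def rename_symbols(self, mapping: Mapping[str, str]) -> "Expr":
        return self.substitute({old: Expr.sym(new) for old, new in mapping.items()})

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return write_infix(self)


# ---------------------------------------------------------------------------
# numeric formatting: shortest repr that round-trips the double exactly
# ---------------------------------------------------------------------------

def format_number(v: float) -> str:
    if v != v:
        return "nan"
    if v == math.inf:
        return "inf"
    if v == -math.inf:
        return "-inf"
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(v)


# ---------------------------------------------------------------------------
# infix parsing (recursive descent)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?)
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op><=|>=|==|!=|[-+*/^<>(),])
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise ExprSyntaxError(f"unexpected character {text[pos]!r}", pos + 1)
        if m.lastgroup != "ws":
            kind = m.lastgroup
            assert kind is not None
            tokens.append((kind, m.group(), pos + 1))
        pos = m.end()
    tokens.append(("end", "", len(text) + 1))
    return tokens


class _Parser:
    """Standard precedence-climbing parser.

    Precedence (low to high): relations < additive < multiplicative <
    power (right-associative) < unary minus < atoms.  Unary minus binding
    tighter than ``^`` means ``-2^2`` is ``(-2)^2 = 4``.
    """

    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str, int]:
        return self.tokens[self.i]

    def advance(self) -> tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect_op(self, op: str) -> None:
        kind, val, col = self.peek()
        if kind != "op" or val != op:
            raise ExprSyntaxError(f"expected {op!r}", col)
        self.advance()

    def parse(self) -> Expr:
        e = self.relation()
        kind, val, col = self.peek()
        if kind != "end":
            raise ExprSyntaxError(f"unexpected token {val!r}", col)
        return e

    def relation(self) -> Expr:
        left = self.additive()
        kind, val, _ = self.peek()
        if kind == "op" and val in _RELATIONS:
            self.advance()
            right = self.additive()
            return Expr.bin(val, left, right)
        return left

    def additive(self) -> Expr:
        e = self.multiplicative()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in ("+", "-"):
                self.advance()
                e = Expr.bin(val, e, self.multiplicative())
            else:
                return e

    def multiplicative(self) -> Expr:
        e = self.power()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in ("*", "/"):
                self.advance()
                e = Expr.bin(val, e, self.power())
            else:
                return e

    def power(self) -> Expr:
        base = self.unary()
        kind, val, _ = self.peek()
        if kind == "op" and val == "^":
            self.advance()
            return Expr.bin("^", base, self.power())  # right-associative
        return base

    def unary(self) -> Expr:
        kind, val, _ = self.peek()
        if kind == "op" and val == "-":
            self.advance()
            return Expr.neg(self.unary())
        if kind == "op" and val == "+":
            self.advance()
            return self.unary()
        return self.atom()

    def atom(self) -> Expr:
        kind, val, col = self.advance()
        if kind == "number":
            return Expr.num(float(val))
        if kind == "name":
            nk, nv, _ = self.peek()
            if nk == "op" and nv == "(":
                if val not in FUNCTIONS:
                    raise ExprSyntaxError(f"unknown function {val!r}", col)
                self.advance()
                args = [self.relation()]
                while True:
                    k2, v2, c2 = self.peek()
                    if k2 == "op" and v2 == ",":
                        self.advance()
                        args.append(self.relation())
                    elif k2 == "op" and v2 == ")":
                        self.advance()
                        break
                    else:
                        raise ExprSyntaxError("expected ',' or ')'", c2)
                try:
                    return Expr.call_fn(val, args)
                except ExprError as exc:
                    raise ExprSyntaxError(str(exc), col) from exc
            return Expr.sym(val)
        if kind == "op" and val == "(":
            e = self.relation()
            self.expect_op(")")
            return e
        raise ExprSyntaxError(f"unexpected token {val!r}" if val else "unexpected end of expression", col)


def parse_infix(text: str) -> Expr:
    """Parse an infix expression string into an :class:`Expr`.

    Raises :class:`ExprSyntaxError` (with 1-based column) on malformed
    input; unknown function names are errors, not symbols.
    """
    if not text or not text.strip():
        raise ExprSyntaxError("empty expression", 1)
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# infix writing (minimal parentheses)
# ---------------------------------------------------------------------------

_PREC = {"<": 1, "<=": 1, ">": 1, ">=": 1, "==": 1, "!=": 1,
         "+": 2, "-": 2, "*": 3, "/": 3, "^": 4}
_PREC_UNARY = 5
_PREC_ATOM = 6


def _prec(e: Expr) -> int:
    if e.kind == BINARY:
        return _PREC[e.name]
    if e.kind == UNARY:
        return _PREC_UNARY
    if e.kind == NUMBER and e.value < 0:
        # a negative literal prints with a leading '-', parenthesize like unary
        return _PREC_UNARY
    return _PREC_ATOM


def write_infix(e: Expr) -> str:
    """Serialize to infix with parentheses only where precedence demands."""
    if e.kind == NUMBER:
        return format_number(e.value)
    if e.kind == SYMBOL:
        return e.name
    if e.kind == UNARY:
        (operand,) = e.args
        inner = write_infix(operand)
        if _prec(operand) < _PREC_UNARY:
            inner = f"({inner})"
        return f"-{inner}"
    if e.kind == CALL:
        return f"{e.name}({', '.join(write_infix(a) for a in e.args)})"
    # binary
    op = e.name
    p = _PREC[op]
    left, right = e.args
    ls, rs = write_infix(left), write_infix(right)
    if op in _RELATIONS:
        # relations are non-associative and lowest precedence
        if _prec(left) <= p:
            ls = f"({ls})"
        if _prec(right) <= p:
            rs = f"({rs})"
        return f"{ls} {op} {rs}"
    if op == "^":
        # right-associative: equal precedence on the left reassociates
        if _prec(left) <= p:
            ls = f"({ls})"
        if _prec(right) < p:
            rs = f"({rs})"
    else:
        # left-associative: equal precedence on the right reassociates
        # (structural identity requires parens even for a+(b+c))
        if _prec(left) < p:
            ls = f"({ls})"
        if _prec(right) <= p:
            rs = f"({rs})"
    return f"{ls}{op}{rs}"


# ---------------------------------------------------------------------------
# content MathML
# ---------------------------------------------------------------------------

_MATHML_OP_ELEMENTS = {
    "plus": "+", "minus": "-", "times": "*", "divide": "/", "power": "^",
    "lt": "<", "leq": "<=", "gt": ">", "geq": ">=", "eq": "==", "neq": "!=",
}
_MATHML_FN_ELEMENTS = {"exp": "exp", "ln": "ln", "tanh": "tanh", "abs": "abs",
                       "min": "min", "max": "max"}
_OP_TO_MATHML = {v: k for k, v in _MATHML_OP_ELEMENTS.items()}


class MathMLError(ExprError):
    pass


def _local(tag) -> str:
    if not isinstance(tag, str):
        return ""
    return tag.rsplit("}", 1)[-1]


def _parse_cn(el: etree._Element) -> Expr:
    ctype = el.get("type", "real")
    if ctype == "e-notation":
        parts = [el.text or ""]
        for child in el:
            if _local(child.tag) != "sep":
                raise MathMLError(f"unexpected element '{_local(child.tag)}' inside cn")
            parts.append(child.text or "")
            if child.tail:
                parts[-1] += child.tail
        if len(parts) != 2:
            raise MathMLError("e-notation cn needs mantissa<sep/>exponent")
        try:
            return Expr.num(float(parts[0].strip()) * 10.0 ** float(parts[1].strip()))
        except ValueError as exc:
            raise MathMLError(f"bad e-notation cn: {exc}") from exc
    if ctype == "rational":
        parts = [el.text or ""]
        for child in el:
            if _local(child.tag) != "sep":
                raise MathMLError(f"unexpected element '{_local(child.tag)}' inside cn")
            parts.append(child.text or "")
        if len(parts) != 2:
            raise MathMLError("rational cn needs numerator<sep/>denominator")
        return Expr.num(float(parts[0]) / float(parts[1]))
    if ctype not in ("real", "integer", "double"):
        raise MathMLError(f"unsupported cn type '{ctype}'")
    text = (el.text or "").strip()
    try:
        return Expr.num(float(text))
    except ValueError as exc:
        raise MathMLError(f"bad numeric literal {text!r} in cn") from exc


def _children(el: etree._Element) -> list[etree._Element]:
    return [c for c in el if isinstance(c.tag, str)]


def _parse_node(el: etree._Element) -> Expr:
    tag = _local(el.tag)
    if tag == "math":
        kids = _children(el)
        if len(kids) != 1:
            raise MathMLError("math element must contain exactly one expression")
        return _parse_node(kids[0])
    if tag == "ci":
        name = (el.text or "").strip()
        if not IDENTIFIER_RE.match(name):
            raise MathMLError(f"invalid identifier {name!r} in ci")
        return Expr.sym(name)
    if tag == "cn":
        return _parse_cn(el)
    if tag == "piecewise":
        args: list[Expr] = []
        otherwise: Expr | None = None
        for child in _children(el):
            ctag = _local(child.tag)
            if ctag == "piece":
                kids = _children(child)
                if len(kids) != 2:
                    raise MathMLError("piece must contain value and condition")
                args.append(_parse_node(kids[0]))
                args.append(_parse_node(kids[1]))
            elif ctag == "otherwise":
                kids = _children(child)
                if len(kids) != 1:
                    raise MathMLError("otherwise must contain one expression")
                otherwise = _parse_node(kids[0])
            else:
                raise MathMLError(f"unsupported element '{ctag}' inside piecewise")
        if otherwise is not None:
            args.append(otherwise)
        return Expr.call_fn("piecewise", args)
    if tag == "apply":
        kids = _children(el)
        if not kids:
            raise MathMLError("empty apply")
        head, *rest = kids
        op = _local(head.tag)
        if op == "apply":
            raise MathMLError("nested apply head is not supported")
        if op == "minus":
            if len(rest) == 1:
                return Expr.neg(_parse_node(rest[0]))
            if len(rest) == 2:
                return Expr.bin("-", _parse_node(rest[0]), _parse_node(rest[1]))
            raise MathMLError("minus takes one or two arguments")
        if op in ("plus", "times"):
            sym = _MATHML_OP_ELEMENTS[op]
            if len(rest) == 0:
                return Expr.num(0.0 if op == "plus" else 1.0)
            e = _parse_node(rest[0])
            for r in rest[1:]:
                e = Expr.bin(sym, e, _parse_node(r))
            return e
        if op in _MATHML_OP_ELEMENTS:
            if len(rest) != 2:
                raise MathMLError(f"{op} takes exactly two arguments")
            return Expr.bin(_MATHML_OP_ELEMENTS[op], _parse_node(rest[0]), _parse_node(rest[1]))
        if op == "log":
            base = 10.0
            operands = []
            for r in rest:
                if _local(r.tag) == "logbase":
                    kids2 = _children(r)
                    if len(kids2) != 1:
                        raise MathMLError("logbase must contain one expression")
                    b = _parse_node(kids2[0])
                    if b.kind != NUMBER:
                        raise MathMLError("only numeric logbase is supported")
                    base = b.value
                else:
                    operands.append(r)
            if len(operands) != 1:
                raise MathMLError("log takes exactly one operand")
            if base != 10.0:
                raise MathMLError(f"unsupported logbase {base!r} (only 10)")
            return Expr.call_fn("log10", [_parse_node(operands[0])])
        if op == "root":
            degree = 2.0
            operands = []
            for r in rest:
                if _local(r.tag) == "degree":
                    kids2 = _children(r)
                    if len(kids2) != 1:
                        raise MathMLError("degree must contain one expression")
                    d = _parse_node(kids2[0])
                    if d.kind != NUMBER:
                        raise MathMLError("only numeric root degree is supported")
                    degree = d.value
                else:
                    operands.append(r)
            if len(operands) != 1:
                raise MathMLError("root takes exactly one operand")
            if degree != 2.0:
                raise MathMLError(f"unsupported root degree {degree!r} (only 2)")
            return Expr.call_fn("sqrt", [_parse_node(operands[0])])
        if op in _MATHML_FN_ELEMENTS:
            return Expr.call_fn(_MATHML_FN_ELEMENTS[op], [_parse_node(r) for r in rest])
        raise MathMLError(f"unsupported MathML element '{op}'")
    raise MathMLError(f"unsupported MathML element '{tag}'")


def parse_mathml(xml: str | bytes | etree._Element) -> Expr:
    """Parse a content-MathML element (or serialized XML) into an Expr.

    Accepts the subset SBML kinetic laws use: apply/ci/cn, the arithmetic
    and relational operators, exp/ln/log(base 10)/root(degree 2)/tanh/
    abs/min/max and piecewise.  Unsupported elements raise
    :class:`MathMLError` naming the element.
    """
    if isinstance(xml, (str, bytes)):
        try:
            el = etree.fromstring(xml.encode() if isinstance(xml, str) else xml)
        except etree.XMLSyntaxError as exc:
            raise MathMLError(f"not well-formed XML: {exc}") from exc
    else:
        el = xml
    return _parse_node(el)


def _E(tag: str, *children: etree._Element, text: str | None = None,
       attrib: dict[str, str] | None = None) -> etree._Element:
    el = etree.Element(f"{{{MATHML_NS}}}{tag}", attrib=attrib or {})
    if text is not None:
        el.text = text
    for c in children:
        el.append(c)
    return el


def _write_node(e: Expr) -> etree._Element:
    if e.kind == NUMBER:
        v = e.value
        if v == int(v) and abs(v) < 1e16:
            return _E("cn", text=str(int(v)), attrib={"type": "integer"})
        return _E("cn", text=repr(v))
    if e.kind == SYMBOL:
        return _E("ci", text=e.name)
    if e.kind == UNARY:
        return _E("apply", _E("minus"), _write_node(e.args[0]))
    if e.kind == BINARY:
        return _E("apply", _E(_OP_TO_MATHML[e.name]),
                  _write_node(e.args[0]), _write_node(e.args[1]))
    # call
    if e.name == "log10":
        return _E("apply", _E("log"),
                  _E("logbase", _E("cn", text="10", attrib={"type": "integer"})),
                  _write_node(e.args[0]))
    if e.name == "sqrt":
        return _E("apply", _E("root"), _write_node(e.args[0]))
    if e.name == "piecewise":
        pw = _E("piecewise")
        args = list(e.args)
        pairs, otherwise = divmod(len(args), 2)
        for k in range(pairs):
            pw.append(_E("piece", _write_node(args[2 * k]), _write_node(args[2 * k + 1])))
        if otherwise:
            pw.append(_E("otherwise", _write_node(args[-1])))
        return pw
    return _E("apply", _E(e.name), *[_write_node(a) for a in e.args])


def write_mathml(e: Expr, wrap_math: bool = True) -> etree._Element:
    """Serialize an Expr to content MathML.

    With ``wrap_math`` (default) the result is a ``<math>`` element ready
    to embed in SBML; otherwise the bare expression element.  ``log10`` is
    emitted as ``log`` with an explicit logbase of 10.
    """
    node = _write_node(e)
    if not wrap_math:
        return node
    math_el = etree.Element(f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
    math_el.append(node)
    return math_el


def mathml_to_string(e: Expr) -> str:
    return etree.tostring(write_mathml(e), encoding="unicode")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

_BIN_EVAL: dict[str, Callable[[float, float], float]] = {
    "+": lambda a, b: a + b,
    "-": lambda a, b: a - b,
    "*": lambda a, b: a * b,
    "^": lambda a, b: a ** b,
    "<": lambda a, b: 1.0 if a < b else 0.0,
    "<=": lambda a, b: 1.0 if a <= b else 0.0,
    ">": lambda a, b: 1.0 if a > b else 0.0,
    ">=": lambda a, b: 1.0 if a >= b else 0.0,
    "==": lambda a, b: 1.0 if a == b else 0.0,
    "!=": lambda a, b: 1.0 if a != b else 0.0,
}

_FN_EVAL: dict[str, Callable[..., float]] = {
    "exp": math.exp,
    "ln": math.log,
    "log10": math.log10,
    "sqrt": math.sqrt,
    "tanh": math.tanh,
    "abs": abs,
    "min": min,
    "max": max,
}


def evaluate(e: Expr, env: Mapping[str, float]) -> float:
    """Evaluate with IEEE double semantics; division by zero yields ±inf.

    ``piecewise`` returns the value of the first true condition, else the
    trailing ``otherwise``; with no true branch and no otherwise an
    :class:`ExprError` is raised.  Unbound symbols raise
    :class:`UnboundSymbolError` naming the symbol.
    """
    if e.kind == NUMBER:
        return e.value
    if e.kind == SYMBOL:
        try:
            return float(env[e.name])
        except KeyError:
            raise UnboundSymbolError(e.name) from None
    if e.kind == UNARY:
        return -evaluate(e.args[0], env)
    if e.kind == BINARY:
        a = evaluate(e.args[0], env)
        b = evaluate(e.args[1], env)
        if e.name == "/":
            if b == 0.0:
                if a == 0.0:
                    return math.nan
                return math.copysign(math.inf, a) * math.copysign(1.0, b)
            return a / b
        try:
            result = _BIN_EVAL[e.name](a, b)
        except OverflowError:
            return math.inf
        except ZeroDivisionError:  # 0 ** negative
            return math.inf
        if isinstance(result, complex):  # negative base, fractional exponent
            return math.nan
        return float(result)
    # call
    if e.name == "piecewise":
        args = list(e.args)
        pairs, has_otherwise = divmod(len(args), 2)
        for k in range(pairs):
            if evaluate(args[2 * k + 1], env) != 0.0:
                return evaluate(args[2 * k], env)
        if has_otherwise:
            return evaluate(args[-1], env)
        raise ExprError("piecewise: no branch matched and no otherwise given")
    vals = [evaluate(a, env) for a in e.args]
    try:
        return float(_FN_EVAL[e.name](*vals))
    except OverflowError:
        return math.inf
    except ValueError:
        return math.nan
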