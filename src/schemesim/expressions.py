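"""Arithmetic/boolean expression language for kinetic laws, rules and triggers.

The grammar covers what appears in rendered mass-balance equations plus the
boolean operators event triggers need:

* numeric literals, identifiers, parentheses
* binary ``+ - * / ^`` with ``^`` right-associative and highest precedence
* unary minus (binding looser than ``^``, so ``-x^2`` is ``-(x^2)``)
* functions ``exp ln log10 sqrt abs pow min max`` and a single-condition
  ``piecewise(a, cond, b)``
* comparisons ``< <= > >= ==`` and ``and / or / not`` for triggers
* the reserved identifier ``t`` for simulation time

Expressions are parsed into a small immutable AST that the rest of the
package renders back to text, translates to SBML MathML, and compiles to
plain Python for fast right-hand-side evaluation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Tuple, Union

from .errors import ExpressionEvalError, ExpressionSyntaxError

__all__ = [
    "Num", "Sym", "Unary", "BinOp", "Call", "Node", "Expression",
    "parse", "evaluate", "render", "free_symbols", "to_python",
    "margin_ast", "substitute", "is_boolean", "FUNCTIONS", "TIME_SYMBOL",
]

TIME_SYMBOL = "t"

#: supported functions -> arity (None = variadic, >= 2)
FUNCTIONS = {
    "exp": 1, "ln": 1, "log10": 1, "sqrt": 1, "abs": 1,
    "pow": 2, "min": None, "max": None, "piecewise": 3,
}

_COMPARISONS = ("<", "<=", ">", ">=", "==")
_KEYWORDS = ("and", "or", "not")


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Sym:
    name: str


@dataclass(frozen=True)
class Unary:
    op: str            # "-" or "not"
    operand: "Node"


@dataclass(frozen=True)
class BinOp:
    op: str            # + - * / ^ < <= > >= == and or
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Call:
    func: str
    args: Tuple["Node", ...]


Node = Union[Num, Sym, Unary, BinOp, Call]


@dataclass(frozen=True)
class Expression:
    """A parsed expression: source text, AST and its free identifiers."""

    source: str
    ast: Node
    free_symbols: frozenset

    def __call__(self, bindings: Mapping[str, float], time: float = 0.0):
        return evaluate(self, bindings, time)


# ---------------------------------------------------------------------------
# Tokenizer

_TOKEN_RE = re.compile(
    r"(?P<ws>\s+)"
    r"|(?P<num>(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op><=|>=|==|[-+*/^<>(),])"
)


@dataclass(frozen=True)
class _Token:
    kind: str   # num | name | op | end
    text: str
    pos: int


def _tokenize(source: str):
    tokens = []
    pos = 0
    n = len(source)
    while pos < n:
        m = _TOKEN_RE.match(source, pos)
        if m is None:
            raise ExpressionSyntaxError(
                f"unexpected character {source[pos]!r}", source, pos)
        if m.lastgroup != "ws":
            tokens.append(_Token(m.lastgroup, m.group(), pos))
        pos = m.end()
    tokens.append(_Token("end", "", n))
    return tokens


# ---------------------------------------------------------------------------
# Pratt parser

# (left, right) binding powers; right < left => right-associative
_INFIX_BP = {
    "or": (1, 2), "and": (3, 4),
    "<": (5, 6), "<=": (5, 6), ">": (5, 6), ">=": (5, 6), "==": (5, 6),
    "+": (7, 8), "-": (7, 8),
    "*": (9, 10), "/": (9, 10),
    "^": (14, 13),
}
_PREFIX_MINUS_BP = 11   # between * and ^
_PREFIX_NOT_BP = 4      # tighter than and/or, looser than comparisons


class _Parser:
    def __init__(self, source: str):
        self.source = source
        self.tokens = _tokenize(source)
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, text: str) -> _Token:
        tok = self.advance()
        if tok.text != text:
            raise ExpressionSyntaxError(
                f"expected {text!r}, found {tok.text or 'end of input'!r}",
                self.source, tok.pos)
        return tok

    # -- entry -------------------------------------------------------------
    def parse(self) -> Node:
        node = self.parse_expr(0)
        tok = self.peek()
        if tok.kind != "end":
            raise ExpressionSyntaxError(
                f"unexpected token {tok.text!r}", self.source, tok.pos)
        return node

    def parse_expr(self, min_bp: int) -> Node:
        left = self._nud()
        while True:
            tok = self.peek()
            op = tok.text if tok.kind in ("op", "name") else None
            if op not in _INFIX_BP:
                break
            lbp, rbp = _INFIX_BP[op]
            if lbp < min_bp:
                break
            self.advance()
            right = self.parse_expr(rbp)
            left = BinOp(op, left, right)
        return left

    def _nud(self) -> Node:
        tok = self.advance()
        if tok.kind == "num":
            return Num(float(tok.text))
        if tok.kind == "name":
            if tok.text == "not":
                return Unary("not", self.parse_expr(_PREFIX_NOT_BP))
            if tok.text in ("and", "or"):
                raise ExpressionSyntaxError(
                    f"{tok.text!r} cannot start an expression",
                    self.source, tok.pos)
            if self.peek().text == "(" and tok.text in FUNCTIONS:
                return self._call(tok)
            if self.peek().text == "(":
                raise ExpressionSyntaxError(
                    f"unknown function {tok.text!r}", self.source, tok.pos)
            return Sym(tok.text)
        if tok.text == "(":
            node = self.parse_expr(0)
            self.expect(")")
            return node
        if tok.text == "-":
            return Unary("-", self.parse_expr(_PREFIX_MINUS_BP))
        raise ExpressionSyntaxError(
            f"unexpected token {tok.text or 'end of input'!r}",
            self.source, tok.pos)

    def _call(self, name_tok: _Token) -> Node:
        self.expect("(")
        args = [self.parse_expr(0)]
        while self.peek().text == ",":
            self.advance()
            args.append(self.parse_expr(0))
        self.expect(")")
        arity = FUNCTIONS[name_tok.text]
        if arity is None:
            if len(args) < 2:
                raise ExpressionSyntaxError(
                    f"{name_tok.text} needs at least 2 arguments",
                    self.source, name_tok.pos)
        elif len(args) != arity:
            raise ExpressionSyntaxError(
                f"{name_tok.text} takes {arity} argument(s), got {len(args)}",
                self.source, name_tok.pos)
        return Call(name_tok.text, tuple(args))


def parse(source: str) -> Expression:
    """Parse ``source`` into an :class:`Expression`."""
    ast = _Parser(source).parse()
    return Expression(source=source, ast=ast,
                      free_symbols=frozenset(free_symbols(ast)))


def free_symbols(node: Node) -> set:
    """All identifiers in ``node`` (function names excluded, ``t`` included)."""
    out = set()
    _collect(node, out)
    return out


def _collect(node: Node, out: set) -> None:
    if isinstance(node, Sym):
        out.add(node.name)
    elif isinstance(node, Unary):
        _collect(node.operand, out)
    elif isinstance(node, BinOp):
        _collect(node.left, out)
        _collect(node.right, out)
    elif isinstance(node, Call):
        for a in node.args:
            _collect(a, out)


def is_boolean(node: Node) -> bool:
    """True when the root of ``node`` produces a boolean (trigger context)."""
    if isinstance(node, BinOp):
        return node.op in _COMPARISONS or node.op in ("and", "or")
    if isinstance(node, Unary):
        return node.op == "not"
    return False


# ---------------------------------------------------------------------------
# Evaluation


def evaluate(expr, bindings: Mapping[str, float], time: float = 0.0):
    """Evaluate ``expr`` (Expression or bare AST) under ``bindings``.

    ``t`` is bound to ``time`` unless the caller supplies it explicitly.
    Raises :class:`ExpressionEvalError` on unbound symbols or arithmetic
    domain errors (``ln`` of a non-positive value, division by zero, ...).
    """
    node = expr.ast if isinstance(expr, Expression) else expr
    source = expr.source if isinstance(expr, Expression) else render(node)
    env = dict(bindings)
    env.setdefault(TIME_SYMBOL, time)
    return _eval(node, env, source)


def _eval(node: Node, env, source):
    if isinstance(node, Num):
        return node.value
    if isinstance(node, Sym):
        try:
            return env[node.name]
        except KeyError:
            raise ExpressionEvalError(
                f"unbound symbol {node.name!r} in {source!r}") from None
    if isinstance(node, Unary):
        v = _eval(node.operand, env, source)
        return (not bool(v)) if node.op == "not" else -v
    if isinstance(node, BinOp):
        op = node.op
        if op == "and":
            return bool(_eval(node.left, env, source)) and \
                bool(_eval(node.right, env, source))
        if op == "or":
            return bool(_eval(node.left, env, source)) or \
                bool(_eval(node.right, env, source))
        a = _eval(node.left, env, source)
        b = _eval(node.right, env, source)
        try:
            if op == "+":
                return a + b
            if op == "-":
                return a - b
            if op == "*":
                return a * b
            if op == "/":
                return a / b
            if op == "^":
                r = a ** b
                if isinstance(r, complex):
                    raise ExpressionEvalError(
                        f"complex result of {a}^{b} in {source!r}")
                return r
            if op == "<":
                return a < b
            if op == "<=":
                return a <= b
            if op == ">":
                return a > b
            if op == ">=":
                return a >= b
            if op == "==":
                return a == b
        except ZeroDivisionError:
            raise ExpressionEvalError(
                f"division by zero in {source!r}") from None
        raise ExpressionEvalError(f"unknown operator {op!r}")
    if isinstance(node, Call):
        if node.func == "piecewise":
            a, cond, b = node.args
            return _eval(a, env, source) if bool(_eval(cond, env, source)) \
                else _eval(b, env, source)
        args = [_eval(a, env, source) for a in node.args]
        try:
            if node.func == "exp":
                return math.exp(args[0])
            if node.func == "ln":
                if args[0] <= 0:
                    raise ExpressionEvalError(
                        f"ln of non-positive value {args[0]} in {source!r}")
                return math.log(args[0])
            if node.func == "log10":
                if args[0] <= 0:
                    raise ExpressionEvalError(
                        f"log10 of non-positive value {args[0]} in {source!r}")
                return math.log10(args[0])
            if node.func == "sqrt":
                if args[0] < 0:
                    raise ExpressionEvalError(
                        f"sqrt of negative value {args[0]} in {source!r}")
                return math.sqrt(args[0])
            if node.func == "abs":
                return abs(args[0])
            if node.func == "pow":
                return args[0] ** args[1]
            if node.func == "min":
                return min(args)
            if node.func == "max":
                return max(args)
        except OverflowError:
            raise ExpressionEvalError(
                f"overflow evaluating {node.func} in {source!r}") from None
        raise ExpressionEvalError(f"unknown function {node.func!r}")
    raise TypeError(f"not an AST node: {node!r}")


# ---------------------------------------------------------------------------
# Rendering

_PREC = {
    "or": 1, "and": 2, "not": 3,
    "<": 4, "<=": 4, ">": 4, ">=": 4, "==": 4,
    "+": 5, "-": 5, "*": 6, "/": 6, "neg": 7, "^": 8,
}
_ATOM = 99


def format_number(v: float) -> str:
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(v)


def render(node: Node) -> str:
    """Render an AST back to expression text; ``parse(render(x)).ast == x``."""
    return _render(node)[0]


def _render(node: Node):
    """Returns (text, precedence of the outermost construct)."""
    if isinstance(node, Num):
        return format_number(node.value), _ATOM
    if isinstance(node, Sym):
        return node.name, _ATOM
    if isinstance(node, Unary):
        if node.op == "not":
            text, prec = _render(node.operand)
            if prec < _PREC["not"]:
                text = f"({text})"
            return f"not {text}", _PREC["not"]
        text, prec = _render(node.operand)
        # operand of unary minus must bind tighter than unary minus itself,
        # except ^ which binds tighter anyway
        if prec <= _PREC["neg"] and prec != _PREC["^"]:
            if prec < _PREC["neg"]:
                text = f"({text})"
        return f"-{text}", _PREC["neg"]
    if isinstance(node, BinOp):
        op = node.op
        myprec = _PREC[op]
        ltext, lprec = _render(node.left)
        rtext, rprec = _render(node.right)
        if op == "^":
            # right-associative: parenthesize left unless it is an atom
            if lprec < _ATOM:
                ltext = f"({ltext})"
            if rprec < myprec:
                rtext = f"({rtext})"
        else:
            if lprec < myprec:
                ltext = f"({ltext})"
            # left-associative: right side needs strictly higher precedence
            if rprec <= myprec:
                rtext = f"({rtext})"
        spaced = op in ("and", "or") or op in _COMPARISONS
        sep = f" {op} " if spaced else op
        return f"{ltext}{sep}{rtext}", myprec
    if isinstance(node, Call):
        args = ", ".join(_render(a)[0] for a in node.args)
        return f"{node.func}({args})", _ATOM
    raise TypeError(f"not an AST node: {node!r}")


# ---------------------------------------------------------------------------
# Compilation to Python / trigger margins / substitution

_PY_FUNCS = {
    "exp": "math.exp", "ln": "math.log", "log10": "math.log10",
    "sqrt": "math.sqrt", "abs": "abs", "min": "min", "max": "max",
}


def to_python(node: Node, name_map: Mapping[str, str]) -> str:
    """Translate an AST into a Python expression string.

    ``name_map`` maps every free identifier (including ``t``) to the Python
    name it is bound to in the generated scope. ``math`` must be available.
    """
    if isinstance(node, Num):
        return repr(node.value)
    if isinstance(node, Sym):
        return name_map[node.name]
    if isinstance(node, Unary):
        x = to_python(node.operand, name_map)
        return f"(not ({x}))" if node.op == "not" else f"(-({x}))"
    if isinstance(node, BinOp):
        a = to_python(node.left, name_map)
        b = to_python(node.right, name_map)
        if node.op == "^":
            return f"(({a})**({b}))"
        if node.op in ("and", "or"):
            return f"(({a}) {node.op} ({b}))"
        return f"(({a}){node.op}({b}))"
    if isinstance(node, Call):
        if node.func == "piecewise":
            a, cond, b = (to_python(x, name_map) for x in node.args)
            return f"(({a}) if ({cond}) else ({b}))"
        if node.func == "pow":
            a, b = (to_python(x, name_map) for x in node.args)
            return f"(({a})**({b}))"
        args = ", ".join(to_python(x, name_map) for x in node.args)
        return f"{_PY_FUNCS[node.func]}({args})"
    raise TypeError(f"not an AST node: {node!r}")


def margin_ast(node: Node) -> Node:
    """Continuous indicator of a boolean trigger: positive iff true.

    Comparisons become signed differences, ``and``/``or`` become
    ``min``/``max`` of margins, ``not`` negates. Root-finding on the margin
    localizes the false->true crossing of the trigger.
    """
    if isinstance(node, BinOp):
        if node.op in (">", ">=", "=="):
            return BinOp("-", node.left, node.right)
        if node.op in ("<", "<="):
            return BinOp("-", node.right, node.left)
        if node.op == "and":
            return Call("min", (margin_ast(node.left), margin_ast(node.right)))
        if node.op == "or":
            return Call("max", (margin_ast(node.left), margin_ast(node.right)))
    if isinstance(node, Unary) and node.op == "not":
        return Unary("-", margin_ast(node.operand))
    raise ExpressionEvalError(
        f"trigger expression must be boolean, got {render(node)!r}")


def substitute(node: Node, mapping: Mapping[str, Node]) -> Node:
    """Replace symbols by AST nodes (used for renaming / inlining)."""
    if isinstance(node, Sym):
        return mapping.get(node.name, node)
    if isinstance(node, Unary):
        return Unary(node.op, substitute(node.operand, mapping))
    if isinstance(node, BinOp):
        return BinOp(node.op, substitute(node.left, mapping),
                     substitute(node.right, mapping))
    if isinstance(node, Call):
        return Call(node.func, tuple(substitute(a, mapping)
                                     for a in node.args))
    return node
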