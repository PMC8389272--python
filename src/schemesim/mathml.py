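"""MathML content markup <-> expression AST translation for SBML I/O."""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from lxml import etree

from . import expressions as ex
from .errors import SBMLImportError, UnsupportedSBMLError

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_URL = "http://www.sbml.org/sbml/symbols/time"
DELAY_URL = "http://www.sbml.org/sbml/symbols/delay"


def _tag(el) -> str:
    return etree.QName(el).localname


_BINARY_OPS = {
    "plus": "+", "minus": "-", "times": "*", "divide": "/", "power": "^",
    "lt": "<", "leq": "<=", "gt": ">", "geq": ">=", "eq": "==",
    "and": "and", "or": "or",
}
_UNARY_FUNCS = {"exp": "exp", "ln": "ln", "abs": "abs"}


def mathml_to_ast(math_el, functions: Optional[Dict] = None) -> ex.Node:
    """Translate a ``<math>`` element (or its child) into an AST.

    ``functions`` maps SBML functionDefinition ids to ``(argnames, body)``
    for inlining. Raises :class:`UnsupportedSBMLError` for csymbol delay and
    multi-piece piecewise, :class:`SBMLImportError` for anything unreadable.
    """
    children = [c for c in math_el if isinstance(c.tag, str)]
    if _tag(math_el) == "math":
        if len(children) != 1:
            raise SBMLImportError("<math> must contain exactly one child")
        return _node(children[0], functions or {})
    return _node(math_el, functions or {})


def _node(el, functions) -> ex.Node:
    tag = _tag(el)
    if tag == "cn":
        return ex.Num(_cn_value(el))
    if tag == "ci":
        return ex.Sym(el.text.strip())
    if tag == "csymbol":
        url = el.get("definitionURL", "")
        if "delay" in url:
            raise UnsupportedSBMLError(["csymbol delay"])
        if url == TIME_URL or url.endswith("/time"):
            return ex.Sym(ex.TIME_SYMBOL)
        raise SBMLImportError(f"unsupported csymbol {url!r}")
    if tag == "piecewise":
        return _piecewise(el, functions)
    if tag == "apply":
        return _apply(el, functions)
    if tag in ("true", "false"):
        # represent boolean constants as always-true/false comparisons
        return ex.BinOp("==", ex.Num(1.0), ex.Num(1.0 if tag == "true"
                                                  else 0.0))
    if tag == "pi":
        return ex.Num(3.141592653589793)
    if tag == "exponentiale":
        return ex.Num(2.718281828459045)
    raise SBMLImportError(f"unsupported MathML element <{tag}>")


def _cn_value(el) -> float:
    ctype = el.get("type", "real")
    texts = [el.text or ""]
    sep_tail = []
    for child in el:
        if _tag(child) == "sep":
            sep_tail.append(child.tail or "")
    if ctype in ("real", "integer"):
        return float(texts[0].strip())
    if ctype == "e-notation":
        mant = float(texts[0].strip())
        expo = float(sep_tail[0].strip())
        return mant * 10.0 ** expo
    if ctype == "rational":
        num = float(texts[0].strip())
        den = float(sep_tail[0].strip())
        return num / den
    raise SBMLImportError(f"unsupported <cn> type {ctype!r}")


def _piecewise(el, functions) -> ex.Node:
    pieces: List[Tuple[ex.Node, ex.Node]] = []
    otherwise = None
    for child in el:
        tag = _tag(child)
        parts = [c for c in child if isinstance(c.tag, str)]
        if tag == "piece":
            if len(parts) != 2:
                raise SBMLImportError("<piece> needs value and condition")
            pieces.append((_node(parts[0], functions),
                           _node(parts[1], functions)))
        elif tag == "otherwise":
            otherwise = _node(parts[0], functions)
    if len(pieces) != 1:
        raise UnsupportedSBMLError(["multiple piecewise"])
    value, cond = pieces[0]
    if otherwise is None:
        otherwise = ex.Num(0.0)
    return ex.Call("piecewise", (value, cond, otherwise))


def _apply(el, functions) -> ex.Node:
    parts = [c for c in el if isinstance(c.tag, str)]
    if not parts:
        raise SBMLImportError("empty <apply>")
    head, args_el = parts[0], parts[1:]
    op = _tag(head)

    if op == "csymbol" and "delay" in head.get("definitionURL", ""):
        raise UnsupportedSBMLError(["csymbol delay"])
    if op == "ci":
        # user-defined function application: inline the definition
        fname = head.text.strip()
        if fname not in functions:
            raise SBMLImportError(
                f"call of undefined function {fname!r}")
        argnames, body = functions[fname]
        if len(argnames) != len(args_el):
            raise SBMLImportError(
                f"function {fname!r} expects {len(argnames)} arguments")
        mapping = {name: _node(a, functions)
                   for name, a in zip(argnames, args_el)}
        return ex.substitute(body, mapping)

    args = [_node(a, functions) for a in args_el]
    if op in _BINARY_OPS:
        sym = _BINARY_OPS[op]
        if op == "minus" and len(args) == 1:
            return ex.Unary("-", args[0])
        if len(args) < 2:
            raise SBMLImportError(f"<{op}> needs at least 2 operands")
        node = args[0]
        for a in args[1:]:
            node = ex.BinOp(sym, node, a)
        return node
    if op == "not":
        return ex.Unary("not", args[0])
    if op in _UNARY_FUNCS:
        return ex.Call(_UNARY_FUNCS[op], (args[0],))
    if op == "log":
        base = None
        for child in el:
            if _tag(child) == "logbase":
                base_el = [c for c in child if isinstance(c.tag, str)][0]
                base = _node(base_el, functions)
        value = args[-1]
        if base is None or base == ex.Num(10.0):
            return ex.Call("log10", (value,))
        return ex.BinOp("/", ex.Call("ln", (value,)),
                        ex.Call("ln", (base,)))
    if op == "root":
        degree = None
        for child in el:
            if _tag(child) == "degree":
                deg_el = [c for c in child if isinstance(c.tag, str)][0]
                degree = _node(deg_el, functions)
        value = args[-1]
        if degree is None or degree == ex.Num(2.0):
            return ex.Call("sqrt", (value,))
        return ex.BinOp("^", value, ex.BinOp("/", ex.Num(1.0), degree))
    if op in ("min", "max"):
        return ex.Call(op, tuple(args))
    if op == "neq":
        return ex.Unary("not", ex.BinOp("==", args[0], args[1]))
    raise SBMLImportError(f"unsupported MathML operator <{op}>")


# ---------------------------------------------------------------------------
# AST -> MathML

_OP_TO_TAG = {v: k for k, v in _BINARY_OPS.items()}


def ast_to_mathml(node: ex.Node) -> etree._Element:
    """Wrap an AST in a ``<math>`` element."""
    math = etree.Element(f"{{{MATHML_NS}}}math")
    math.append(_element(node))
    return math


def _element(node: ex.Node) -> etree._Element:
    M = f"{{{MATHML_NS}}}"
    if isinstance(node, ex.Num):
        el = etree.Element(M + "cn")
        v = node.value
        if v == int(v) and abs(v) < 1e15:
            el.set("type", "integer")
            el.text = str(int(v))
        else:
            el.text = repr(v)
        return el
    if isinstance(node, ex.Sym):
        if node.name == ex.TIME_SYMBOL:
            el = etree.Element(M + "csymbol")
            el.set("encoding", "text")
            el.set("definitionURL", TIME_URL)
            el.text = "time"
            return el
        el = etree.Element(M + "ci")
        el.text = node.name
        return el
    if isinstance(node, ex.Unary):
        ap = etree.Element(M + "apply")
        etree.SubElement(ap, M + ("not" if node.op == "not" else "minus"))
        ap.append(_element(node.operand))
        return ap
    if isinstance(node, ex.BinOp):
        ap = etree.Element(M + "apply")
        etree.SubElement(ap, M + _OP_TO_TAG[node.op])
        ap.append(_element(node.left))
        ap.append(_element(node.right))
        return ap
    if isinstance(node, ex.Call):
        if node.func == "piecewise":
            value, cond, other = node.args
            pw = etree.Element(M + "piecewise")
            piece = etree.SubElement(pw, M + "piece")
            piece.append(_element(value))
            piece.append(_element(cond))
            otherwise = etree.SubElement(pw, M + "otherwise")
            otherwise.append(_element(other))
            return pw
        if node.func == "pow":
            ap = etree.Element(M + "apply")
            etree.SubElement(ap, M + "power")
            ap.append(_element(node.args[0]))
            ap.append(_element(node.args[1]))
            return ap
        if node.func == "sqrt":
            ap = etree.Element(M + "apply")
            etree.SubElement(ap, M + "root")
            ap.append(_element(node.args[0]))
            return ap
        if node.func == "ln":
            ap = etree.Element(M + "apply")
            etree.SubElement(ap, M + "ln")
            ap.append(_element(node.args[0]))
            return ap
        if node.func == "log10":
            ap = etree.Element(M + "apply")
            etree.SubElement(ap, M + "log")
            ap.append(_element(node.args[0]))
            return ap
        tag = {"exp": "exp", "abs": "abs", "min": "min",
               "max": "max"}.get(node.func)
        if tag is None:
            raise SBMLImportError(
                f"cannot express function {node.func!r} in MathML")
        ap = etree.Element(M + "apply")
        etree.SubElement(ap, M + tag)
        for a in node.args:
            ap.append(_element(a))
        return ap
    raise TypeError(f"not an AST node: {node!r}")
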