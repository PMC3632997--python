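"""Small arithmetic expression trees shared by the model readers.

Supports +, -, *, /, power, unary minus, numeric literals and variable
references — the subset needed for rate laws and lumped-parameter balance
equations.  Expressions round-trip between infix text (the equation-model
format) and MathML content markup (SBML kinetic laws and rules).
"""

from __future__ import annotations

import ast as _pyast
from dataclasses import dataclass

from lxml import etree

MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class ExprError(ValueError):
    pass


@dataclass(frozen=True)
class Expr:
    pass


@dataclass(frozen=True)
class Num(Expr):
    value: float


@dataclass(frozen=True)
class Var(Expr):
    name: str


@dataclass(frozen=True)
class Neg(Expr):
    arg: Expr


@dataclass(frozen=True)
class BinOp(Expr):
    op: str  # one of + - * / ^
    left: Expr
    right: Expr


_ALLOWED_OPS = {"+", "-", "*", "/", "^"}


def variables(expr: Expr) -> frozenset[str]:
    out: set[str] = set()
    stack = [expr]
    while stack:
        node = stack.pop()
        if isinstance(node, Var):
            out.add(node.name)
        elif isinstance(node, Neg):
            stack.append(node.arg)
        elif isinstance(node, BinOp):
            stack.extend((node.left, node.right))
    return frozenset(out)


def evaluate(expr: Expr, env: dict[str, float]) -> float:
    if isinstance(expr, Num):
        return expr.value
    if isinstance(expr, Var):
        try:
            return env[expr.name]
        except KeyError:
            raise ExprError(f"unbound variable {expr.name!r}") from None
    if isinstance(expr, Neg):
        return -evaluate(expr.arg, env)
    if isinstance(expr, BinOp):
        a = evaluate(expr.left, env)
        b = evaluate(expr.right, env)
        if expr.op == "+":
            return a + b
        if expr.op == "-":
            return a - b
        if expr.op == "*":
            return a * b
        if expr.op == "/":
            if b == 0:
                raise ExprError("division by zero")
            return a / b
        if expr.op == "^":
            return a**b
    raise ExprError(f"cannot evaluate node {expr!r}")


def rename(expr: Expr, mapping: dict[str, str]) -> Expr:
    if isinstance(expr, Var):
        return Var(mapping.get(expr.name, expr.name))
    if isinstance(expr, Neg):
        return Neg(rename(expr.arg, mapping))
    if isinstance(expr, BinOp):
        return BinOp(expr.op, rename(expr.left, mapping), rename(expr.right, mapping))
    return expr


# ---------------------------------------------------------------------------
# infix text


def parse_infix(text: str) -> Expr:
    """Parse infix arithmetic; both ``^`` and ``**`` denote power."""
    src = text.replace("^", "**").strip()
    if not src:
        raise ExprError("empty expression")
    try:
        tree = _pyast.parse(src, mode="eval")
    except SyntaxError as exc:
        raise ExprError(f"syntax error in expression {text!r}: {exc.msg}") from None
    return _from_pyast(tree.body, text)


_BINOP_MAP = {
    _pyast.Add: "+",
    _pyast.Sub: "-",
    _pyast.Mult: "*",
    _pyast.Div: "/",
    _pyast.Pow: "^",
}


def _from_pyast(node: _pyast.AST, source: str) -> Expr:
    if isinstance(node, _pyast.Constant):
        if isinstance(node.value, (int, float)) and not isinstance(node.value, bool):
            return Num(float(node.value))
        raise ExprError(f"non-numeric literal {node.value!r} in {source!r}")
    if isinstance(node, _pyast.Name):
        return Var(node.id)
    if isinstance(node, _pyast.UnaryOp):
        arg = _from_pyast(node.operand, source)
        if isinstance(node.op, _pyast.USub):
            return Neg(arg)
        if isinstance(node.op, _pyast.UAdd):
            return arg
        raise ExprError(f"unsupported unary operator in {source!r}")
    if isinstance(node, _pyast.BinOp):
        op = _BINOP_MAP.get(type(node.op))
        if op is None:
            raise ExprError(f"unsupported operator in {source!r}")
        return BinOp(op, _from_pyast(node.left, source), _from_pyast(node.right, source))
    raise ExprError(f"unsupported syntax in expression {source!r}")


def to_infix(expr: Expr, _parent_prec: int = 0) -> str:
    prec = {"+": 1, "-": 1, "*": 2, "/": 2, "^": 3}
    if isinstance(expr, Num):
        v = expr.value
        return repr(int(v)) if float(v).is_integer() else repr(v)
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Neg):
        inner = to_infix(expr.arg, 4)
        return f"-{inner}"
    if isinstance(expr, BinOp):
        p = prec[expr.op]
        left = to_infix(expr.left, p)
        # - and / are left-associative; ^ right-associative
        right = to_infix(expr.right, p + (0 if expr.op == "^" else 1))
        s = f"{left} {expr.op} {right}"
        return f"({s})" if p < _parent_prec else s
    raise ExprError(f"cannot render {expr!r}")


# ---------------------------------------------------------------------------
# MathML content markup

_MATHML_BINARY = {"divide": "/", "power": "^"}
_MATHML_NARY = {"plus": "+", "times": "*"}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def parse_mathml(element: etree._Element) -> Expr:
    """Parse a MathML content element (``<math>`` or its single child)."""
    if _local(element.tag) == "math":
        children = [c for c in element if isinstance(c.tag, str)]
        if len(children) != 1:
            raise ExprError("math element must have exactly one child")
        return parse_mathml(children[0])
    tag = _local(element.tag)
    if tag == "cn":
        return Num(float(element.text.strip()))
    if tag == "ci":
        return Var(element.text.strip())
    if tag == "apply":
        children = [c for c in element if isinstance(c.tag, str)]
        if not children:
            raise ExprError("empty apply element")
        op = _local(children[0].tag)
        args = [parse_mathml(c) for c in children[1:]]
        if op == "minus":
            if len(args) == 1:
                return Neg(args[0])
            if len(args) == 2:
                return BinOp("-", args[0], args[1])
            raise ExprError("minus takes one or two arguments")
        if op in _MATHML_BINARY:
            if len(args) != 2:
                raise ExprError(f"{op} takes two arguments")
            return BinOp(_MATHML_BINARY[op], args[0], args[1])
        if op in _MATHML_NARY:
            if not args:
                raise ExprError(f"{op} needs arguments")
            out = args[0]
            for nxt in args[1:]:
                out = BinOp(_MATHML_NARY[op], out, nxt)
            return out
        raise ExprError(f"unsupported MathML operator {op!r}")
    raise ExprError(f"unsupported MathML element {tag!r}")


def to_mathml(expr: Expr) -> etree._Element:
    """Render as a ``<math>`` element in the MathML namespace."""
    math = etree.Element(f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
    math.append(_to_mathml_node(expr))
    return math


_OP_ELEMENT = {"+": "plus", "-": "minus", "*": "times", "/": "divide", "^": "power"}


def _to_mathml_node(expr: Expr) -> etree._Element:
    if isinstance(expr, Num):
        el = etree.Element(f"{{{MATHML_NS}}}cn")
        v = expr.value
        el.text = repr(int(v)) if float(v).is_integer() else repr(v)
        if not float(v).is_integer():
            el.set("type", "real")
        return el
    if isinstance(expr, Var):
        el = etree.Element(f"{{{MATHML_NS}}}ci")
        el.text = f" {expr.name} "
        return el
    if isinstance(expr, Neg):
        apply = etree.Element(f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply, f"{{{MATHML_NS}}}minus")
        apply.append(_to_mathml_node(expr.arg))
        return apply
    if isinstance(expr, BinOp):
        apply = etree.Element(f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply, f"{{{MATHML_NS}}}{_OP_ELEMENT[expr.op]}")
        apply.append(_to_mathml_node(expr.left))
        apply.append(_to_mathml_node(expr.right))
        return apply
    raise ExprError(f"cannot render {expr!r}")
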