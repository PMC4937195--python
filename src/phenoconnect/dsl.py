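"""The transformation expression language and its interpreter.

Generated harmonization algorithms are written in a small, closed,
jQuery-style chained-method language: attribute values are accessed as
``$('name')`` and transformed by chaining calls, e.g.::

    $('Height').div(100).value()
    $('SEX').map({'1':'0','2':'1'})
    $('Height').unit('cm').toUnit('m').value()

Only the methods ``div, times, plus, pow, map, unit, toUnit, value`` exist;
this is a closed interpreter, not embedded JavaScript, so scripts are
testable and injection-safe. Arithmetic is exact decimal arithmetic; ``null``
(a missing value) is absorbing under every operation. A conditional form
``cond ? a : b`` (with ``>=, <=, >, <, ==`` and ``||``) exists for algorithm
templates only and is rejected by the default parser.

Both straight and typographic quotes are accepted on input; the canonical
printed form uses single straight quotes, and ``parse`` then ``str`` is a
fixpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation, localcontext
from fractions import Fraction
from typing import Optional, Union

log = logging.getLogger(__name__)

METHODS = frozenset({"div", "times", "plus", "pow", "map", "unit", "toUnit", "value"})
_ARITH = {"div", "times", "plus", "pow"}

QUOTES = {"'": "'", '"': '"', "‘": "’", "“": "”"}
_COMPARE_OPS = (">=", "<=", "==", ">", "<")


class DslSyntaxError(ValueError):
    """Raised when a script does not parse; carries the character position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


class DslEvalError(RuntimeError):
    """A runtime failure: unknown attribute, non-numeric operand, bad unit."""


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class AttrRef:
    name: str

    def render(self) -> str:
        return f"$('{self.name}')"


@dataclass(frozen=True)
class Const:
    value: Union[Decimal, str]

    def render(self) -> str:
        if isinstance(self.value, Decimal):
            return _render_number(self.value)
        return f"'{self.value}'"


@dataclass(frozen=True)
class MapLiteral:
    pairs: tuple[tuple[str, str], ...]

    def render(self) -> str:
        inner = ",".join(f"'{k}':'{v}'" for k, v in self.pairs)
        return "{" + inner + "}"


@dataclass(frozen=True)
class Call:
    method: str
    receiver: "Node"
    args: tuple["Node", ...] = ()

    def render(self) -> str:
        return f"{self.receiver.render()}.{self.method}({','.join(a.render() for a in self.args)})"


@dataclass(frozen=True)
class Compare:
    op: str
    left: "Node"
    right: "Node"

    def render(self) -> str:
        return f"{self.left.render()} {self.op} {self.right.render()}"


@dataclass(frozen=True)
class OrExpr:
    parts: tuple["Node", ...]

    def render(self) -> str:
        return " || ".join(p.render() for p in self.parts)


@dataclass(frozen=True)
class Ternary:
    condition: "Node"
    if_true: "Node"
    if_false: "Node"

    def render(self) -> str:
        return f"{self.condition.render()} ? {self.if_true.render()} : {self.if_false.render()}"


Node = Union[AttrRef, Const, MapLiteral, Call, Compare, OrExpr, Ternary]


def _render_number(d: Decimal) -> str:
    if d == d.to_integral_value():
        return str(d.quantize(Decimal(1)))
    return format(d.normalize(), "f")


@dataclass
class DslScript:
    """A parsed script: original text, AST and the attributes it reads."""

    source_text: str
    ast: Node
    referenced_attributes: frozenset[str] = field(default_factory=frozenset)

    def __str__(self) -> str:
        return self.ast.render()

    @property
    def canonical(self) -> str:
        return self.ast.render()


@dataclass
class EvalValue:
    """Result of evaluating a script on one row: a value and optional unit tag."""

    value: Union[Decimal, str, bool, None]
    unit: Optional[str] = None


# ---------------------------------------------------------------------------
# parser


class _Parser:
    def __init__(self, text: str, allow_conditional: bool):
        self.text = text
        self.pos = 0
        self.allow_conditional = allow_conditional

    def error(self, msg: str) -> DslSyntaxError:
        return DslSyntaxError(msg, self.pos)

    def _skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self._skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def startswith(self, s: str) -> bool:
        self._skip_ws()
        return self.text.startswith(s, self.pos)

    def expect(self, s: str) -> None:
        if not self.startswith(s):
            raise self.error(f"expected {s!r}")
        self.pos += len(s)

    def parse(self) -> Node:
        node = self.expression()
        self._skip_ws()
        if self.pos != len(self.text):
            raise self.error("unexpected trailing input")
        return node

    def expression(self) -> Node:
        node = self.or_expr()
        if self.startswith("?"):
            if not self.allow_conditional:
                raise self.error("conditional '?' is only allowed in templates")
            self.expect("?")
            if_true = self.or_expr()
            self.expect(":")
            if_false = self.or_expr()
            return Ternary(node, if_true, if_false)
        return node

    def or_expr(self) -> Node:
        parts = [self.comparison()]
        while self.startswith("||"):
            if not self.allow_conditional:
                raise self.error("'||' is only allowed in templates")
            self.expect("||")
            parts.append(self.comparison())
        return parts[0] if len(parts) == 1 else OrExpr(tuple(parts))

    def comparison(self) -> Node:
        left = self.chain()
        self._skip_ws()
        for op in _COMPARE_OPS:
            if self.text.startswith(op, self.pos):
                if not self.allow_conditional:
                    raise self.error(f"comparison {op!r} is only allowed in templates")
                self.pos += len(op)
                return Compare(op, left, self.chain())
        return left

    def chain(self) -> Node:
        node = self.primary()
        while self.startswith("."):
            self.expect(".")
            start = self.pos
            name = self._ident()
            if name not in METHODS:
                self.pos = start
                raise self.error(f"unknown method {name!r}")
            self.expect("(")
            args: list[Node] = []
            if not self.startswith(")"):
                args.append(self.argument())
                while self.startswith(","):
                    self.expect(",")
                    args.append(self.argument())
            self.expect(")")
            node = Call(name, node, tuple(args))
        return node

    def argument(self) -> Node:
        if self.peek() == "{":
            return self.map_literal()
        return self.chain()

    def primary(self) -> Node:
        c = self.peek()
        if c == "$":
            self.expect("$")
            self.expect("(")
            name = self._string()
            self.expect(")")
            return AttrRef(name)
        if c in QUOTES:
            return Const(self._string())
        if c.isdigit() or c == "-" or c == ".":
            return Const(self._number())
        raise self.error("expected $('attr'), a number or a string")

    def map_literal(self) -> MapLiteral:
        self.expect("{")
        pairs: list[tuple[str, str]] = []
        if not self.startswith("}"):
            while True:
                k = self._string()
                self.expect(":")
                v = self._string()
                pairs.append((k, v))
                if self.startswith(","):
                    self.expect(",")
                else:
                    break
        self.expect("}")
        return MapLiteral(tuple(pairs))

    def _ident(self) -> str:
        self._skip_ws()
        start = self.pos
        while self.pos < len(self.text) and (
            self.text[self.pos].isalnum() or self.text[self.pos] == "_"
        ):
            self.pos += 1
        if self.pos == start:
            raise self.error("expected an identifier")
        return self.text[start : self.pos]

    def _string(self) -> str:
        self._skip_ws()
        if self.pos >= len(self.text) or self.text[self.pos] not in QUOTES:
            raise self.error("expected a quoted string")
        close = QUOTES[self.text[self.pos]]
        closers = {close}
        self.pos += 1
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in closers:
            self.pos += 1
        if self.pos >= len(self.text):
            raise self.error("unterminated string")
        s = self.text[start : self.pos]
        self.pos += 1
        return s

    def _number(self) -> Decimal:
        self._skip_ws()
        start = self.pos
        if self.pos < len(self.text) and self.text[self.pos] == "-":
            self.pos += 1
        while self.pos < len(self.text) and (
            self.text[self.pos].isdigit() or self.text[self.pos] == "."
        ):
            self.pos += 1
        lit = self.text[start : self.pos]
        try:
            return Decimal(lit)
        except InvalidOperation:
            self.pos = start
            raise self.error(f"bad numeric literal {lit!r}") from None


def parse(script: str, allow_conditional: bool = False) -> DslScript:
    """Parse a script into a :class:`DslScript`.

    ``allow_conditional`` enables the ternary/comparison extension used by
    algorithm templates; auto-generated arithmetic never uses it.
    """
    if not script or not script.strip():
        raise DslSyntaxError("empty script", 0)
    ast = _Parser(script, allow_conditional).parse()
    return DslScript(
        source_text=script,
        ast=ast,
        referenced_attributes=frozenset(_collect_refs(ast)),
    )


def _collect_refs(node: Node) -> set[str]:
    if isinstance(node, AttrRef):
        return {node.name}
    if isinstance(node, Call):
        refs = _collect_refs(node.receiver)
        for a in node.args:
            refs |= _collect_refs(a)
        return refs
    if isinstance(node, Compare):
        return _collect_refs(node.left) | _collect_refs(node.right)
    if isinstance(node, OrExpr):
        out: set[str] = set()
        for p in node.parts:
            out |= _collect_refs(p)
        return out
    if isinstance(node, Ternary):
        return (
            _collect_refs(node.condition)
            | _collect_refs(node.if_true)
            | _collect_refs(node.if_false)
        )
    return set()


def referenced_attributes(script: DslScript) -> frozenset[str]:
    """Exactly the attribute names the script reads."""
    return script.referenced_attributes


# ---------------------------------------------------------------------------
# evaluator


def _as_decimal(v: EvalValue, what: str) -> Optional[Decimal]:
    if v.value is None:
        return None
    if isinstance(v.value, Decimal):
        return v.value
    if isinstance(v.value, str):
        try:
            return Decimal(v.value.strip())
        except InvalidOperation:
            raise DslEvalError(f"non-numeric value {v.value!r} in {what}") from None
    raise DslEvalError(f"non-numeric value {v.value!r} in {what}")


def evaluate(
    script: DslScript,
    row: dict,
    source_entity=None,
    unit_engine=None,
) -> EvalValue:
    """Evaluate a parsed script against one data row.

    ``source_entity`` (when given) defines which attribute names exist; a
    reference to an absent attribute raises :class:`DslEvalError`, which
    callers count as a conversion failure. A missing value (``None``)
    propagates: any arithmetic or mapping of ``null`` is ``null``. Division
    by zero yields ``null`` with a logged warning rather than an error.
    """
    known = (
        set(source_entity.attribute_names)
        if source_entity is not None
        else set(row.keys())
    )

    def ev(node: Node) -> EvalValue:
        if isinstance(node, AttrRef):
            if node.name not in known:
                raise DslEvalError(f"unknown attribute {node.name!r}")
            return EvalValue(row.get(node.name))
        if isinstance(node, Const):
            return EvalValue(node.value)
        if isinstance(node, Call):
            return ev_call(node)
        if isinstance(node, Compare):
            lv, rv = ev(node.left), ev(node.right)
            if lv.value is None or rv.value is None:
                return EvalValue(None)
            if node.op == "==":
                try:
                    return EvalValue(_as_decimal(lv, "==") == _as_decimal(rv, "=="))
                except DslEvalError:
                    return EvalValue(str(lv.value) == str(rv.value))
            left = _as_decimal(lv, node.op)
            right = _as_decimal(rv, node.op)
            result = {
                ">=": left >= right,
                "<=": left <= right,
                ">": left > right,
                "<": left < right,
            }[node.op]
            return EvalValue(result)
        if isinstance(node, OrExpr):
            saw_null = False
            for p in node.parts:
                v = ev(p).value
                if v is None:
                    saw_null = True
                elif v is True:
                    return EvalValue(True)
            return EvalValue(None if saw_null else False)
        if isinstance(node, Ternary):
            cond = ev(node.condition).value
            if cond is None:
                return EvalValue(None)
            return ev(node.if_true) if cond else ev(node.if_false)
        raise DslEvalError(f"cannot evaluate node {node!r}")

    def ev_call(node: Call) -> EvalValue:
        recv = ev(node.receiver)
        m = node.method
        if m == "value":
            return recv
        if m in _ARITH:
            cur = _as_decimal(recv, m)
            arg = _as_decimal(ev(node.args[0]), m)
            if cur is None or arg is None:
                return EvalValue(None)
            with localcontext() as ctx:
                ctx.prec = 28
                if m == "div":
                    if arg == 0:
                        log.warning("division by zero; result is null")
                        return EvalValue(None)
                    return EvalValue(cur / arg, recv.unit)
                if m == "times":
                    return EvalValue(cur * arg, recv.unit)
                if m == "plus":
                    return EvalValue(cur + arg, recv.unit)
                if m == "pow":
                    if arg == arg.to_integral_value():
                        return EvalValue(cur ** int(arg), recv.unit)
                    return EvalValue(
                        Decimal(float(cur) ** float(arg)), recv.unit
                    )
        if m == "map":
            if recv.value is None:
                return EvalValue(None)
            literal = node.args[0]
            if not isinstance(literal, MapLiteral):
                raise DslEvalError("map() takes a {'k':'v'} literal")
            key = (
                _render_number(recv.value)
                if isinstance(recv.value, Decimal)
                else str(recv.value)
            )
            for k, v in literal.pairs:
                if k == key:
                    return EvalValue(v)
            return EvalValue(None)  # unmapped code
        if m == "unit":
            tag = ev(node.args[0]).value
            return EvalValue(recv.value, str(tag))
        if m == "toUnit":
            target_unit = str(ev(node.args[0]).value)
            if recv.value is None:
                return EvalValue(None, target_unit)
            if recv.unit is None:
                raise DslEvalError("toUnit() before unit() — no source unit set")
            if unit_engine is None:
                raise DslEvalError("toUnit() needs a unit engine")
            factor: Fraction = unit_engine.value_factor(recv.unit, target_unit)
            cur = _as_decimal(recv, "toUnit")
            with localcontext() as ctx:
                ctx.prec = 28
                converted = cur * Decimal(factor.numerator) / Decimal(factor.denominator)
            return EvalValue(converted, target_unit)
        raise DslEvalError(f"unknown method {m!r}")

    return ev(script.ast)


def render_value(v: EvalValue, significant_digits: int = 10) -> Optional[str]:
    """Canonical string form of an evaluated value (for CSV export / preview).

    Decimals are rendered with up to ``significant_digits`` significant
    digits, trailing zeros stripped; booleans as ``true``/``false``.
    """
    if v.value is None:
        return None
    if isinstance(v.value, bool):
        return "true" if v.value else "false"
    if isinstance(v.value, Decimal):
        with localcontext() as ctx:
            ctx.prec = significant_digits
            return _render_number(+v.value)
    return str(v.value)
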