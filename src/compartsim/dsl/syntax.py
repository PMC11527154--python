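"""Abstract syntax of the rule language.

The surface language describes a model as ``;``-terminated statements:
constant and function definitions, species declarations, an initial
state, rewriting rules ``<left> -> <right> @ <rate>`` and observable
definitions.  Patterns are multisets of attributed species terms,
``{}`` (or ``()``) blocks give compartment contents, ``?x`` sequence
variables bind residual content, optionally with split weights
``?x[R]``.

The classes here are pure syntax: names are unresolved, numeric
literals still carry their written units.  Resolution and unit
checking happen in :mod:`compartsim.dsl.typecheck`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

from .units import Unit

# --------------------------------------------------------------------------
# expressions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Loc:
    line: int = 0
    col: int = 0

    def __str__(self) -> str:
        return f"{self.line}:{self.col}"


class Expr:
    """Base class for expression nodes."""

    loc: Loc


@dataclass(frozen=True)
class Num(Expr):
    value: float
    unit: Optional[Unit] = None  # None: plain dimensionless literal
    unit_text: Optional[str] = field(default=None, compare=False)
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class Str(Expr):
    value: str
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class Name(Expr):
    """Constant reference, bound attribute variable, or enum literal."""

    ident: str
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class AttrRef(Expr):
    """``S.attr`` -- attribute of the matched reactant of species S."""

    species: str
    attr: str
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class CountRef(Expr):
    """``#x`` -- population count bound to variable x."""

    var: str
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class BinOp(Expr):
    op: str  # + - * / ^ == != < > <= >= && ||
    left: Expr
    right: Expr
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class UnOp(Expr):
    op: str  # -
    operand: Expr
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class Call(Expr):
    fn: str
    args: Tuple[Expr, ...]
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class IfExpr(Expr):
    cond: Expr
    then: Expr
    els: Expr
    loc: Loc = field(default=Loc(), compare=False)


# --------------------------------------------------------------------------
# patterns
# --------------------------------------------------------------------------

#: comparison/assignment kinds usable in an attribute slot
CONSTRAINT_OPS = ("==", "!=", "<", ">", "<=", ">=", "=", "bind")


@dataclass(frozen=True)
class AttrConstraint:
    """One item of an attribute list: ``a==v``, ``a>v``, ``a=v`` (rhs
    assignment) or a bare binding ``a``."""

    name: str
    op: str  # member of CONSTRAINT_OPS
    expr: Optional[Expr] = None
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class SeqVar:
    """Sequence variable ``?x`` with optional split weight ``?x[R]``."""

    name: str
    weight: Optional[Expr] = None
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class PatternNode:
    """One species occurrence in a pattern multiset.

    ``count`` is an optional multiplicity expression (init / rhs).
    ``bind`` is a population binding ``Species:var``.  ``content`` is
    the nested multiset; ``None`` means "no content block written"
    (content implicitly preserved), which differs from an explicit
    empty block ``{}``.
    """

    species: str
    attrs: Tuple[AttrConstraint, ...] = ()
    bind: Optional[str] = None
    content: Optional[Tuple[Union["PatternNode", SeqVar], ...]] = None
    count: Optional[Expr] = None
    #: raw names from a ``(...)`` list that may be either a bare attribute
    #: binding or a content species; resolved during type checking
    ambiguous: Tuple[str, ...] = ()
    loc: Loc = field(default=Loc(), compare=False)


PatternElem = Union[PatternNode, SeqVar]
Pattern = Tuple[PatternElem, ...]

# --------------------------------------------------------------------------
# declarations / statements
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AttributeDecl:
    name: str
    kind: str  # int | real | string | enum | nf_int | nf_real
    unit: Optional[Unit] = None
    unit_text: Optional[str] = None
    enum_values: Tuple[str, ...] = ()
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class SpeciesDecl:
    name: str
    attributes: Tuple[AttributeDecl, ...] = ()
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class ConstDecl:
    name: str
    expr: Expr
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class FuncDecl:
    name: str
    params: Tuple[str, ...]
    body: Expr
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class RuleDef:
    lhs: Pattern
    rhs: Pattern
    rate: Expr
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class InitDecl:
    content: Pattern
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class ObserveDecl:
    name: str
    pattern: PatternNode
    scope: Optional[str] = None  # restrict to contents of this compartment species
    loc: Loc = field(default=Loc(), compare=False)


@dataclass(frozen=True)
class ModelAST:
    species: Tuple[SpeciesDecl, ...] = ()
    constants: Tuple[ConstDecl, ...] = ()
    functions: Tuple[FuncDecl, ...] = ()
    init: Optional[InitDecl] = None
    rules: Tuple[RuleDef, ...] = ()
    observables: Tuple[ObserveDecl, ...] = ()


# --------------------------------------------------------------------------
# pretty printer (inverse of the parser up to whitespace/comments)
# --------------------------------------------------------------------------

_PREC = {"||": 1, "&&": 2, "==": 3, "!=": 3, "<": 3, ">": 3, "<=": 3, ">=": 3,
         "+": 4, "-": 4, "*": 5, "/": 5, "^": 6}


def fmt_expr(e: Expr, prec: int = 0) -> str:
    if isinstance(e, Num):
        txt = repr(e.value) if e.value != int(e.value) else str(int(e.value))
        if e.unit_text:
            txt = f"{txt} {e.unit_text}"
        return txt
    if isinstance(e, Str):
        return f'"{e.value}"'
    if isinstance(e, Name):
        return e.ident
    if isinstance(e, AttrRef):
        return f"{e.species}.{e.attr}"
    if isinstance(e, CountRef):
        return f"#{e.var}"
    if isinstance(e, UnOp):
        inner = fmt_expr(e.operand, 7)
        return f"{e.op}{inner}"
    if isinstance(e, BinOp):
        p = _PREC[e.op]
        txt = f"{fmt_expr(e.left, p)} {e.op} {fmt_expr(e.right, p + 1)}"
        return f"({txt})" if p < prec else txt
    if isinstance(e, Call):
        return f"{e.fn}({', '.join(fmt_expr(a) for a in e.args)})"
    if isinstance(e, IfExpr):
        txt = f"if {fmt_expr(e.cond)} then {fmt_expr(e.then)} else {fmt_expr(e.els)}"
        return f"({txt})" if prec > 0 else txt
    raise TypeError(f"unknown expression node {e!r}")


def fmt_elem(el: PatternElem) -> str:
    if isinstance(el, SeqVar):
        txt = f"?{el.name}"
        if el.weight is not None:
            txt += f"[{fmt_expr(el.weight)}]"
        return txt
    parts = []
    if el.count is not None:
        parts.append(f"({fmt_expr(el.count)}) ")
    parts.append(el.species)
    items = [f"{c.name}" if c.op == "bind"
             else f"{c.name}{'==' if c.op == '==' else c.op}{fmt_expr(c.expr)}"
             for c in el.attrs]
    items += list(el.ambiguous)
    if el.bind is not None:
        txt_bind = f":{el.bind}"
    else:
        txt_bind = ""
    if items:
        parts.append("(" + ",".join(items) + ")")
    parts.append(txt_bind)
    if el.content is not None:
        parts.append("{" + " + ".join(fmt_elem(c) for c in el.content) + "}")
    return "".join(parts)


def fmt_pattern(p: Pattern) -> str:
    return " + ".join(fmt_elem(el) for el in p)


def pretty_print(ast: ModelAST) -> str:
    """Render an AST back to parseable model text."""

    lines: List[str] = []
    for c in ast.constants:
        lines.append(f"const {c.name}: {fmt_expr(c.expr)};")
    for f in ast.functions:
        lines.append(f"func {f.name}({', '.join(f.params)}): {fmt_expr(f.body)};")
    for s in ast.species:
        attrs = []
        for a in s.attributes:
            t = a.kind
            if a.kind == "enum":
                t = "enum {" + " ".join(a.enum_values) + "}"
            if a.unit_text:
                t += f" [{a.unit_text}]"
            attrs.append(f"{a.name}: {t}")
        lines.append(f"species {s.name}({', '.join(attrs)});")
    if ast.init is not None:
        lines.append(f"init {fmt_pattern(ast.init.content)};")
    for r in ast.rules:
        lhs = fmt_pattern(r.lhs)
        rhs = fmt_pattern(r.rhs)
        lines.append(f"{lhs} -> {rhs} @ {fmt_expr(r.rate)};")
    for o in ast.observables:
        scope = f" in {o.scope}" if o.scope else ""
        lines.append(f"observe {o.name}: {fmt_elem(o.pattern)}{scope};")
    return "\n".join(lines) + "\n"
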