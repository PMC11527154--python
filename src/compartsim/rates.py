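"""Rate-expression evaluation and cached partial evaluation.

After type checking, rate and effect expressions are a small typed IR
over literals, attribute accesses and population counts.  During
reaction enumeration the IR leaves are *bound*: attribute accesses
become state slots, population counts become count slots or
network-free eligibility queries, and variant-determined values become
literals.

Bound expressions are evaluated on the hot path through *performance
templates*: the expression tree is rendered to Python source with all
literals and slot indices abstracted into a parameter vector, compiled
once, and cached under its shape key.  Re-encountering the same shape
-- for another reaction instance, or after a simulator rebuild --
reuses the compiled callable with a fresh parameter vector, so rebuild
cost does not include recompilation.  The tree-walking interpreter
remains as the semantic reference and as the evaluator for cold paths
(effects at firing time, split weights, samplers).

All numeric values are in canonical units; unit bookkeeping ends at
type checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Callable, Dict, List, Optional, Tuple

__all__ = [
    "Lit", "StrLit", "AttrVal", "CountVal", "B", "U", "Fn", "Cond",
    "CountSlot", "AttrSlot", "NfCount", "SumSlots",
    "interpret", "EvalError", "TemplateCache", "Template", "parameterize",
]


class EvalError(ValueError):
    """Runtime evaluation failure (division by zero, negative rate...)."""


# --------------------------------------------------------------------------
# typed / bound IR
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Lit:
    value: float


@dataclass(frozen=True)
class StrLit:
    value: str


@dataclass(frozen=True)
class AttrVal:
    """Attribute of the entity matched by lhs node ``node`` (unbound)."""

    node: int
    attr: int


@dataclass(frozen=True)
class CountVal:
    """Population count ``#var`` (unbound)."""

    var: str


@dataclass(frozen=True)
class B:
    op: str
    left: Any
    right: Any


@dataclass(frozen=True)
class U:
    op: str
    operand: Any


@dataclass(frozen=True)
class Fn:
    name: str
    args: Tuple[Any, ...]


@dataclass(frozen=True)
class Cond:
    cond: Any
    then: Any
    els: Any


# bound leaves (produced by the matcher) ------------------------------------


@dataclass(frozen=True)
class CountSlot:
    """Count of one (compartment instance, species variant) slot."""

    slot: int


@dataclass(frozen=True)
class AttrSlot:
    """Per-instance compartment attribute slot."""

    slot: int


@dataclass(frozen=True)
class NfCount:
    """Number of eligible network-free instances in one store."""

    store: Any  # store key, opaque to the evaluator
    pred: Any   # callable(tuple) -> bool, opaque


@dataclass(frozen=True)
class SumSlots:
    """Sum of several count slots plus a constant offset.

    Used for ``#rest`` over a sequence variable: the residual element
    count of a compartment is the sum of its count slots minus the
    elements matched by other patterns, plus its (static) number of
    child compartments.
    """

    slots: Tuple[int, ...]
    offset: float


# --------------------------------------------------------------------------
# interpreter
# --------------------------------------------------------------------------

def _hill(x: float, k: float, n: float) -> float:
    xn = x ** n
    return xn / (xn + k ** n)


_PURE_FNS: Dict[str, Callable] = {
    "hill": _hill,
    "exp": math.exp,
    "ln": math.log,
    "log": math.log10,
    "sqrt": math.sqrt,
    "abs": abs,
    "floor": math.floor,
    "ceil": math.ceil,
    "round": round,
    "min": min,
    "max": max,
}

#: samplers; usable on rule right-hand sides and in init only
SAMPLER_FNS = ("norm", "unif", "pois")


class Env:
    """Evaluation environment protocol for :func:`interpret`.

    ``C``/``A`` are the flat count and attribute arrays, ``nf`` counts
    eligible network-free instances.  ``attr_val``/``count_val`` serve
    unbound leaves (effect evaluation at firing time), ``rng`` serves
    samplers.
    """

    C: List[float] = []
    A: List[float] = []
    rng = None

    def nf(self, store: Any, pred: Any) -> int:  # pragma: no cover - protocol
        raise EvalError("network-free count not available in this context")

    def attr_val(self, node: int, attr: int) -> Any:  # pragma: no cover
        raise EvalError("unbound attribute access in this context")

    def count_val(self, var: str) -> float:  # pragma: no cover
        raise EvalError(f"unbound count #{var} in this context")


def interpret(expr: Any, env: Env) -> Any:
    """Reference tree-walking evaluator (the semantic oracle)."""

    tp = type(expr)
    if tp is Lit:
        return expr.value
    if tp is StrLit:
        return expr.value
    if tp is CountSlot:
        return env.C[expr.slot]
    if tp is AttrSlot:
        return env.A[expr.slot]
    if tp is NfCount:
        return env.nf(expr.store, expr.pred)
    if tp is SumSlots:
        return sum(env.C[s] for s in expr.slots) + expr.offset
    if tp is AttrVal:
        return env.attr_val(expr.node, expr.attr)
    if tp is CountVal:
        return env.count_val(expr.var)
    if tp is B:
        op = expr.op
        if op == "&&":
            return bool(interpret(expr.left, env)) and bool(interpret(expr.right, env))
        if op == "||":
            return bool(interpret(expr.left, env)) or bool(interpret(expr.right, env))
        a = interpret(expr.left, env)
        b = interpret(expr.right, env)
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
                return a ** b
        except ZeroDivisionError as exc:
            raise EvalError("division by zero in rate expression") from exc
        if op == "==":
            return a == b
        if op == "!=":
            return a != b
        if op == "<":
            return a < b
        if op == ">":
            return a > b
        if op == "<=":
            return a <= b
        if op == ">=":
            return a >= b
        raise EvalError(f"unknown operator {op}")
    if tp is U:
        return -interpret(expr.operand, env)
    if tp is Cond:
        if interpret(expr.cond, env):
            return interpret(expr.then, env)
        return interpret(expr.els, env)
    if tp is Fn:
        args = [interpret(a, env) for a in expr.args]
        if expr.name in _PURE_FNS:
            return _PURE_FNS[expr.name](*args)
        if expr.name == "norm":
            return float(env.rng.normal(args[0], args[1]))
        if expr.name == "unif":
            return float(env.rng.uniform(args[0], args[1]))
        if expr.name == "pois":
            return float(env.rng.poisson(args[0]))
        raise EvalError(f"unknown function {expr.name}")
    raise EvalError(f"cannot evaluate node {expr!r}")


# --------------------------------------------------------------------------
# performance templates
# --------------------------------------------------------------------------


@dataclass
class Template:
    """A compiled, shape-keyed evaluator.

    ``fn(P, C, A, nf)`` evaluates the expression with parameter vector
    ``P`` against count array ``C``, attribute array ``A`` and
    network-free counter ``nf``.
    """

    shape_key: str
    fn: Callable[[Tuple, List[float], List[float], Callable], float]


def _emit(expr: Any, params: List[Any]) -> str:
    """Render *expr* to Python source; abstract leaves into ``P``.

    Every literal value and slot index is appended to ``params`` and
    referenced as ``P[i]``; the emitted source is the shape key,
    identical for all expressions of equal shape.
    """

    def slot(v: Any) -> str:
        params.append(v)
        return f"P[{len(params) - 1}]"

    tp = type(expr)
    if tp is Lit:
        return slot(expr.value)
    if tp is StrLit:
        return slot(expr.value)
    if tp is CountSlot:
        return f"C[{slot(expr.slot)}]"
    if tp is AttrSlot:
        return f"A[{slot(expr.slot)}]"
    if tp is NfCount:
        return f"nf({slot(expr.store)},{slot(expr.pred)})"
    if tp is SumSlots:
        terms = "+".join(f"C[{slot(s)}]" for s in expr.slots)
        terms = terms or "0.0"
        return f"({terms}+{slot(expr.offset)})"
    if tp is B:
        op = {"^": "**", "&&": "and", "||": "or"}.get(expr.op, expr.op)
        return f"({_emit(expr.left, params)}{op}{_emit(expr.right, params)})"
    if tp is U:
        return f"(-{_emit(expr.operand, params)})"
    if tp is Cond:
        return (f"({_emit(expr.then, params)} if {_emit(expr.cond, params)}"
                f" else {_emit(expr.els, params)})")
    if tp is Fn:
        if expr.name in SAMPLER_FNS:
            raise EvalError(f"sampler {expr.name!r} not allowed in rate position")
        if expr.name not in _PURE_FNS:
            raise EvalError(f"unknown function {expr.name}")
        args = ",".join(_emit(a, params) for a in expr.args)
        return f"_{expr.name}({args})"
    raise EvalError(f"cannot compile node {expr!r} (unbound leaf)")


_COMPILE_GLOBALS = {f"_{name}": fn for name, fn in _PURE_FNS.items()}
_COMPILE_GLOBALS["__builtins__"] = {}


def parameterize(expr: Any) -> Tuple:
    """Extract the parameter vector for *expr* (mirrors compilation order)."""
    params: List[Any] = []
    _emit(expr, params)
    return tuple(params)


class TemplateCache:
    """Content-addressed cache of compiled rate-expression templates.

    The shape key abstracts *all* numeric literals and slot indices, so
    two expressions differing only in constants or indices share one
    compiled evaluator and differ in their parameter vectors.
    """

    def __init__(self) -> None:
        self._templates: Dict[str, Template] = {}
        self.compilations = 0
        self.hits = 0

    def get_or_compile(self, bound_expr: Any) -> Tuple[Template, Tuple]:
        params: List[Any] = []
        src = _emit(bound_expr, params)
        tmpl = self._templates.get(src)
        if tmpl is None:
            self.compilations += 1
            code = compile(f"lambda P,C,A,nf:({src})", "<template>", "eval")
            fn = eval(code, dict(_COMPILE_GLOBALS))
            tmpl = Template(src, fn)
            self._templates[src] = tmpl
        else:
            self.hits += 1
        return tmpl, tuple(params)

    def __len__(self) -> int:
        return len(self._templates)
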