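"""Name resolution, type and unit checking.

Turns a :class:`~compartsim.dsl.syntax.ModelAST` into a
:class:`~compartsim.model.TypedModel`:

* species whose occurrences ever carry a content block are derived to
  be compartments; network-free attributes are rejected on them;
* constants are folded to canonical-unit floats;
* every expression is resolved against the rule's bindings (bare
  attribute bindings, ``S.attr`` accesses, ``#x`` population counts,
  sequence variables) and checked dimensionally -- a metre adds to
  centimetres but not to seconds;
* rate expressions must reduce to 1/time or be fully dimensionless
  (a dimensionless rate is read as "per canonical time unit");
* rules are paired (rhs occurrences linked to the lhs occurrence they
  preserve) and classified regular/structural.
"""

from __future__ import annotations

from typing import Any, Dict, List, Optional, Tuple, Union

from .. import rates as R
from ..model import (AttributeDef, ModelError, ROOT_SPECIES, Species,
                     TypedModel, TypedNode, TypedObservable, TypedRule,
                     TypedSeqVar)
from . import syntax as S
from .parser import parse
from .units import DIMENSIONLESS, Unit

__all__ = ["typecheck", "load_model", "infer_unit", "UnitMismatch"]

NumType = Tuple[str, Tuple[int, ...]]  # ("num", dims) | ("str", ()) | ("bool", ())
NUM0: NumType = ("num", (0, 0, 0, 0, 0))
STR_T: NumType = ("str", ())
BOOL_T: NumType = ("bool", ())

_PER_TIME = (0, -1, 0, 0, 0)

_CMP_OPS = ("==", "!=", "<", ">", "<=", ">=")


class UnitMismatch(ModelError):
    """Incompatible dimensions in an expression."""


def _dims_mul(a, b, sign=1):
    return tuple(x + sign * y for x, y in zip(a, b))


def _dimless(t: NumType) -> bool:
    return t[0] == "num" and all(d == 0 for d in t[1])


class _RuleEnv:
    """Per-rule binding environment."""

    def __init__(self) -> None:
        self.attr_bindings: Dict[str, Tuple[TypedNode, int]] = {}
        self.species_nodes: Dict[str, List[TypedNode]] = {}
        self.pop_vars: Dict[str, TypedNode] = {}
        self.seq_vars: Dict[str, TypedSeqVar] = {}


class _Checker:
    def __init__(self, ast: S.ModelAST, max_indices: int):
        self.ast = ast
        self.max_indices = max_indices
        self.functions = {f.name: f for f in ast.functions}
        self.constants: Dict[str, float] = {}
        self.constant_units: Dict[str, Unit] = {}
        self.species: List[Species] = []
        self.by_name: Dict[str, Species] = {}
        self._node_counter = 0

    # ------------------------------------------------------------------
    def run(self) -> TypedModel:
        self._build_species()
        self._fold_constants()
        rules = [self._check_rule(i, r) for i, r in enumerate(self.ast.rules)]
        init = self._check_init()
        observables = [self._check_observable(o) for o in self.ast.observables]
        model = TypedModel(self.species, self.by_name, self.constants,
                           self.constant_units, rules, init, observables,
                           max_indices=self.max_indices)
        from ..matcher import classify_rule  # cycle: matcher reads model types
        for rule in model.rules:
            rule.kind = classify_rule(rule)
        return model

    # ------------------------------------------------------------------
    # species table
    # ------------------------------------------------------------------
    def _build_species(self) -> None:
        compartment_names = set()

        def scan_elem(el) -> None:
            if isinstance(el, S.PatternNode):
                if el.content is not None:
                    compartment_names.add(el.species)
                    for c in el.content:
                        scan_elem(c)

        for r in self.ast.rules:
            for el in (*r.lhs, *r.rhs):
                scan_elem(el)
        if self.ast.init:
            for el in self.ast.init.content:
                scan_elem(el)
        for o in self.ast.observables:
            if o.scope:
                compartment_names.add(o.scope)

        decls = {ROOT_SPECIES: S.SpeciesDecl(ROOT_SPECIES, ())}
        for sd in self.ast.species:
            if sd.name in decls:
                raise ModelError(f"duplicate species {sd.name}", sd.loc)
            decls[sd.name] = sd
        compartment_names.add(ROOT_SPECIES)

        for name in compartment_names:
            if name not in decls:
                raise ModelError(f"unknown species {name!r} used as compartment")

        for sid, (name, sd) in enumerate(decls.items()):
            attrs = []
            for a in sd.attributes:
                if a.kind == "enum" and not a.enum_values:
                    raise ModelError(f"enum attribute {a.name} has empty value set",
                                     a.loc)
                attrs.append(AttributeDef(a.name, a.kind,
                                          a.unit or DIMENSIONLESS, a.enum_values))
            is_comp = name in compartment_names
            if is_comp and any(a.is_nf for a in attrs):
                raise ModelError(
                    f"species {name} is a compartment; network-free attributes "
                    f"are only supported on non-compartment species", sd.loc)
            sp = Species(sid, name, tuple(attrs), is_comp)
            self.species.append(sp)
            self.by_name[name] = sp

    # ------------------------------------------------------------------
    # constants
    # ------------------------------------------------------------------
    def _fold_constants(self) -> None:
        for c in self.ast.constants:
            if c.name in self.constants:
                raise ModelError(f"duplicate constant {c.name}", c.loc)
            ir, t = self._resolve(c.expr, env=None, allow_sampler=False)
            if t[0] != "num":
                raise ModelError(f"constant {c.name} is not numeric", c.loc)
            self.constants[c.name] = float(R.interpret(ir, R.Env()))
            self.constant_units[c.name] = Unit(t[1], 1.0)

    # ------------------------------------------------------------------
    # expression resolution
    # ------------------------------------------------------------------
    def _resolve(self, e: S.Expr, env: Optional[_RuleEnv],
                 allow_sampler: bool, allow_nf: bool = False,
                 depth: int = 0) -> Tuple[Any, NumType]:
        if depth > 50:
            raise ModelError("expression nesting/recursion too deep", e.loc)
        if isinstance(e, S.Num):
            unit = e.unit or DIMENSIONLESS
            return R.Lit(unit.to_canonical(e.value)), ("num", unit.dims)
        if isinstance(e, S.Str):
            return R.StrLit(e.value), STR_T
        if isinstance(e, S.Name):
            if env is not None and e.ident in env.attr_bindings:
                node, ai = env.attr_bindings[e.ident]
                return self._attr_access(node, ai, e.loc, allow_nf)
            if e.ident in self.constants:
                return (R.Lit(self.constants[e.ident]),
                        ("num", self.constant_units[e.ident].dims))
            raise ModelError(f"unknown identifier {e.ident!r}", e.loc)
        if isinstance(e, S.AttrRef):
            if env is None:
                raise ModelError(f"attribute access {e.species}.{e.attr} "
                                 f"outside a rule", e.loc)
            nodes = env.species_nodes.get(e.species)
            if not nodes:
                raise ModelError(
                    f"{e.species}.{e.attr}: no reactant of species {e.species}",
                    e.loc)
            if len(nodes) > 1:
                raise ModelError(
                    f"{e.species}.{e.attr} is ambiguous "
                    f"({len(nodes)} occurrences of {e.species})", e.loc)
            node = nodes[0]
            ai = node.species.attr_index.get(e.attr)
            if ai is None:
                raise ModelError(f"species {e.species} has no attribute {e.attr}",
                                 e.loc)
            return self._attr_access(node, ai, e.loc, allow_nf)
        if isinstance(e, S.CountRef):
            if env is None or (e.var not in env.pop_vars
                               and e.var not in env.seq_vars):
                raise ModelError(f"#{e.var}: unbound population variable", e.loc)
            return R.CountVal(e.var), NUM0
        if isinstance(e, S.UnOp):
            ir, t = self._resolve(e.operand, env, allow_sampler, allow_nf, depth + 1)
            if t[0] != "num":
                raise ModelError("unary '-' needs a numeric operand", e.loc)
            return R.U("-", ir), t
        if isinstance(e, S.BinOp):
            return self._resolve_binop(e, env, allow_sampler, allow_nf, depth)
        if isinstance(e, S.IfExpr):
            c, ct = self._resolve(e.cond, env, allow_sampler, allow_nf, depth + 1)
            if ct[0] != "bool":
                raise ModelError("'if' condition must be a comparison", e.loc)
            a, at = self._resolve(e.then, env, allow_sampler, allow_nf, depth + 1)
            b, bt = self._resolve(e.els, env, allow_sampler, allow_nf, depth + 1)
            if at != bt:
                raise UnitMismatch("'if' branches have different types/dimensions",
                                   e.loc)
            return R.Cond(c, a, b), at
        if isinstance(e, S.Call):
            return self._resolve_call(e, env, allow_sampler, allow_nf, depth)
        raise ModelError(f"unsupported expression {e!r}", getattr(e, "loc", None))

    def _attr_access(self, node: TypedNode, ai: int, loc,
                     allow_nf: bool) -> Tuple[Any, NumType]:
        attr = node.species.attributes[ai]
        if attr.is_nf and not allow_nf:
            raise ModelError(
                f"network-free attribute {node.species.name}.{attr.name} cannot "
                f"appear in rate or constraint position", loc)
        t = STR_T if not attr.is_numeric else ("num", attr.unit.dims)
        return R.AttrVal(node.node_id, ai), t

    def _resolve_binop(self, e: S.BinOp, env, allow_sampler, allow_nf,
                       depth) -> Tuple[Any, NumType]:
        a, at = self._resolve(e.left, env, allow_sampler, allow_nf, depth + 1)
        b, bt = self._resolve(e.right, env, allow_sampler, allow_nf, depth + 1)
        op = e.op
        if op in ("&&", "||"):
            if at[0] != "bool" or bt[0] != "bool":
                raise ModelError(f"{op} needs boolean operands", e.loc)
            return R.B(op, a, b), BOOL_T
        if op in _CMP_OPS:
            if at[0] == "str" and bt[0] == "str":
                if op not in ("==", "!="):
                    raise ModelError("strings only compare with == / !=", e.loc)
                return R.B(op, a, b), BOOL_T
            if at[0] != "num" or bt[0] != "num":
                raise ModelError(f"cannot compare {at[0]} with {bt[0]}", e.loc)
            if at[1] != bt[1]:
                raise UnitMismatch(
                    f"comparison between different dimensions "
                    f"({at[1]} vs {bt[1]})", e.loc)
            return R.B(op, a, b), BOOL_T
        if at[0] != "num" or bt[0] != "num":
            raise ModelError(f"operator {op} needs numeric operands", e.loc)
        if op in ("+", "-"):
            if at[1] != bt[1]:
                raise UnitMismatch(
                    f"cannot apply {op!r} to different dimensions "
                    f"({at[1]} vs {bt[1]})", e.loc)
            return R.B(op, a, b), at
        if op == "*":
            return R.B(op, a, b), ("num", _dims_mul(at[1], bt[1]))
        if op == "/":
            return R.B(op, a, b), ("num", _dims_mul(at[1], bt[1], -1))
        if op == "^":
            if all(d == 0 for d in at[1]):
                return R.B(op, a, b), NUM0
            if isinstance(b, R.Lit) and float(b.value).is_integer():
                n = int(b.value)
                return R.B(op, a, b), ("num", tuple(d * n for d in at[1]))
            raise UnitMismatch(
                "dimensioned base needs a constant integer exponent", e.loc)
        raise ModelError(f"unknown operator {op}", e.loc)

    def _resolve_call(self, e: S.Call, env, allow_sampler, allow_nf,
                      depth) -> Tuple[Any, NumType]:
        name = e.fn
        if name in self.functions:
            f = self.functions[name]
            if len(f.params) != len(e.args):
                raise ModelError(
                    f"{name} expects {len(f.params)} arguments", e.loc)
            body = _substitute(f.body, dict(zip(f.params, e.args)))
            return self._resolve(body, env, allow_sampler, allow_nf, depth + 1)
        args = [self._resolve(a, env, allow_sampler, allow_nf, depth + 1)
                for a in e.args]
        irs = tuple(ir for ir, _ in args)
        ts = [t for _, t in args]

        def need(n: int) -> None:
            if len(args) != n:
                raise ModelError(f"{name} expects {n} arguments", e.loc)

        if name in R.SAMPLER_FNS:
            if not allow_sampler:
                raise ModelError(
                    f"sampler {name!r} only allowed on rule right-hand sides "
                    f"and in the initial state", e.loc)
            need(1 if name == "pois" else 2)
            if any(t[0] != "num" for t in ts):
                raise ModelError(f"{name} needs numeric arguments", e.loc)
            if len(ts) == 2 and ts[0][1] != ts[1][1]:
                raise UnitMismatch(f"{name} arguments differ in dimension", e.loc)
            return R.Fn(name, irs), ts[0]
        if name == "hill":
            need(3)
            if ts[0][1] != ts[1][1]:
                raise UnitMismatch("hill(x,k,n): x and k differ in dimension",
                                   e.loc)
            if not _dimless(ts[2]):
                raise UnitMismatch("hill exponent must be dimensionless", e.loc)
            return R.Fn(name, irs), NUM0
        if name in ("min", "max"):
            need(2)
            if ts[0] != ts[1]:
                raise UnitMismatch(f"{name} arguments differ in dimension", e.loc)
            return R.Fn(name, irs), ts[0]
        if name in ("exp", "ln", "log", "sqrt"):
            need(1)
            if not _dimless(ts[0]):
                raise UnitMismatch(f"{name} needs a dimensionless argument", e.loc)
            return R.Fn(name, irs), NUM0
        if name in ("abs", "floor", "ceil", "round"):
            need(1)
            return R.Fn(name, irs), ts[0]
        raise ModelError(f"unknown function {name!r}", e.loc)

    # ------------------------------------------------------------------
    # rules
    # ------------------------------------------------------------------
    def _check_rule(self, idx: int, r: S.RuleDef) -> TypedRule:
        self._node_counter = 0
        env = _RuleEnv()
        rule = TypedRule(idx, [], [], None, loc=r.loc)

        # pass 1: build lhs skeleton and register bindings
        rule.lhs = [self._build_node(el, "lhs", env, rule, None) for el in r.lhs]
        # pass 2: resolve lhs constraint expressions (may reference bindings)
        for node in rule.lhs_nodes:
            self._resolve_constraints(node, env)
        # rhs
        rule.rhs = [self._build_node(el, "rhs", env, rule, None) for el in r.rhs]
        for node in rule.rhs_nodes:
            self._resolve_assignments(node, env)
        # rate
        rate_ir, t = self._resolve(r.rate, env, allow_sampler=False)
        if t[0] != "num":
            raise ModelError("rate expression must be numeric", r.loc)
        if not (all(d == 0 for d in t[1]) or t[1] == _PER_TIME):
            raise UnitMismatch(
                f"rate must have dimension 1/time (or be dimensionless), "
                f"got {t[1]}", r.loc)
        rule.rate = rate_ir
        self._pair(rule.lhs, rule.rhs, rule)
        self._check_seq_vars(rule, r.loc)
        self._check_copy_semantics(rule)
        return rule

    def _new_node(self, species: Species, side: str, rule: TypedRule,
                  parent, loc) -> TypedNode:
        node = TypedNode(self._node_counter, species, side, parent=parent, loc=loc)
        self._node_counter += 1
        if side == "lhs":
            rule.lhs_nodes.append(node)
        elif side == "rhs":
            rule.rhs_nodes.append(node)
        return node

    def _build_node(self, el: S.PatternElem, side: str, env: _RuleEnv,
                    rule: TypedRule, parent: Optional[TypedNode]):
        if isinstance(el, S.SeqVar):
            if parent is None and side == "lhs":
                # binding the context's residual is ambiguous; on the rhs a
                # top-level occurrence releases content into the context
                raise ModelError(
                    f"sequence variable ?{el.name} must appear inside a "
                    f"compartment content block", el.loc)
            if side == "lhs":
                if el.name in rule.seq_vars:
                    raise ModelError(f"sequence variable ?{el.name} bound twice",
                                     el.loc)
                sv = TypedSeqVar(el.name, None, parent)
                if el.weight is not None:
                    ir, t = self._resolve(el.weight, env, allow_sampler=False)
                    if t[0] != "num" or not all(d == 0 for d in t[1]):
                        raise ModelError(
                            f"split weight of ?{el.name} must be a "
                            f"dimensionless number", el.loc)
                    sv.weight = ir
                rule.seq_vars[el.name] = sv
                env.seq_vars[el.name] = sv
                return sv
            # rhs occurrence
            if el.name not in rule.seq_vars:
                raise ModelError(f"?{el.name} not bound on the left side", el.loc)
            if el.weight is not None:
                raise ModelError("split weights belong on the left side", el.loc)
            if el.name in rule.rhs_seq_parents:
                raise ModelError(f"?{el.name} used twice on the right side",
                                 el.loc)
            rule.rhs_seq_parents[el.name] = parent
            return TypedSeqVar(el.name, None, parent)

        sp = self.by_name.get(el.species)
        if sp is None:
            raise ModelError(f"unknown species {el.species!r}", el.loc)
        node = self._new_node(sp, side, rule, parent, el.loc)
        node._raw = el  # stash for the constraint/assignment pass

        if el.count is not None:
            if side == "lhs":
                raise ModelError(
                    "multiplicities are not allowed on the left side; repeat "
                    "the pattern instead", el.loc)
        if el.bind:
            if side != "lhs":
                raise ModelError("population bindings belong on the left side",
                                 el.loc)
            if el.bind in env.pop_vars:
                raise ModelError(f"population variable {el.bind} bound twice",
                                 el.loc)
            node.pop_bind = el.bind
            env.pop_vars[el.bind] = node
            rule.pop_vars[el.bind] = node

        if side == "lhs":
            env.species_nodes.setdefault(sp.name, []).append(node)
            # register bare attribute bindings before expression resolution
            for name in el.ambiguous:
                if name in self.by_name:
                    continue  # content species, handled below
                ai = sp.attr_index.get(name)
                if ai is None:
                    raise ModelError(
                        f"{name!r} is neither a species nor an attribute of "
                        f"{sp.name}", el.loc)
                if name in env.attr_bindings:
                    raise ModelError(f"binding {name!r} appears twice", el.loc)
                env.attr_bindings[name] = (node, ai)
            for c in el.attrs:
                if c.op == "bind":
                    ai = sp.attr_index.get(c.name)
                    if ai is None:
                        raise ModelError(
                            f"species {sp.name} has no attribute {c.name}", c.loc)
                    env.attr_bindings[c.name] = (node, ai)

        content_elems: List[S.PatternElem] = []
        for name in el.ambiguous:
            if name in self.by_name:
                content_elems.append(S.PatternNode(name, loc=el.loc))
            elif side != "lhs":
                raise ModelError(
                    f"{name!r} is neither a species nor an assignment", el.loc)
        if el.content is not None:
            content_elems.extend(el.content)

        if content_elems or el.content is not None:
            if not sp.is_compartment:
                # defensive; species with content were derived compartments
                raise ModelError(f"species {sp.name} is not a compartment", el.loc)
            node.content = [self._build_node(c, side, env, rule, node)
                            for c in content_elems]
        return node

    def _resolve_constraints(self, node: TypedNode, env: _RuleEnv) -> None:
        el: S.PatternNode = node._raw
        sp = node.species
        for c in el.attrs:
            if c.op == "bind":
                continue
            if c.op == "=":
                raise ModelError(
                    f"assignment {c.name}= not allowed on the left side "
                    f"(use == to constrain)", c.loc)
            ai = sp.attr_index.get(c.name)
            if ai is None:
                raise ModelError(f"species {sp.name} has no attribute {c.name}",
                                 c.loc)
            attr = sp.attributes[ai]
            ir, t = self._resolve(c.expr, env, allow_sampler=False)
            self._check_attr_type(attr, t, c)
            if attr.kind == "enum" and isinstance(ir, R.StrLit) \
                    and ir.value not in attr.enum_values:
                raise ModelError(
                    f"{ir.value!r} is not a value of enum attribute "
                    f"{sp.name}.{attr.name} {attr.enum_values}", c.loc)
            if not attr.is_numeric and c.op not in ("==", "!="):
                raise ModelError(
                    f"attribute {attr.name} only supports == / != constraints",
                    c.loc)
            target = node.nf_constraints if attr.is_nf else node.constraints
            target.append((ai, c.op, ir))

    def _resolve_assignments(self, node: TypedNode, env: _RuleEnv) -> None:
        el: S.PatternNode = node._raw
        sp = node.species
        for c in el.attrs:
            if c.op != "=":
                raise ModelError(
                    f"only assignments (attr=expr) are allowed on the right "
                    f"side, got {c.name}{c.op}", c.loc)
            ai = sp.attr_index.get(c.name)
            if ai is None:
                raise ModelError(f"species {sp.name} has no attribute {c.name}",
                                 c.loc)
            attr = sp.attributes[ai]
            ir, t = self._resolve(c.expr, env, allow_sampler=True, allow_nf=True)
            self._check_attr_type(attr, t, c)
            if attr.kind == "enum" and isinstance(ir, R.StrLit) \
                    and ir.value not in attr.enum_values:
                raise ModelError(
                    f"{ir.value!r} is not a value of enum attribute "
                    f"{sp.name}.{attr.name} {attr.enum_values}", c.loc)
            node.assignments[ai] = ir
        if el.count is not None:
            ir, t = self._resolve(el.count, env, allow_sampler=True, allow_nf=True)
            if t[0] != "num" or not all(d == 0 for d in t[1]):
                raise ModelError("multiplicity must be a dimensionless number",
                                 el.loc)
            node.count = ir

    def _check_attr_type(self, attr: AttributeDef, t: NumType, c) -> None:
        if attr.is_numeric:
            if t[0] != "num":
                raise ModelError(
                    f"attribute {attr.name} is numeric but expression is {t[0]}",
                    c.loc)
            if t[1] != attr.unit.dims:
                raise UnitMismatch(
                    f"attribute {attr.name}: expected dimensions "
                    f"{attr.unit.dims}, got {t[1]}", c.loc)
        else:
            if t[0] != "str":
                raise ModelError(
                    f"attribute {attr.name} holds strings but expression "
                    f"is {t[0]}", c.loc)

    # ------------------------------------------------------------------
    # pairing and rule sanity
    # ------------------------------------------------------------------
    def _pair(self, lhs_elems, rhs_elems, rule: TypedRule) -> None:
        lhs_nodes = [n for n in lhs_elems if isinstance(n, TypedNode)]
        rhs_nodes = [n for n in rhs_elems if isinstance(n, TypedNode)
                     and n.count is None]
        by_sp: Dict[int, List[TypedNode]] = {}
        for n in lhs_nodes:
            by_sp.setdefault(n.species.sid, []).append(n)
        for rn in rhs_nodes:
            cands = by_sp.get(rn.species.sid, [])
            ln = next((c for c in cands if c.partner is None), None)
            if ln is None:
                continue
            ln.partner = rn
            rn.partner = ln
            if ln.content is not None and rn.content is not None:
                self._pair(ln.content, rn.content, rule)
            elif ln.content is not None and rn.content is None:
                raise ModelError(
                    f"{ln.species.name}: left side opens a content block but "
                    f"the right side does not; write the residual explicitly",
                    rule.loc)

    def _check_seq_vars(self, rule: TypedRule, loc) -> None:
        # weights only make sense when >=2 sequence variables share a slot
        for sv in rule.seq_vars.values():
            siblings = [s for s in rule.seq_vars.values() if s.parent is sv.parent]
            if sv.weight is not None and len(siblings) < 2:
                raise ModelError(
                    f"split weight on ?{sv.name} needs a second sequence "
                    f"variable in the same content block", loc)

    def _check_copy_semantics(self, rule: TypedRule) -> None:
        for rn in rule.rhs_nodes:
            for i in rn.species.enum_idx + rn.species.nf_idx:
                if i in rn.assignments:
                    continue
                if rn.partner is not None:
                    continue  # copied from the preserved lhs occurrence
                if rn.species.is_compartment:
                    # per-instance attributes of a fresh compartment
                    raise ModelError(
                        f"new compartment {rn.species.name} must assign "
                        f"attribute {rn.species.attributes[i].name}", rn.loc)
                raise ModelError(
                    f"produced species {rn.species.name} must assign attribute "
                    f"{rn.species.attributes[i].name} (no matching reactant)",
                    rn.loc)

    # ------------------------------------------------------------------
    # init and observables
    # ------------------------------------------------------------------
    def _check_init(self) -> List[TypedNode]:
        if self.ast.init is None:
            return []
        self._node_counter = 0
        dummy = TypedRule(-1, [], [], None)
        out = []
        for el in self.ast.init.content:
            out.append(self._build_init_node(el, None, dummy))
        return out

    def _build_init_node(self, el: S.PatternElem, parent,
                         rule: TypedRule) -> TypedNode:
        if isinstance(el, S.SeqVar):
            raise ModelError("sequence variables are not allowed in init", el.loc)
        sp = self.by_name.get(el.species)
        if sp is None:
            raise ModelError(f"unknown species {el.species!r}", el.loc)
        node = self._new_node(sp, "init", rule, parent, el.loc)
        for name in el.ambiguous:
            raise ModelError(f"init: {name!r} must be an assignment or a "
                             f"counted species", el.loc)
        for c in el.attrs:
            if c.op != "=":
                raise ModelError("init uses assignments (attr=value) only",
                                 c.loc)
            ai = sp.attr_index.get(c.name)
            if ai is None:
                raise ModelError(f"species {sp.name} has no attribute {c.name}",
                                 c.loc)
            attr = sp.attributes[ai]
            ir, t = self._resolve(c.expr, None, allow_sampler=True)
            self._check_attr_type(attr, t, c)
            if attr.kind == "enum" and isinstance(ir, R.StrLit) \
                    and ir.value not in attr.enum_values:
                raise ModelError(
                    f"{ir.value!r} is not a value of enum "
                    f"{sp.name}.{attr.name}", c.loc)
            node.assignments[ai] = ir
        for i, attr in enumerate(sp.attributes):
            if i not in node.assignments:
                raise ModelError(
                    f"init: attribute {sp.name}.{attr.name} not assigned",
                    el.loc)
        if el.count is not None:
            ir, t = self._resolve(el.count, None, allow_sampler=True)
            if t[0] != "num" or not all(d == 0 for d in t[1]):
                raise ModelError("init count must be a dimensionless number",
                                 el.loc)
            node.count = ir
        if el.content is not None:
            if not sp.is_compartment:
                raise ModelError(f"species {sp.name} is not a compartment",
                                 el.loc)
            node.content = [self._build_init_node(c, node, rule)
                            for c in el.content]
        return node

    def _check_observable(self, o: S.ObserveDecl) -> TypedObservable:
        sp = self.by_name.get(o.pattern.species)
        if sp is None:
            raise ModelError(f"unknown species {o.pattern.species!r}", o.loc)
        self._node_counter = 0
        dummy = TypedRule(-1, [], [], None)
        node = self._new_node(sp, "obs", dummy, None, o.loc)
        node._raw = o.pattern
        env = _RuleEnv()
        env.species_nodes[sp.name] = [node]
        for c in o.pattern.attrs:
            if c.op == "bind":
                ai = sp.attr_index.get(c.name)
                if ai is None:
                    raise ModelError(f"species {sp.name} has no attribute "
                                     f"{c.name}", c.loc)
                env.attr_bindings[c.name] = (node, ai)
        self._resolve_constraints(node, env)
        scope = None
        if o.scope:
            scope = self.by_name.get(o.scope)
            if scope is None or not scope.is_compartment:
                raise ModelError(f"observable scope {o.scope!r} is not a "
                                 f"compartment species", o.loc)
        return TypedObservable(o.name, sp, node.constraints,
                               node.nf_constraints, scope)


def _substitute(e: S.Expr, subst: Dict[str, S.Expr]) -> S.Expr:
    """Inline user-function parameters (syntactic substitution)."""
    if isinstance(e, S.Name) and e.ident in subst:
        return subst[e.ident]
    if isinstance(e, S.BinOp):
        return S.BinOp(e.op, _substitute(e.left, subst),
                       _substitute(e.right, subst), loc=e.loc)
    if isinstance(e, S.UnOp):
        return S.UnOp(e.op, _substitute(e.operand, subst), loc=e.loc)
    if isinstance(e, S.Call):
        return S.Call(e.fn, tuple(_substitute(a, subst) for a in e.args),
                      loc=e.loc)
    if isinstance(e, S.IfExpr):
        return S.IfExpr(_substitute(e.cond, subst), _substitute(e.then, subst),
                        _substitute(e.els, subst), loc=e.loc)
    return e


def typecheck(ast: S.ModelAST, max_indices: int = 10 ** 6) -> TypedModel:
    """Check an AST and return the resolved model."""
    return _Checker(ast, max_indices).run()


def load_model(text: str, max_indices: int = 10 ** 6) -> TypedModel:
    """Parse and typecheck model text."""
    return typecheck(parse(text), max_indices=max_indices)


def infer_unit(expr_text: str, constants: Optional[Dict[str, Unit]] = None
               ) -> Unit:
    """Infer the unit of a standalone expression (testing/inspection aid).

    ``constants`` maps names to units; their values are taken as 1.
    """
    from .parser import _Parser, tokenize
    e = _Parser(tokenize(expr_text)).parse_expr()
    ast = S.ModelAST()
    chk = _Checker(ast, 10 ** 6)
    for name, unit in (constants or {}).items():
        chk.constants[name] = 1.0
        chk.constant_units[name] = unit
    _, t = chk._resolve(e, None, allow_sampler=True)
    if t[0] != "num":
        raise UnitMismatch(f"expression is {t[0]}, not numeric")
    return Unit(t[1], 1.0)
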