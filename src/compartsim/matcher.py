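"""Rule classification, reaction enumeration and dependencies.

``classify_rule`` marks each rule *regular* (pure count and attribute
updates: executable on the flat state) or *structural* (creates,
deletes, fuses, splits or re-nests compartments, or redistributes a
sequence variable: requires the tree form and a full rebuild).

``enumerate_reactions`` instantiates every concrete reaction of a
model against a flattened state: one reaction per (rule, compartment
context, species-variant combination).  Matching runs against the
grouped canonical state, so n identical entities contribute one
reaction whose rate expression sees their count -- an equivalent CTMC
with an exponentially smaller network.  Multiplicity convention: the
modeler's rate expression defines the kinetics (write ``k*#a`` or
``k*#a*(#a-1)`` explicitly); enumeration adds no hidden binomial
factors.

Availability guards (required reactant counts, dynamic
compartment-attribute constraints, exact-content residual checks) are
folded into the propensity expression, so a reaction whose guard
fails simply has propensity zero and revives -- via dependency-driven
updates -- as soon as counts or attributes allow it again.

``build_dependency_graph`` over-approximates "firing r changes the
propensity of s" from the read/write slot sets of each reaction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Dict, FrozenSet, Iterator, List, Optional, Tuple

from . import rates as R
from .model import (ModelError, ModelTooLargeError, Species, TypedModel,
                    TypedNode, TypedRule, TypedSeqVar)
from .state import FlatState, VariantKey, coerce_attr

__all__ = ["classify_rule", "enumerate_reactions", "build_dependency_graph",
           "Reaction", "ReactionNetwork", "reachable_variants"]


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def classify_rule(rule: TypedRule) -> str:
    """Mark a rule regular or structural (conservative, per-rule)."""

    for n in rule.lhs_nodes:
        if n.species.is_compartment and n.partner is None:
            return "structural"
    for n in rule.rhs_nodes:
        if n.species.is_compartment and (n.partner is None or n.count is not None):
            return "structural"
    for name, sv in rule.seq_vars.items():
        if name not in rule.rhs_seq_parents:
            return "structural"  # residual content dropped (deleted)
        rhs_parent = rule.rhs_seq_parents[name]
        if rhs_parent is None or rhs_parent.partner is not sv.parent:
            return "structural"  # residual moved to another compartment
    return "regular"


# --------------------------------------------------------------------------
# reachable species variants
# --------------------------------------------------------------------------


class Unfoldable(Exception):
    """Expression depends on dynamic state; cannot fold at build time."""


class _StaticEnv(R.Env):
    """Folds expressions over a variant binding; anything dynamic raises."""

    def __init__(self, rule: Optional[TypedRule],
                 var_assign: Dict[int, VariantKey]):
        self.rule = rule
        self.var_assign = var_assign

    def attr_val(self, node_id: int, attr: int) -> Any:
        node = self.rule.lhs_nodes[node_id]
        sp = node.species
        if sp.is_compartment or sp.attributes[attr].is_nf:
            raise Unfoldable
        key = self.var_assign.get(node_id)
        if key is None:
            raise Unfoldable
        return key[1][sp.enum_idx.index(attr)]

    def count_val(self, var: str):
        raise Unfoldable

    def nf(self, store, pred):
        raise Unfoldable

    @property
    def rng(self):  # samplers are dynamic
        raise Unfoldable

    @rng.setter
    def rng(self, v):  # pragma: no cover
        pass


def _has_sampler(ir: Any) -> bool:
    if isinstance(ir, R.Fn):
        if ir.name in R.SAMPLER_FNS:
            return True
        return any(_has_sampler(a) for a in ir.args)
    if isinstance(ir, R.B):
        return _has_sampler(ir.left) or _has_sampler(ir.right)
    if isinstance(ir, R.U):
        return _has_sampler(ir.operand)
    if isinstance(ir, R.Cond):
        return any(_has_sampler(x) for x in (ir.cond, ir.then, ir.els))
    return False


def try_fold(ir: Any, rule: Optional[TypedRule],
             var_assign: Dict[int, VariantKey]) -> Any:
    if _has_sampler(ir):
        raise Unfoldable
    return R.interpret(ir, _StaticEnv(rule, var_assign))


def _rhs_variant(rn: TypedNode, rule: TypedRule,
                 var_assign: Dict[int, VariantKey]) -> VariantKey:
    """Variant produced by a non-compartment rhs node under a binding."""
    sp = rn.species
    vals = []
    for pos, ai in enumerate(sp.enum_idx):
        if ai in rn.assignments:
            try:
                v = try_fold(rn.assignments[ai], rule, var_assign)
            except Unfoldable:
                raise ModelError(
                    f"rule {rule.idx}: attribute "
                    f"{sp.name}.{sp.attributes[ai].name} is assigned a "
                    f"state-dependent value; it cannot be enumerated into the "
                    f"network -- declare it network-free") from None
        elif rn.partner is not None:
            v = var_assign[rn.partner.node_id][1][pos]
        else:  # unreachable: copy semantics checked at typecheck
            raise ModelError(f"rule {rule.idx}: unassigned attribute on "
                             f"produced species {sp.name}")
        vals.append(coerce_attr(sp.attributes[ai].kind, v))
    return (sp.sid, tuple(vals))


def _own_constraints_ok(node: TypedNode, key: VariantKey,
                        rule: TypedRule) -> bool:
    """Check constraints that fold with only this node bound."""
    assign = {node.node_id: key}
    for ai, op, ir in node.constraints:
        sp = node.species
        lhs_val = key[1][sp.enum_idx.index(ai)]
        try:
            rhs_val = try_fold(ir, rule, assign)
        except Unfoldable:
            continue
        if not _cmp(op, lhs_val, rhs_val):
            return False
    return True


def _cmp(op: str, a: Any, b: Any) -> bool:
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
    raise ModelError(f"bad constraint operator {op}")


def reachable_variants(model: TypedModel,
                       seeds: FrozenSet[VariantKey]) -> Dict[int, List[VariantKey]]:
    """Fixpoint of rule productions over the seed variants.

    Returns, per non-compartment species id, the sorted list of
    variants the reaction network must enumerate.  Over-approximation
    is safe (unreachable variants yield zero-propensity reactions);
    under-approximation would lose reactions and is forbidden.
    """

    variants: set = set(seeds)
    for rule in model.rules:
        for node in itertools.chain(rule.lhs_nodes, rule.rhs_nodes):
            if not node.species.is_compartment and not node.species.attributes:
                variants.add((node.species.sid, ()))

    changed = True
    while changed:
        changed = False
        if len(variants) > model.max_indices:
            raise ModelTooLargeError(
                f"model too large: more than {model.max_indices} species "
                f"variants reachable")
        by_sp: Dict[int, List[VariantKey]] = {}
        for key in variants:
            by_sp.setdefault(key[0], []).append(key)
        for rule in model.rules:
            lhs_nc = [n for n in rule.lhs_nodes if not n.species.is_compartment]
            choice_lists = []
            for n in lhs_nc:
                cands = [k for k in by_sp.get(n.species.sid, ())
                         if _own_constraints_ok(n, k, rule)]
                choice_lists.append(cands)
            if any(not c for c in choice_lists) and lhs_nc:
                continue
            for combo in itertools.product(*choice_lists):
                var_assign = {n.node_id: k for n, k in zip(lhs_nc, combo)}
                for rn in rule.rhs_nodes:
                    if rn.species.is_compartment:
                        continue
                    key = _rhs_variant(rn, rule, var_assign)
                    if key not in variants:
                        variants.add(key)
                        changed = True
    out: Dict[int, List[VariantKey]] = {}
    for key in sorted(variants):
        out.setdefault(key[0], []).append(key)
    return out


# --------------------------------------------------------------------------
# reactions
# --------------------------------------------------------------------------


@dataclass
class Binding:
    """Concrete match of a rule's lhs against the state."""

    ctx_iid: int
    comp: Dict[int, int] = field(default_factory=dict)  # lhs node_id -> iid
    var: Dict[int, VariantKey] = field(default_factory=dict)

    def parent_iid(self, node: TypedNode) -> int:
        if node.parent is None:
            return self.ctx_iid
        return self.comp[node.parent.node_id]


@dataclass
class Reaction:
    rid: int
    rule: TypedRule
    kind: str
    binding: Binding
    prop_expr: Any  # bound IR: guards * rate
    tmpl: Any = None
    params: Tuple = ()
    reads: FrozenSet = frozenset()
    writes: FrozenSet = frozenset()
    # regular effects
    delta: List[Tuple[int, float]] = field(default_factory=list)
    dyn_deltas: List[Tuple[int, Any]] = field(default_factory=list)
    #: (attribute slot, bound IR, attribute kind)
    attr_updates: List[Tuple[int, Any, str]] = field(default_factory=list)
    #: (store key, pred, lhs node_id) for each nf reactant to consume
    nf_consume: List[Tuple[Tuple[int, int], Any, int]] = field(default_factory=list)
    #: (store key, per-nf-attr IR list, source lhs node_id or None,
    #:  copy count: float or IR evaluated at firing time)
    nf_produce: List[Tuple[Tuple[int, int], List[Any], Optional[int], Any]] = \
        field(default_factory=list)
    propensity: float = 0.0

    @property
    def simple(self) -> bool:
        """Static-delta fast path (no fire-time evaluation needed)."""
        return not (self.dyn_deltas or self.attr_updates or self.nf_consume
                    or self.nf_produce)


class ReactionNetwork:
    def __init__(self, model: TypedModel, flat: FlatState,
                 reactions: List[Reaction],
                 rv: Dict[int, List[VariantKey]]):
        self.model = model
        self.flat = flat
        self.reactions = reactions
        self.rv = rv

    def __len__(self) -> int:
        return len(self.reactions)

    def dump(self) -> str:
        """Human-readable network listing for inspection and tests."""
        lines = []
        for r in self.reactions:
            b = r.binding
            lines.append(
                f"R{r.rid} rule={r.rule.idx} kind={r.kind} ctx={b.ctx_iid} "
                f"comp={dict(sorted(b.comp.items()))} "
                f"vars={dict(sorted(b.var.items()))}")
        return "\n".join(lines)


def _pattern_sig(node: TypedNode) -> Tuple:
    """Structural signature used to detect interchangeable patterns."""
    content: Tuple = ()
    if node.content is not None:
        content = tuple(sorted(
            (_pattern_sig(c) if isinstance(c, TypedNode) else ("?",)
             for c in node.content), key=repr))
    return (node.species.sid,
            tuple(sorted(repr(c) for c in node.constraints)),
            tuple(sorted(repr(c) for c in node.nf_constraints)),
            node.pop_bind is None,
            node.content is None, content)


class _Enumerator:
    def __init__(self, model: TypedModel, flat: FlatState,
                 template_cache: R.TemplateCache,
                 rv: Dict[int, List[VariantKey]]):
        self.model = model
        self.flat = flat
        self.cache = template_cache
        self.rv = rv
        self._pred_cache: Dict[Tuple, Any] = {}
        self._sig_cache: Dict[int, Tuple] = {}
        self._cand_cache: Dict[Tuple[int, int], List[VariantKey]] = {}
        self.reactions: List[Reaction] = []

    def _sig(self, node: TypedNode) -> Tuple:
        s = self._sig_cache.get(id(node))
        if s is None:
            s = _pattern_sig(node)
            self._sig_cache[id(node)] = s
        return s

    def _cands(self, node: TypedNode, rule: TypedRule) -> List[VariantKey]:
        key = (rule.idx, node.node_id)
        c = self._cand_cache.get(key)
        if c is None:
            c = [k for k in self.rv.get(node.species.sid, ())
                 if _own_constraints_ok(node, k, rule)]
            self._cand_cache[key] = c
        return c

    # -- matching --------------------------------------------------------
    def run(self) -> ReactionNetwork:
        flat = self.flat
        for ctx_iid in flat.order:
            for rule in self.model.rules:
                if not rule.lhs:
                    if ctx_iid == flat.root_iid:
                        self._emit(rule, Binding(ctx_iid))
                    continue
                for binding in self._match_block(rule.lhs, ctx_iid,
                                                 Binding(ctx_iid), rule,
                                                 exact=False):
                    self._emit(rule, binding)
        net = ReactionNetwork(self.model, flat, self.reactions, self.rv)
        total = len(flat.C)
        if total > self.model.max_indices:
            raise ModelTooLargeError(
                f"model too large: {total} enumerated indices exceed cap "
                f"{self.model.max_indices}")
        return net

    def _match_block(self, elems, ctx_iid: int, binding: Binding,
                     rule: TypedRule, exact: bool) -> Iterator[Binding]:
        comp_pats = [e for e in elems
                     if isinstance(e, TypedNode) and e.species.is_compartment]
        nc_pats = [e for e in elems
                   if isinstance(e, TypedNode) and not e.species.is_compartment]
        has_seq = any(isinstance(e, TypedSeqVar) for e in elems)
        children = self.flat.instances[ctx_iid].child_iids

        by_sp: Dict[int, List[TypedNode]] = {}
        for p in comp_pats:
            by_sp.setdefault(p.species.sid, []).append(p)
        child_by_sp: Dict[int, List[int]] = {}
        for cid in children:
            child_by_sp.setdefault(self.flat.instances[cid].species.sid,
                                   []).append(cid)
        if exact and not has_seq:
            # exact content: child compartments fully accounted for
            if {s: len(v) for s, v in child_by_sp.items()} != \
                    {s: len(v) for s, v in by_sp.items()}:
                return

        def comp_groups(groups: List[Tuple[List[TypedNode], List[int]]],
                        b: Binding) -> Iterator[Binding]:
            if not groups:
                yield b
                return
            (pats, cands), rest = groups[0], groups[1:]
            k = len(pats)
            if len(cands) < k:
                return
            same = len({self._sig(p) for p in pats}) == 1
            seqs = (itertools.combinations(cands, k) if same
                    else itertools.permutations(cands, k))
            for chosen in seqs:
                b2 = Binding(b.ctx_iid, dict(b.comp), dict(b.var))
                for p, cid in zip(pats, chosen):
                    b2.comp[p.node_id] = cid
                # recurse into content blocks
                streams = [b2]
                ok = True
                for p, cid in zip(pats, chosen):
                    if p.content is None:
                        continue
                    nxt = []
                    for bb in streams:
                        nxt.extend(self._match_block(p.content, cid, bb,
                                                     rule, exact=True))
                    streams = nxt
                    if not streams:
                        ok = False
                        break
                if not ok:
                    continue
                for bb in streams:
                    yield from comp_groups(rest, bb)

        groups = [(pats, child_by_sp.get(sid, []))
                  for sid, pats in by_sp.items()]

        def nc_assign(b: Binding) -> Iterator[Binding]:
            # group interchangeable non-compartment patterns for
            # unordered variant selection
            grouped: Dict[Tuple, List[TypedNode]] = {}
            for p in nc_pats:
                grouped.setdefault(self._sig(p), []).append(p)
            group_list = list(grouped.values())

            def rec(gi: int, bb: Binding) -> Iterator[Binding]:
                if gi == len(group_list):
                    if self._cross_constraints_ok(rule, bb):
                        yield bb
                    return
                pats = group_list[gi]
                cands = self._cands(pats[0], rule)
                same = len({self._sig(p) for p in pats}) == 1
                it = (itertools.combinations_with_replacement(cands, len(pats))
                      if same else itertools.product(cands, repeat=len(pats)))
                for combo in it:
                    b3 = Binding(bb.ctx_iid, dict(bb.comp), dict(bb.var))
                    for p, k in zip(pats, combo):
                        b3.var[p.node_id] = k
                    yield from rec(gi + 1, b3)

            yield from rec(0, b)

        for b_comp in comp_groups(groups, binding):
            yield from nc_assign(b_comp)

    def _cross_constraints_ok(self, rule: TypedRule, b: Binding) -> bool:
        """Constraints that fold under the full binding must hold."""
        for node in rule.lhs_nodes:
            if node.species.is_compartment:
                continue
            sp = node.species
            key = b.var.get(node.node_id)
            if key is None:
                continue  # bound later; outermost check sees everything
            for ai, op, ir in node.constraints:
                lhs_val = key[1][sp.enum_idx.index(ai)]
                try:
                    rhs_val = try_fold(ir, rule, b.var)
                except Unfoldable:
                    continue  # dynamic; becomes a propensity guard
                if not _cmp(op, lhs_val, rhs_val):
                    return False
        return True

    # -- binding expressions ---------------------------------------------
    def _pred_for(self, node: TypedNode, rule: TypedRule, b: Binding):
        """Compile the nf-attribute constraints of a node to a predicate."""
        sp = node.species
        tests = []
        for ai, op, ir in node.nf_constraints:
            pos = sp.nf_idx.index(ai)
            try:
                val = try_fold(ir, rule, b.var)
            except Unfoldable:
                raise ModelError(
                    f"rule {rule.idx}: network-free constraint on "
                    f"{sp.name}.{sp.attributes[ai].name} must compare against "
                    f"a statically known value") from None
            tests.append((pos, op, val))
        key = (sp.sid, tuple(tests))
        pred = self._pred_cache.get(key)
        if pred is None:
            def pred(t, _tests=tuple(tests)):
                return all(_cmp(op, t[pos], val) for pos, op, val in _tests)
            self._pred_cache[key] = pred
        return pred

    def _store_key(self, node: TypedNode, b: Binding) -> Tuple[int, int]:
        iid = b.parent_iid(node)
        vid = self.flat.variants.vid(b.var[node.node_id])
        return (iid, vid)

    def _seq_sum(self, sv: TypedSeqVar, rule: TypedRule, b: Binding):
        parent = sv.parent
        iid = b.comp[parent.node_id]
        # all slots this instance could ever hold
        slots = []
        for sid, keys in self.rv.items():
            for k in keys:
                slots.append(self.flat.ensure_slot(iid, self.flat.variants.vid(k)))
        siblings_nc = sum(1 for e in parent.content
                          if isinstance(e, TypedNode)
                          and not e.species.is_compartment)
        siblings_c = sum(1 for e in parent.content
                         if isinstance(e, TypedNode)
                         and e.species.is_compartment)
        n_children = len(self.flat.instances[iid].child_iids)
        offset = float(n_children - siblings_c - siblings_nc)
        return R.SumSlots(tuple(sorted(set(slots))), offset)

    def _bind(self, ir: Any, rule: TypedRule, b: Binding) -> Any:
        tp = type(ir)
        if tp in (R.Lit, R.StrLit, R.CountSlot, R.AttrSlot, R.NfCount,
                  R.SumSlots):
            return ir
        if tp is R.AttrVal:
            node = rule.lhs_nodes[ir.node]
            sp = node.species
            attr = sp.attributes[ir.attr]
            if sp.is_compartment:
                iid = b.comp[node.node_id]
                return R.AttrSlot(self.flat.attr_slot(iid, ir.attr))
            if attr.is_nf:
                return ir  # bound at firing time to the chosen instance
            val = b.var[node.node_id][1][sp.enum_idx.index(ir.attr)]
            return R.StrLit(val) if isinstance(val, str) else R.Lit(float(val))
        if tp is R.CountVal:
            if ir.var in rule.pop_vars:
                node = rule.pop_vars[ir.var]
                if node.species.is_compartment:
                    # instance population is static between rebuilds
                    parent = b.parent_iid(node)
                    sid = node.species.sid
                    n = sum(1 for cid in self.flat.instances[parent].child_iids
                            if self.flat.instances[cid].species.sid == sid)
                    return R.Lit(float(n))
                store = self._store_key(node, b)
                if node.nf_constraints:
                    return R.NfCount(store, self._pred_for(node, rule, b))
                return R.CountSlot(self.flat.ensure_slot(*store))
            sv = rule.seq_vars.get(ir.var)
            if sv is None:
                raise ModelError(f"#{ir.var}: unbound in rule {rule.idx}")
            return self._seq_sum(sv, rule, b)
        if tp is R.B:
            return R.B(ir.op, self._bind(ir.left, rule, b),
                       self._bind(ir.right, rule, b))
        if tp is R.U:
            return R.U(ir.op, self._bind(ir.operand, rule, b))
        if tp is R.Cond:
            return R.Cond(self._bind(ir.cond, rule, b),
                          self._bind(ir.then, rule, b),
                          self._bind(ir.els, rule, b))
        if tp is R.Fn:
            return R.Fn(ir.name, tuple(self._bind(a, rule, b) for a in ir.args))
        raise ModelError(f"cannot bind IR node {ir!r}")

    # -- reaction construction -------------------------------------------
    def _emit(self, rule: TypedRule, b: Binding) -> None:
        flat = self.flat
        factors: List[Any] = []

        # required reactant counts per slot / nf store
        need: Dict[int, int] = {}
        nf_need: Dict[Tuple[Tuple[int, int], Any], int] = {}
        for node in rule.lhs_nodes:
            if node.species.is_compartment:
                continue
            store = self._store_key(node, b)
            if node.nf_constraints:
                pred = self._pred_for(node, rule, b)
                nf_need[(store, pred)] = nf_need.get((store, pred), 0) + 1
            else:
                slot = flat.ensure_slot(*store)
                need[slot] = need.get(slot, 0) + 1
        for slot, k in sorted(need.items()):
            factors.append(R.B(">=", R.CountSlot(slot), R.Lit(float(k))))
        for (store, pred), k in nf_need.items():
            factors.append(R.B(">=", R.NfCount(store, pred), R.Lit(float(k))))

        # dynamic constraints (could not be folded statically)
        for node in rule.lhs_nodes:
            sp = node.species
            for ai, op, ir in node.constraints:
                if sp.is_compartment:
                    lhs_ir = R.AttrVal(node.node_id, ai)
                else:
                    try:
                        rhs_val = try_fold(ir, rule, b.var)
                        continue  # already checked statically
                    except Unfoldable:
                        lhs_ir = R.AttrVal(node.node_id, ai)
                factors.append(self._bind(R.B(op, lhs_ir, ir), rule, b))

        # exact-content residual guards
        for node in rule.lhs_nodes:
            if node.content is None or not node.species.is_compartment:
                continue
            if any(isinstance(e, TypedSeqVar) for e in node.content):
                continue
            iid = b.comp[node.node_id]
            slots = []
            for sid, keys in self.rv.items():
                for k in keys:
                    slots.append(flat.ensure_slot(iid, flat.variants.vid(k)))
            matched = sum(1 for e in node.content
                          if isinstance(e, TypedNode)
                          and not e.species.is_compartment)
            factors.append(R.B("==", R.SumSlots(tuple(sorted(set(slots))), 0.0),
                               R.Lit(float(matched))))

        expr = self._bind(rule.rate, rule, b)
        for f in reversed(factors):
            expr = R.B("*", f, expr)

        rid = len(self.reactions)
        rx = Reaction(rid, rule, rule.kind, b, expr)
        tmpl, params = self.cache.get_or_compile(expr)
        rx.tmpl, rx.params = tmpl, params
        rx.reads = frozenset(_collect_reads(expr))
        if rule.kind == "regular":
            self._build_effects(rx, rule, b)
        self.reactions.append(rx)

    def _build_effects(self, rx: Reaction, rule: TypedRule, b: Binding) -> None:
        flat = self.flat
        delta: Dict[int, float] = {}
        writes: set = set()

        def add_delta(slot: int, d: float) -> None:
            delta[slot] = delta.get(slot, 0.0) + d

        for node in rule.lhs_nodes:
            if node.species.is_compartment:
                continue
            sp = node.species
            store = self._store_key(node, b)
            slot = flat.ensure_slot(*store)
            partner = node.partner
            if partner is None:
                add_delta(slot, -1.0)
                if sp.nf_idx:
                    pred = (self._pred_for(node, rule, b)
                            if node.nf_constraints else None)
                    rx.nf_consume.append((store, pred, node.node_id))
                    writes.add(("nf",) + store)
                continue
            # preserved occurrence: apply attribute updates, if any
            if not partner.assignments:
                continue
            new_key = _rhs_variant(partner, rule, b.var)
            if new_key != b.var[node.node_id]:
                new_slot = flat.ensure_slot(b.parent_iid(node),
                                            flat.variants.vid(new_key))
                add_delta(slot, -1.0)
                add_delta(new_slot, +1.0)
            if sp.nf_idx:
                pred = (self._pred_for(node, rule, b)
                        if node.nf_constraints else None)
                rx.nf_consume.append((store, pred, node.node_id))
                writes.add(("nf",) + store)
                new_store = (b.parent_iid(node), flat.variants.vid(new_key))
                nf_irs = [self._bind(partner.assignments[ai], rule, b)
                          if ai in partner.assignments else R.AttrVal(
                              node.node_id, ai)
                          for ai in sp.nf_idx]
                rx.nf_produce.append((new_store, nf_irs, node.node_id, 1.0))
                writes.add(("nf",) + new_store)

        for rn in rule.rhs_nodes:
            if rn.species.is_compartment or rn.partner is not None:
                continue
            sp = rn.species
            key = _rhs_variant(rn, rule, b.var)
            parent_iid = (b.comp[rn.parent.partner.node_id]
                          if rn.parent is not None else b.ctx_iid)
            slot = flat.ensure_slot(parent_iid, flat.variants.vid(key))
            count_ir = rn.count
            if count_ir is None:
                n: Any = 1.0
            else:
                try:
                    n = float(try_fold(count_ir, rule, b.var))
                except Unfoldable:
                    n = None
            if sp.nf_idx:
                store = (parent_iid, flat.variants.vid(key))
                nf_irs = [self._bind(rn.assignments[ai], rule, b)
                          for ai in sp.nf_idx]
                if n is None:
                    cnt = self._bind(count_ir, rule, b)
                    rx.nf_produce.append((store, nf_irs, None, cnt))
                    rx.dyn_deltas.append((slot, cnt))
                else:
                    rx.nf_produce.append((store, nf_irs, None, n))
                    add_delta(slot, n)
                writes.add(("nf",) + store)
            elif n is None:
                rx.dyn_deltas.append((slot, self._bind(count_ir, rule, b)))
            else:
                add_delta(slot, n)

        # compartment attribute updates on preserved compartments
        for rn in rule.rhs_nodes:
            if not rn.species.is_compartment or rn.partner is None:
                continue
            iid = b.comp[rn.partner.node_id]
            for ai, ir in rn.assignments.items():
                aslot = flat.attr_slot(iid, ai)
                kind = rn.species.attributes[ai].kind
                rx.attr_updates.append((aslot, self._bind(ir, rule, b), kind))
                writes.add(("a", aslot))

        rx.delta = [(s, d) for s, d in sorted(delta.items()) if d != 0.0]
        for s, _ in rx.delta:
            writes.add(("c", s))
        for s, _ in rx.dyn_deltas:
            writes.add(("c", s))
        rx.writes = frozenset(writes)


def _collect_reads(ir: Any, out: Optional[set] = None) -> set:
    if out is None:
        out = set()
    tp = type(ir)
    if tp is R.CountSlot:
        out.add(("c", ir.slot))
    elif tp is R.AttrSlot:
        out.add(("a", ir.slot))
    elif tp is R.NfCount:
        out.add(("nf",) + tuple(ir.store))
    elif tp is R.SumSlots:
        for s in ir.slots:
            out.add(("c", s))
    elif tp is R.B:
        _collect_reads(ir.left, out)
        _collect_reads(ir.right, out)
    elif tp is R.U:
        _collect_reads(ir.operand, out)
    elif tp is R.Cond:
        for x in (ir.cond, ir.then, ir.els):
            _collect_reads(x, out)
    elif tp is R.Fn:
        for a in ir.args:
            _collect_reads(a, out)
    return out


def enumerate_reactions(model: TypedModel, flat: FlatState,
                        template_cache: Optional[R.TemplateCache] = None,
                        rv: Optional[Dict[int, List[VariantKey]]] = None
                        ) -> ReactionNetwork:
    """Instantiate all concrete reactions of *model* against *flat*."""
    if template_cache is None:
        template_cache = R.TemplateCache()
    if rv is None:
        seeds = frozenset(
            flat.variants.keys[vid] for (iid, vid) in flat.slot_of
            if flat.C[flat.slot_of[(iid, vid)]] > 0)
        rv = reachable_variants(model, seeds)
    return _Enumerator(model, flat, template_cache, rv).run()


def build_dependency_graph(network: ReactionNetwork) -> Dict[int, Tuple[int, ...]]:
    """Over-approximate edges r -> s: firing r may change p_s."""
    readers: Dict[Any, List[int]] = {}
    for rx in network.reactions:
        for key in rx.reads:
            readers.setdefault(key, []).append(rx.rid)
    graph: Dict[int, Tuple[int, ...]] = {}
    for rx in network.reactions:
        deps: set = set()
        for key in rx.writes:
            deps.update(readers.get(key, ()))
        graph[rx.rid] = tuple(sorted(deps))
    return graph
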