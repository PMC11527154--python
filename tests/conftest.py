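"""Shared helpers: independent oracles used across the suite.

``NaiveDirectMethod`` is a from-scratch direct-method SSA: it
recomputes every propensity each step with the tree-walking
interpreter and selects by a linear cumulative scan over the same
reaction layout the engine uses.  It shares no propensity bookkeeping
with the engine, so lockstep agreement checks the cumulative-sum
tree, the dependency-driven updates and the compiled rate templates
at once.

``brute_force_matches`` is an exhaustive recursive pattern matcher
over the concrete tree, used to cross-check reaction enumeration.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pytest

from compartsim import rates as R
from compartsim.matcher import enumerate_reactions
from compartsim.model import TypedModel, TypedNode, TypedSeqVar
from compartsim.netfree import fire_regular
from compartsim.state import (StateTree, build_initial_state, tree_to_flat)


class _InterpEnv(R.Env):
    def __init__(self, flat):
        self.flat = flat
        self.C = flat.C
        self.A = flat.A

    def nf(self, store, pred):
        return self.flat.nf_count(store, pred)


def interp_propensity(rx, flat) -> float:
    """Propensity via the interpreter (independent of templates)."""
    return float(R.interpret(rx.prop_expr, _InterpEnv(flat)))


class NaiveDirectMethod:
    """Direct-method SSA with full propensity recomputation each step.

    Reaction order mirrors the engine's build-time layout (descending
    initial propensity), walked in depth-first (node, left subtree,
    right subtree) order with the same comparison conventions.
    """

    def __init__(self, model: TypedModel, flat, rng: np.random.Generator):
        self.model = model
        self.flat = flat
        self.rng = rng
        self.net = enumerate_reactions(model, flat)
        self.reactions = self.net.reactions
        p0 = [interp_propensity(rx, flat) for rx in self.reactions]
        order = sorted(range(len(p0)), key=lambda i: (-p0[i], i))
        self.layout = order  # heap position -> rid
        self.dfs = self._dfs_order(len(order))
        self.t = 0.0

    def _dfs_order(self, n: int) -> List[int]:
        out: List[int] = []

        def rec(i: int) -> None:
            if i >= n:
                return
            out.append(i)
            rec(2 * i + 1)
            rec(2 * i + 2)

        rec(0)
        return out

    def step(self) -> Optional[Tuple[float, int]]:
        import math
        props = {rx.rid: interp_propensity(rx, self.flat)
                 for rx in self.reactions}
        total = sum(props[self.layout[i]] for i in range(len(self.layout)))
        if total <= 0:
            return None
        u1 = self.rng.random()
        dt = -math.log1p(-u1) / total
        u2 = self.rng.random()
        r = u2 * total
        rid = self.layout[self.dfs[-1]] if self.dfs else -1
        for pos in self.dfs:
            cand = self.layout[pos]
            p = props[cand]
            if r < p:
                rid = cand
                break
            r -= p
        self.t += dt
        rx = self.reactions[rid]
        if rx.kind == "regular":
            fire_regular(rx, self.flat, self.rng)
        return dt, rid

    def run(self, steps: int) -> List[Tuple[float, int]]:
        out = []
        for _ in range(steps):
            got = self.step()
            if got is None:
                break
            out.append(got)
        return out


# --------------------------------------------------------------------------
# brute-force matcher
# --------------------------------------------------------------------------

def _node_sig(n) -> Tuple:
    from compartsim.matcher import _pattern_sig
    return _pattern_sig(n)


def brute_force_matches(model: TypedModel, tree: StateTree) -> Set[Tuple]:
    """All concrete matches of all rules against the present state.

    Returns canonical signatures: (rule idx, ctx iid, per-species
    sorted compartment-instance tuple, per-pattern-signature sorted
    variant tuple).  Only for models without attributes on
    non-compartment species (single-variant species).
    """
    out: Set[Tuple] = set()
    for rule in model.rules:
        for ctx in tree.root.walk():
            if not rule.lhs and ctx.iid != tree.root.iid:
                continue  # source-free rules apply at root scope only
            for assign in _match(rule.lhs, ctx, tree):
                comp_ids = tuple(sorted(
                    (nid, iid) for nid, iid in assign.items()))
                out.add((rule.idx, ctx.iid, comp_ids))
    return out


def _match(elems, ctx, tree):
    """Yield dicts lhs_node_id -> matched compartment iid."""
    comp_pats = [e for e in elems if isinstance(e, TypedNode)
                 and e.species.is_compartment]
    nc_pats = [e for e in elems if isinstance(e, TypedNode)
               and not e.species.is_compartment]

    # non-compartment availability on the concrete state
    needed: Dict[int, int] = {}
    for p in nc_pats:
        key = (p.species.sid, ())
        needed[key[0]] = needed.get(key[0], 0) + 1
    for sid, k in needed.items():
        if ctx.pops.get((sid, ()), 0) < k:
            return

    groups: Dict[int, List] = {}
    for p in comp_pats:
        groups.setdefault(p.species.sid, []).append(p)

    def assign_groups(group_items, acc):
        if not group_items:
            yield dict(acc)
            return
        (sid, pats), rest = group_items[0], group_items[1:]
        cands = [c for c in ctx.children if c.species.sid == sid]
        if len(cands) < len(pats):
            return
        same = len({_node_sig(p) for p in pats}) == 1
        seqs = (itertools.combinations(cands, len(pats)) if same
                else itertools.permutations(cands, len(pats)))
        for chosen in seqs:
            sub_assigns = [dict(acc)]
            ok = True
            for p, c in zip(pats, chosen):
                for a in sub_assigns:
                    a[p.node_id] = c.iid
                if p.content is not None:
                    nxt = []
                    for a in sub_assigns:
                        for inner in _match_content(p.content, c, tree):
                            merged = dict(a)
                            merged.update(inner)
                            nxt.append(merged)
                    sub_assigns = nxt
                    if not sub_assigns:
                        ok = False
                        break
            if not ok:
                continue
            for a in sub_assigns:
                yield from assign_groups(rest, a)

    yield from assign_groups(list(groups.items()), {})


def _match_content(elems, comp, tree):
    """Content-block matching: exact unless a sequence variable binds
    the residual."""
    has_seq = any(isinstance(e, TypedSeqVar) for e in elems)
    nc_pats = [e for e in elems if isinstance(e, TypedNode)
               and not e.species.is_compartment]
    comp_pats = [e for e in elems if isinstance(e, TypedNode)
                 and e.species.is_compartment]
    if not has_seq:
        total = sum(comp.pops.values())
        if total != len(nc_pats) or len(comp.children) != len(comp_pats):
            return
    yield from _match(elems, comp, tree)


@pytest.fixture
def naive_cls():
    return NaiveDirectMethod


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
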