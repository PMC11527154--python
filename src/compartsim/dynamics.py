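"""Hybrid simulation loop with dynamic compartments.

The engine alternates between two representations: the flat simulator
executes regular reactions on index-based arrays; when a
structure-changing reaction is selected, the state is converted back
to the compartment tree, the rewrite (creation, deletion, fusion,
fission, shuttling) is applied there, the tree is re-flattened and
the reaction network, dependency graph, update plans and propensity
tree are rebuilt from scratch.  Rebuilding is costly but amortizes
while structural changes are rare; the event log reports regular
firings, structural firings and rebuild counts so that regime is
measurable.

Sequence-variable splits assign every residual element -- each
individual entity copy, and each child compartment as an atomic unit
with its contents -- independently to branch j with probability
R_j / sum(R), the weights evaluated at firing time.  Fusion takes the
multiset union of contents; the compartment instance matched first
(lowest instance id) keeps its identity.

After a rebuild the exponential clock simply restarts; by the
memorylessness of the CTMC this is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import rates as R
from .matcher import (Binding, Unfoldable, _cmp, enumerate_reactions,
                      try_fold)
from .model import (ModelError, Species, TypedModel, TypedNode, TypedRule,
                    TypedSeqVar)
from .netfree import choose_and_remove, eligible_count
from .ssa import FlatSimulator, SimClock, StaticRunOutcome
from .state import (CompartmentNode, FlatState, StateTree, VariantTable,
                    build_initial_state, coerce_attr, flat_to_tree,
                    tree_to_flat)

__all__ = ["SimConfig", "TimedEvent", "Trajectory", "run", "simulate",
           "apply_structural", "StructuralEvent"]


# --------------------------------------------------------------------------
# configuration / results
# --------------------------------------------------------------------------


@dataclass
class TimedEvent:
    """Scheduled intervention: purge a species at a scope at a time."""

    time: float
    species: str
    scope: str = "root"  # root | all

    def __post_init__(self) -> None:
        if self.scope not in ("root", "all"):
            raise ModelError(f"unknown event scope {self.scope!r}")


@dataclass
class SimConfig:
    t_end: float
    seed: int = 0
    replications: int = 1
    interval: Optional[float] = None  # observable sampling interval
    events: List[TimedEvent] = field(default_factory=list)
    max_indices: Optional[int] = None  # "model too large" cap override
    debug: bool = False

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ModelError("t_end must be positive")
        if self.replications < 1:
            raise ModelError("replications must be >= 1")
        if self.interval is None:
            self.interval = self.t_end / 100.0
        if self.interval <= 0:
            raise ModelError("sampling interval must be positive")
        for ev in self.events:
            if ev.time < 0:
                raise ModelError(f"event time {ev.time} before start")


@dataclass
class StructuralEvent:
    time: float
    rule: int
    detail: str


@dataclass
class Trajectory:
    """Sampled observables plus the event log of one replication."""

    obs_names: List[str]
    times: List[float] = field(default_factory=list)
    values: List[List[float]] = field(default_factory=list)
    events: List[Tuple[float, str, Any, str]] = field(default_factory=list)
    n_regular: int = 0
    n_structural: int = 0
    n_builds: int = 0
    final_tree: Optional[StateTree] = None

    @property
    def n_rebuilds(self) -> int:
        return max(0, self.n_builds - 1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.times, name="time"),
                            columns=self.obs_names).reset_index()

    def events_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.events,
                            columns=["time", "kind", "rule", "details"])

    def column(self, name: str) -> np.ndarray:
        i = self.obs_names.index(name)
        return np.asarray([row[i] for row in self.values])


# --------------------------------------------------------------------------
# observables
# --------------------------------------------------------------------------


class _ObsEvaluator:
    """Per-rebuild compiled observable queries over the flat state."""

    def __init__(self, model: TypedModel, flat: FlatState):
        self.model = model
        self.flat = flat
        self.entries = [self._build(o) for o in model.observables]

    def _match_variant(self, obs, key) -> bool:
        sp = obs.species
        if key[0] != sp.sid:
            return False
        for ai, op, ir in obs.constraints:
            val = key[1][sp.enum_idx.index(ai)]
            try:
                ref = try_fold(ir, None, {})
            except Unfoldable:
                raise ModelError(
                    f"observable {obs.name}: constraint is not static")
            if not _cmp(op, val, ref):
                return False
        return True

    def _in_scope(self, obs, iid: int) -> bool:
        if obs.scope is None:
            return True
        return self.flat.instances[iid].species.sid == obs.scope.sid

    def _build(self, obs):
        flat = self.flat
        if obs.species.is_compartment:
            insts = []
            for iid in flat.order:
                rec = flat.instances[iid]
                if rec.species.sid != obs.species.sid:
                    continue
                if obs.scope is not None and (
                        rec.parent < 0
                        or flat.instances[rec.parent].species.sid
                        != obs.scope.sid):
                    continue
                checks = []
                for ai, op, ir in obs.constraints:
                    aslot = flat.attr_slot(iid, ai)
                    try:
                        ref = try_fold(ir, None, {})
                    except Unfoldable:
                        raise ModelError(
                            f"observable {obs.name}: constraint must compare "
                            f"against a constant")
                    checks.append((aslot, op, ref))
                insts.append((iid, checks))
            return ("comp", insts)
        if obs.nf_constraints:
            tests = []
            for ai, op, ir in obs.nf_constraints:
                pos = obs.species.nf_idx.index(ai)
                ref = try_fold(ir, None, {})
                tests.append((pos, op, ref))

            def pred(t, _tests=tuple(tests)):
                return all(_cmp(op, t[pos], ref) for pos, op, ref in _tests)

            stores = [(iid, vid) for (iid, vid) in flat.slot_of
                      if self._match_variant(obs, flat.variants.keys[vid])
                      and self._in_scope(obs, iid)]
            return ("nf", stores, pred)
        slots = [s for (iid, vid), s in flat.slot_of.items()
                 if self._match_variant(obs, flat.variants.keys[vid])
                 and self._in_scope(obs, iid)]
        return ("sum", sorted(slots))

    def values(self) -> List[float]:
        flat = self.flat
        out = []
        for entry in self.entries:
            if entry[0] == "sum":
                out.append(float(sum(flat.C[s] for s in entry[1])))
            elif entry[0] == "nf":
                _, stores, pred = entry
                out.append(float(sum(flat.nf_count(st, pred)
                                     for st in stores)))
            else:
                total = 0
                for iid, checks in entry[1]:
                    if all(_cmp(op, flat.A[aslot], ref)
                           for aslot, op, ref in checks):
                        total += 1
                out.append(float(total))
        return out


class _Sampler:
    """Records observables on the fixed time grid as time advances."""

    def __init__(self, model: TypedModel, interval: float, t_end: float,
                 traj: Trajectory):
        self.model = model
        self.interval = interval
        self.t_end = t_end
        self.traj = traj
        self.next_idx = 0
        self.evaluator: Optional[_ObsEvaluator] = None

    def attach(self, flat: FlatState) -> None:
        self.evaluator = _ObsEvaluator(self.model, flat)

    def _grid_time(self, idx: int) -> float:
        return min(idx * self.interval, self.t_end)

    def record_until(self, flat: FlatState, t: float, inclusive: bool) -> None:
        while True:
            gt = self._grid_time(self.next_idx)
            if gt < t or (inclusive and gt <= t):
                self.traj.times.append(gt)
                self.traj.values.append(self.evaluator.values())
                if gt >= self.t_end:
                    self.next_idx = 10 ** 18  # grid exhausted
                    return
                self.next_idx += 1
            else:
                return


# --------------------------------------------------------------------------
# structural rewriting
# --------------------------------------------------------------------------


class _TreeFireEnv(R.Env):
    """Expression environment while rewriting the tree."""

    def __init__(self, tree: StateTree, rng, rule: TypedRule,
                 binding: Binding, nodes: Dict[int, CompartmentNode]):
        self.tree = tree
        self.rng = rng
        self.rule = rule
        self.binding = binding
        self.nodes = nodes
        self.chosen: Dict[int, Tuple] = {}
        self.residual_counts: Dict[str, int] = {}

    def attr_val(self, node_id: int, attr: int) -> Any:
        node = self.rule.lhs_nodes[node_id]
        sp = node.species
        if sp.is_compartment:
            return self.nodes[self.binding.comp[node_id]].attrs[attr]
        if sp.attributes[attr].is_nf:
            t = self.chosen.get(node_id)
            if t is None:
                raise ModelError("internal: network-free value not chosen")
            return t[sp.nf_idx.index(attr)]
        key = self.binding.var[node_id]
        return key[1][sp.enum_idx.index(attr)]

    def count_val(self, var: str) -> float:
        rule, b = self.rule, self.binding
        if var in rule.pop_vars:
            node = rule.pop_vars[var]
            parent = self.nodes[b.parent_iid(node)]
            if node.species.is_compartment:
                return float(sum(
                    1 for c in parent.children
                    if c.species.sid == node.species.sid))
            return float(parent.pops.get(b.var[node.node_id], 0))
        if var in self.residual_counts:
            return float(self.residual_counts[var])
        raise ModelError(f"#{var}: unbound at rewrite time")


@dataclass
class _Residual:
    pops: Dict = field(default_factory=dict)
    nf: Dict = field(default_factory=dict)
    children: List[CompartmentNode] = field(default_factory=list)

    def element_count(self) -> int:
        return sum(self.pops.values()) + len(self.children)

    def merge_into(self, target: CompartmentNode) -> None:
        for key, n in self.pops.items():
            target.add(key, n, self.nf.get(key))
        for child in self.children:
            target.children.append(child)


def _nf_pred(node: TypedNode, rule: TypedRule, var_assign) -> Optional[Any]:
    if not node.nf_constraints:
        return None
    sp = node.species
    tests = []
    for ai, op, ir in node.nf_constraints:
        pos = sp.nf_idx.index(ai)
        val = try_fold(ir, rule, var_assign)
        tests.append((pos, op, val))

    def pred(t, _tests=tuple(tests)):
        return all(_cmp(op, t[pos], val) for pos, op, val in _tests)

    return pred


def apply_structural(tree: StateTree, rule: TypedRule, binding: Binding,
                     rng) -> StructuralEvent:
    """Apply a structure-changing rewrite to the tree in place."""

    nodes = tree.nodes_by_iid()
    env = _TreeFireEnv(tree, rng, rule, binding, nodes)
    detail_parts: List[str] = []

    # 1. consume matched non-compartment reactants (catalysts included;
    #    preserved occurrences are re-added by the rhs placement)
    for node in rule.lhs_nodes:
        if node.species.is_compartment:
            continue
        parent = nodes[binding.parent_iid(node)]
        key = binding.var[node.node_id]
        if node.species.nf_idx:
            store = parent.nf.setdefault(key, [])
            pred = _nf_pred(node, rule, binding.var)
            env.chosen[node.node_id] = choose_and_remove(store, pred, rng)
        parent.remove(key, 1)

    # 2. detach matched compartment instances (content travels along)
    matched_comp_iids = set(binding.comp.values())
    for node_id, iid in binding.comp.items():
        comp = nodes[iid]
        parent = nodes[binding.parent_iid(rule.lhs_nodes[node_id])]
        parent.children.remove(comp)

    # 3. extract residual content of every lhs content block
    residuals: Dict[int, _Residual] = {}  # lhs node_id -> residual
    for node in rule.lhs_nodes:
        if not node.species.is_compartment or node.content is None:
            continue
        comp = nodes[binding.comp[node.node_id]]
        # matched children were detached in step 2; the rest is residual
        res = _Residual(dict(comp.pops),
                        {k: list(v) for k, v in comp.nf.items() if v},
                        list(comp.children))
        comp.pops.clear()
        comp.nf.clear()
        comp.children = []
        residuals[node.node_id] = res

    # 4. bind residuals to sequence variables (sampling splits)
    seq_content: Dict[str, _Residual] = {}
    by_parent: Dict[int, List[TypedSeqVar]] = {}
    for sv in rule.seq_vars.values():
        by_parent.setdefault(sv.parent.node_id, []).append(sv)
    for pid, svs in by_parent.items():
        res = residuals.get(pid)
        if res is None:
            raise ModelError("internal: sequence variable without residual")
        if len(svs) == 1:
            seq_content[svs[0].name] = res
        else:
            weights = []
            for sv in svs:
                w = float(R.interpret(sv.weight, env)) \
                    if sv.weight is not None else 1.0
                if w < 0:
                    raise ModelError(
                        f"negative split weight for ?{sv.name}")
                weights.append(w)
            wsum = sum(weights)
            if wsum <= 0:
                raise ModelError("split weights sum to zero")
            probs = [w / wsum for w in weights]
            parts = _split_residual(res, probs, rng)
            for sv, part in zip(svs, parts):
                seq_content[sv.name] = part
    for name, res in seq_content.items():
        env.residual_counts[name] = res.element_count()

    # 5. destroy unpaired lhs compartments (unbound content dies with them)
    for node in rule.lhs_nodes:
        if node.species.is_compartment and node.partner is None:
            detail_parts.append(f"-{node.species.name}"
                                f"#{binding.comp[node.node_id]}")

    # 6. build the rhs
    def place(elems, target: CompartmentNode) -> None:
        for el in elems:
            if isinstance(el, TypedSeqVar):
                res = seq_content.get(el.name)
                if res is not None:
                    res.merge_into(target)
                continue
            _place_node(el, target)

    def _place_node(rn: TypedNode, target: CompartmentNode) -> None:
        sp = rn.species
        if sp.is_compartment:
            if rn.partner is not None:
                comp = nodes[binding.comp[rn.partner.node_id]]
                for ai, ir in rn.assignments.items():
                    comp.attrs[ai] = coerce_attr(
                        sp.attributes[ai].kind, R.interpret(ir, env))
                target.children.append(comp)
                if rn.content is not None:
                    place(rn.content, comp)
                return
            n = 1
            if rn.count is not None:
                n = int(round(float(R.interpret(rn.count, env))))
                if n < 0:
                    raise ModelError("negative compartment production count")
            for _ in range(n):
                attrs = [coerce_attr(a.kind,
                                     R.interpret(rn.assignments[i], env))
                         for i, a in enumerate(sp.attributes)]
                comp = tree.new_node(sp, attrs, target)
                detail_parts.append(f"+{sp.name}#{comp.iid}")
                if rn.content is not None:
                    place(rn.content, comp)
            return
        # non-compartment production / preserved occurrence
        n = 1
        if rn.count is not None:
            n = int(round(float(R.interpret(rn.count, env))))
            if n < 0:
                raise ModelError("negative production count")
        for _ in range(n):
            enum_vals = []
            for pos, ai in enumerate(sp.enum_idx):
                if ai in rn.assignments:
                    v = R.interpret(rn.assignments[ai], env)
                elif rn.partner is not None:
                    v = binding.var[rn.partner.node_id][1][pos]
                else:
                    raise ModelError(
                        f"produced {sp.name}: attribute not assigned")
                enum_vals.append(coerce_attr(sp.attributes[ai].kind, v))
            nf_tuple = None
            if sp.nf_idx:
                vals = []
                for pos, ai in enumerate(sp.nf_idx):
                    if ai in rn.assignments:
                        v = R.interpret(rn.assignments[ai], env)
                    elif rn.partner is not None:
                        v = env.chosen[rn.partner.node_id][pos]
                    else:
                        raise ModelError(
                            f"produced {sp.name}: nf attribute not assigned")
                    vals.append(coerce_attr(sp.attributes[ai].kind, v))
                nf_tuple = tuple(vals)
            key = (sp.sid, tuple(enum_vals))
            target.add(key, 1, [nf_tuple] if nf_tuple is not None else None)

    ctx = nodes[binding.ctx_iid]
    place(rule.rhs, ctx)

    return StructuralEvent(0.0, rule.idx, ",".join(detail_parts) or "rewrite")


def _split_residual(res: _Residual, probs: List[float], rng
                    ) -> List[_Residual]:
    """Assign each residual element independently to one branch."""
    k = len(probs)
    parts = [_Residual() for _ in range(k)]
    for key in sorted(res.pops):
        n = res.pops[key]
        nf = res.nf.get(key)
        if nf:
            # assign each individual tuple
            choices = rng.choice(k, size=n, p=probs)
            for t, c in zip(nf, choices):
                parts[c].pops[key] = parts[c].pops.get(key, 0) + 1
                parts[c].nf.setdefault(key, []).append(t)
        else:
            counts = rng.multinomial(n, probs)
            for c, m in enumerate(counts):
                if m:
                    parts[c].pops[key] = parts[c].pops.get(key, 0) + int(m)
    for child in res.children:
        c = int(rng.choice(k, p=probs))
        parts[c].children.append(child)
    return parts


# --------------------------------------------------------------------------
# timed events
# --------------------------------------------------------------------------


def _apply_event(tree: StateTree, model: TypedModel, ev: TimedEvent) -> str:
    sp = model.species_by_name.get(ev.species)
    if sp is None:
        raise ModelError(f"event purges unknown species {ev.species!r}")
    scopes = [tree.root] if ev.scope == "root" else list(tree.root.walk())
    removed = 0
    for node in scopes:
        for key in [k for k in node.pops if k[0] == sp.sid]:
            removed += node.pops.pop(key)
            node.nf.pop(key, None)
        if sp.is_compartment:
            keep = []
            for c in node.children:
                if c.species.sid == sp.sid:
                    removed += 1
                else:
                    keep.append(c)
            node.children = keep
    return f"purge {ev.species} ({ev.scope}): removed {removed}"


# --------------------------------------------------------------------------
# outer loop
# --------------------------------------------------------------------------


def run(model: TypedModel, config: SimConfig, replication: int = 0
        ) -> Trajectory:
    """Run one replication of the hybrid loop until t_end."""

    rng = np.random.default_rng(np.random.SeedSequence(
        (int(config.seed), int(replication))))
    if config.max_indices is not None:
        model.max_indices = config.max_indices
    tree = build_initial_state(model, rng)
    clock = SimClock(0.0, rng)
    traj = Trajectory([o.name for o in model.observables])
    sampler = _Sampler(model, float(config.interval), config.t_end, traj)
    variants = VariantTable()
    tcache = R.TemplateCache()
    events = sorted(config.events, key=lambda e: e.time)
    ev_i = 0

    while True:
        flat = tree_to_flat(tree, variants)
        network = enumerate_reactions(model, flat, tcache)
        sim = FlatSimulator(network, rng)
        traj.n_builds += 1
        sampler.attach(flat)
        if config.debug:
            _debug_checks(sim, flat, tree)
        seg_end = config.t_end
        if ev_i < len(events):
            seg_end = min(seg_end, events[ev_i].time)
        out = sim.run(clock, seg_end, sampler)
        traj.n_regular += out.steps

        if out.status == "structural":
            tree = flat_to_tree(flat)
            ev = apply_structural(tree, out.reaction.rule,
                                  out.reaction.binding, rng)
            traj.n_structural += 1
            traj.events.append((clock.t, "structural",
                                out.reaction.rule.idx, ev.detail))
            continue
        # reached seg_end (t_end, event time, or quiescent until seg_end)
        if ev_i < len(events) and seg_end < config.t_end:
            tree = flat_to_tree(flat)
            detail = _apply_event(tree, model, events[ev_i])
            traj.events.append((clock.t, "event", events[ev_i].species, detail))
            ev_i += 1
            continue
        # done: keep the final tree for inspection
        traj.final_tree = flat_to_tree(flat)
        return traj


def simulate(model: TypedModel, config: SimConfig) -> List[Trajectory]:
    """Run all configured replications (seed = (base seed, index))."""
    return [run(model, config, rep) for rep in range(config.replications)]


def _debug_checks(sim: FlatSimulator, flat: FlatState, tree: StateTree) -> None:
    total = sim.tree.total
    fresh = sim.tree.fresh_total()
    if fresh > 0 and abs(total - fresh) > 1e-9 * max(1.0, fresh):
        raise ModelError(f"propensity tree total {total} deviates from "
                         f"fresh sum {fresh}")
    rt = flat_to_tree(flat)
    if rt.signature() != tree.signature():
        raise ModelError("flatten/unflatten round trip mismatch")
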