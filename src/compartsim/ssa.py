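"""Exact SSA over a static reaction network.

Selection and update use a complete binary tree with cumulative-sum
tracking: each node stores the propensity of one reaction and the sum
of the propensities in its child subtrees, giving O(log n) weighted
selection and O(log n) propensity updates.  Reactions are laid out in
descending order of their build-time propensity, placing likely
reactions near the root.

Updates are rolled out in two phases: first the changed node values
are written, then the de-duplicated set of ancestor sums is
recomputed bottom-up -- shared ancestors of several changed nodes are
summed exactly once.  Which nodes and ancestors each reaction's
firing touches is precomputed into an :class:`UpdatePlan`.  Because
every affected subtree sum is recomputed from its children rather
than adjusted incrementally, floating-point error does not accumulate
over steps; it is bounded by a single summation over the tree depth.

Timestep sampling follows the direct method: dt ~ Exp(total
propensity), reaction by weighted choice from one uniform draw walked
down the tree (descent order: the node's own propensity first, then
the left subtree, then the right; strict ``<`` against the own value,
``<=`` on subtree entry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import rates as R
from .matcher import Reaction, ReactionNetwork, build_dependency_graph
from .model import ModelError
from .netfree import fire_regular
from .state import FlatState

__all__ = ["PropensityTree", "UpdatePlan", "SimClock", "build_tree",
           "build_plans", "FlatSimulator", "StaticRunOutcome"]


class PropensityTree:
    """Complete binary tree of (propensity, child-subtree sum) pairs."""

    def __init__(self, props: Sequence[Tuple[int, float]]):
        # likely reactions towards the root: descending propensity
        order = sorted(props, key=lambda rp: (-rp[1], rp[0]))
        self.rids: List[int] = [rid for rid, _ in order]
        self.pos: Dict[int, int] = {rid: i for i, rid in enumerate(self.rids)}
        self.own: List[float] = [float(p) for _, p in order]
        n = len(self.own)
        self.sub: List[float] = [0.0] * n
        self.n = n
        for i in range(n - 1, 0, -1):
            parent = (i - 1) >> 1
            self.sub[parent] += self.own[i] + self.sub[i]
        #: ancestor-sum recomputations performed (operation counter)
        self.sum_ops = 0

    @property
    def total(self) -> float:
        return (self.own[0] + self.sub[0]) if self.n else 0.0

    def fresh_total(self) -> float:
        """Recompute the total from scratch (compensated summation)."""
        return float(math.fsum(self.own))

    def propensity(self, rid: int) -> float:
        return self.own[self.pos[rid]]

    # -- selection -------------------------------------------------------
    def sample(self, r: float) -> int:
        """Weighted choice: walk ``r`` in [0, total) down the tree."""
        own, sub, n = self.own, self.sub, self.n
        i = 0
        while True:
            p = own[i]
            if r < p:
                return self.rids[i]
            r -= p
            left = 2 * i + 1
            if left < n:
                lt = own[left] + sub[left]
                if r <= lt:
                    i = left
                    continue
                r -= lt
                right = left + 1
                if right < n:
                    i = right
                    continue
            # numerical leftover: clamp to the current node
            return self.rids[i]

    def select_by_scan(self, r: float) -> int:
        """Linear cumulative scan in tree order (selection oracle).

        Walks the same (own, left subtree, right subtree) order as
        :meth:`sample` but subtracts node values one at a time.
        """
        own, sub, n = self.own, self.sub, self.n

        def scan(i: int, r: float):
            p = own[i]
            if r < p:
                return self.rids[i], None
            r -= p
            for c in (2 * i + 1, 2 * i + 2):
                if c < n:
                    ct = own[c] + sub[c]
                    if r <= ct:
                        got, rem = scan(c, r)
                        if got is not None:
                            return got, None
                        r = rem
                    else:
                        r -= ct
            return None, r

        got, rem = scan(0, r)
        if got is None:
            # leftover beyond the last node: clamp like sample()
            return self.rids[0] if n else -1
        return got

    # -- two-phase update ------------------------------------------------
    def set_own(self, rid: int, p: float) -> None:
        if p < 0:
            raise ModelError(f"negative propensity {p} for reaction {rid}")
        self.own[self.pos[rid]] = p

    def update_ancestors(self, schedule: Sequence[int]) -> None:
        own, sub, n = self.own, self.sub, self.n
        for i in schedule:  # descending positions: children before parents
            left = 2 * i + 1
            s = 0.0
            if left < n:
                s = own[left] + sub[left]
                right = left + 1
                if right < n:
                    s += own[right] + sub[right]
            sub[i] = s
            self.sum_ops += 1

    def apply_update(self, plan: "UpdatePlan",
                     changes: Sequence[Tuple[int, float]]) -> None:
        """Phase 1: write changed node values; phase 2: ancestor sums."""
        for rid, p in changes:
            self.set_own(rid, p)
        self.update_ancestors(plan.schedule)


@dataclass(frozen=True)
class UpdatePlan:
    """Precomputed update schedule for one reaction's firing."""

    rids: Tuple[int, ...]      # dependent reactions to re-evaluate
    positions: Tuple[int, ...]  # their tree positions
    schedule: Tuple[int, ...]   # de-duplicated ancestors, descending


def build_tree(props: Sequence[Tuple[int, float]]) -> PropensityTree:
    return PropensityTree(props)


def build_plans(graph: Dict[int, Tuple[int, ...]],
                tree: PropensityTree) -> Dict[int, UpdatePlan]:
    """Precompute, per reaction, the summation work its firing entails.

    Ancestors shared between several updated nodes appear once; the
    schedule is ordered children-first so each subtree sum is
    recomputed from already-updated values.
    """
    plans: Dict[int, UpdatePlan] = {}
    for rid, deps in graph.items():
        positions = tuple(tree.pos[d] for d in deps)
        anc = 0  # bitset of ancestor positions
        for p in positions:
            # own value changed: every proper ancestor's sum changes;
            # positions with children also need no own-sum fix (sub
            # unchanged by own updates)
            while p > 0:
                p = (p - 1) >> 1
                bit = 1 << p
                if anc & bit:
                    break  # ancestors above are already marked
                anc |= bit
        schedule = []
        p = anc.bit_length() - 1
        while p >= 0:
            if anc >> p & 1:
                schedule.append(p)
            p -= 1
        plans[rid] = UpdatePlan(tuple(deps), positions,
                                tuple(sorted(schedule, reverse=True)))
    return plans


@dataclass
class SimClock:
    t: float
    rng: np.random.Generator


@dataclass
class StaticRunOutcome:
    status: str  # "t_end" | "quiescent" | "structural"
    reaction: Optional[Reaction] = None
    steps: int = 0


class FlatSimulator:
    """Static (flat) simulator: network + propensity tree + plans."""

    def __init__(self, network: ReactionNetwork, rng: np.random.Generator,
                 graph: Optional[Dict[int, Tuple[int, ...]]] = None):
        self.network = network
        self.flat: FlatState = network.flat
        self.rng = rng
        self.graph = graph if graph is not None else \
            build_dependency_graph(network)
        props = [(rx.rid, self.eval_propensity(rx))
                 for rx in network.reactions]
        self.tree = PropensityTree(props)
        self.plans = build_plans(self.graph, self.tree)

    # ------------------------------------------------------------------
    def eval_propensity(self, rx: Reaction) -> float:
        flat = self.flat
        try:
            p = rx.tmpl.fn(rx.params, flat.C, flat.A, flat.nf_count)
        except ZeroDivisionError:
            raise R.EvalError(
                f"division by zero in rate of rule {rx.rule.idx} "
                f"(line {rx.rule.loc})") from None
        p = float(p)
        if math.isnan(p) or math.isinf(p):
            raise ModelError(
                f"rule {rx.rule.idx}: propensity is {p} (overflow/NaN)")
        if p < 0:
            raise ModelError(
                f"rule {rx.rule.idx} (line {rx.rule.loc}): negative rate {p}")
        rx.propensity = p
        return p

    # ------------------------------------------------------------------
    def run(self, clock: SimClock, t_end: float,
            sampler: Optional["_SamplerProto"] = None,
            max_steps: Optional[int] = None,
            trace: Optional[list] = None) -> StaticRunOutcome:
        """Run regular reactions until t_end, quiescence or a
        structural reaction is selected (the latter is returned
        unapplied; the clock is already advanced to its firing time).
        """
        tree = self.tree
        flat = self.flat
        rng = clock.rng
        reactions = self.network.reactions
        plans = self.plans
        steps = 0
        while True:
            if max_steps is not None and steps >= max_steps:
                return StaticRunOutcome("t_end", steps=steps)
            total = tree.total
            if total <= 0.0:
                if sampler is not None:
                    sampler.record_until(flat, t_end, inclusive=True)
                clock.t = t_end
                return StaticRunOutcome("quiescent", steps=steps)
            u1 = rng.random()
            dt = -math.log1p(-u1) / total
            t_new = clock.t + dt
            u2 = rng.random()
            if t_new > t_end:
                if sampler is not None:
                    sampler.record_until(flat, t_end, inclusive=True)
                clock.t = t_end
                return StaticRunOutcome("t_end", steps=steps)
            if sampler is not None:
                sampler.record_until(flat, t_new, inclusive=False)
            clock.t = t_new
            rid = tree.sample(u2 * total)
            if trace is not None:
                trace.append((dt, rid))
            rx = reactions[rid]
            if rx.kind == "structural":
                return StaticRunOutcome("structural", rx, steps)
            fire_regular(rx, flat, rng)
            steps += 1
            plan = plans[rid]
            changes = [(dep, self.eval_propensity(reactions[dep]))
                       for dep in plan.rids]
            tree.apply_update(plan, changes)


class _SamplerProto:  # pragma: no cover - typing aid
    def record_until(self, flat: FlatState, t: float, inclusive: bool) -> None:
        ...
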