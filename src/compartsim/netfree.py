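"""Network-free attribute handling.

Attributes declared ``nf_int`` / ``nf_real`` are not enumerated into
the reaction network.  Instead, each (compartment instance, species
variant) slot carries an instance store: one value tuple per
individual copy, kept in lock-step with the slot's count.

Propensities of rules constrained on network-free attributes use
``eligible_count`` -- the number of stored tuples satisfying the
left-hand-side constraints -- so constrained-rate semantics are exact
rather than rejection-based.  When such a rule fires, one eligible
instance is drawn uniformly at random, its values are bound to the
rule's right-hand-side expressions, and store and count array are
updated together.
"""

from __future__ import annotations

from typing import Any, Dict, List, Optional, Tuple

from . import rates as R
from .model import ModelError
from .state import FlatState, coerce_attr

__all__ = ["eligible_count", "eligible_indices", "FireEnv",
           "choose_and_remove", "produce", "fire_regular"]


def eligible_count(store: List[Tuple], pred: Optional[Any]) -> int:
    """Number of instances in *store* satisfying *pred* (None = all)."""
    if pred is None:
        return len(store)
    return sum(1 for t in store if pred(t))


def eligible_indices(store: List[Tuple], pred: Optional[Any]) -> List[int]:
    if pred is None:
        return list(range(len(store)))
    return [i for i, t in enumerate(store) if pred(t)]


class FireEnv(R.Env):
    """Evaluation environment at firing time.

    Binds the network-free attribute values of the instances chosen
    for consumption, and exposes the flat arrays for any remaining
    dynamic leaves (compartment attribute slots, count slots).
    """

    def __init__(self, flat: FlatState, rng):
        self.flat = flat
        self.C = flat.C
        self.A = flat.A
        self.rng = rng
        #: lhs node_id -> chosen nf value tuple
        self.chosen: Dict[int, Tuple] = {}
        #: lhs node_id -> species (for nf attr position lookup)
        self.species_of: Dict[int, Any] = {}

    def nf(self, store, pred):
        return self.flat.nf_count(store, pred)

    def attr_val(self, node_id: int, attr: int) -> Any:
        t = self.chosen.get(node_id)
        sp = self.species_of.get(node_id)
        if t is None or sp is None:
            raise ModelError(
                "internal error: unbound attribute access at firing time")
        return t[sp.nf_idx.index(attr)]


def choose_and_remove(store: List[Tuple], pred: Optional[Any], rng) -> Tuple:
    """Draw one eligible instance uniformly and remove it."""
    idx = eligible_indices(store, pred)
    if not idx:
        raise ModelError(
            "internal error: reaction fired with no eligible network-free "
            "instance (stale propensity)")
    if len(idx) == 1:
        i = idx[0]
    else:
        i = idx[int(rng.integers(len(idx)))]
    return store.pop(i)


def produce(flat: FlatState, store_key, values: Tuple) -> None:
    flat.nf_stores.setdefault(store_key, []).append(values)


def fire_regular(rx, flat: FlatState, rng) -> None:
    """Apply a regular reaction's effects to the flat state.

    Fast path: static count deltas only.  Full path adds network-free
    consumption/production, dynamic production counts and compartment
    attribute updates (all right-hand-side expressions read the
    pre-firing state).
    """

    if rx.simple:
        C = flat.C
        for s, d in rx.delta:
            C[s] += d
        return

    env = FireEnv(flat, rng)
    model = flat.model
    for store, pred, nid in rx.nf_consume:
        vs = flat.nf_stores.setdefault(store, [])
        env.chosen[nid] = choose_and_remove(vs, pred, rng)
        env.species_of[nid] = rx.rule.lhs_nodes[nid].species

    # attribute updates are simultaneous: evaluate all, then write
    new_attrs = []
    for aslot, ir, kind in rx.attr_updates:
        new_attrs.append((aslot, coerce_attr(kind, R.interpret(ir, env))))

    C = flat.C
    for s, d in rx.delta:
        C[s] += d
    for s, ir in rx.dyn_deltas:
        n = int(round(float(R.interpret(ir, env))))
        if n < 0:
            raise ModelError(f"rule {rx.rule.idx}: negative production "
                             f"count {n}")
        C[s] += n
    for aslot, v in new_attrs:
        flat.A[aslot] = v
    for store, irs, src, cnt in rx.nf_produce:
        if isinstance(cnt, float):
            n = int(cnt)
        else:
            n = int(round(float(R.interpret(cnt, env))))
        sid = flat.variants.keys[store[1]][0]
        sp = model.species[sid]
        kinds = [sp.attributes[ai].kind for ai in sp.nf_idx]
        vs = flat.nf_stores.setdefault(store, [])
        for _ in range(n):
            vs.append(tuple(coerce_attr(k, R.interpret(ir, env))
                            for k, ir in zip(kinds, irs)))
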