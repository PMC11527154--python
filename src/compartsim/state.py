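"""Simulation state: nested compartment tree and its flat form.

The tree form is an n-ary tree of compartment instances.  Each
instance owns per-instance attribute values, a multiset of
non-compartment entities (grouped by *species variant* -- species plus
the tuple of its enumerated attribute values -- with identical
entities merged into one count), network-free value vectors (one tuple
per individual copy), and child compartment instances, which are never
merged.

The flat form stores every (instance, variant) amount in one array
with static index-based access, per-instance attribute slots in a
second array, and enough parent/child bookkeeping to reverse the
transformation exactly.  The variant dictionary is global, shared by
all instances and across rebuilds, so identical contents in different
compartments share variant ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Tuple

import numpy as np

from . import rates as R
from .model import (ModelError, ModelTooLargeError, Species, TypedModel,
                    TypedNode)

__all__ = ["VariantTable", "CompartmentNode", "StateTree", "FlatState",
           "build_initial_state", "tree_to_flat", "flat_to_tree"]

EnumTuple = Tuple[Any, ...]
VariantKey = Tuple[int, EnumTuple]  # (species id, enumerated attribute tuple)


def coerce_attr(kind: str, value: Any) -> Any:
    if kind in ("int", "nf_int"):
        return int(round(float(value)))
    if kind in ("real", "nf_real"):
        return float(value)
    return str(value)


class VariantTable:
    """Global species-variant dictionary: (sid, enum attrs) -> variant id."""

    def __init__(self) -> None:
        self.index: Dict[VariantKey, int] = {}
        self.keys: List[VariantKey] = []

    def vid(self, key: VariantKey) -> int:
        v = self.index.get(key)
        if v is None:
            v = len(self.keys)
            self.index[key] = v
            self.keys.append(key)
        return v

    def __len__(self) -> int:
        return len(self.keys)


class CompartmentNode:
    """One compartment instance with its content multiset."""

    __slots__ = ("iid", "species", "attrs", "pops", "nf", "children")

    def __init__(self, iid: int, species: Species,
                 attrs: Optional[List[Any]] = None):
        self.iid = iid
        self.species = species
        self.attrs: List[Any] = attrs if attrs is not None else []
        #: variant key -> count (merged identical entities)
        self.pops: Dict[VariantKey, int] = {}
        #: variant key -> list of network-free value tuples (len == count)
        self.nf: Dict[VariantKey, List[Tuple]] = {}
        self.children: List["CompartmentNode"] = []

    # -- content editing -------------------------------------------------
    def add(self, key: VariantKey, n: int = 1,
            nf_tuples: Optional[List[Tuple]] = None) -> None:
        if n == 0 and not nf_tuples:
            return
        self.pops[key] = self.pops.get(key, 0) + n
        if nf_tuples:
            self.nf.setdefault(key, []).extend(nf_tuples)
        if self.pops[key] == 0:
            del self.pops[key]

    def remove(self, key: VariantKey, n: int = 1) -> None:
        have = self.pops.get(key, 0)
        if have < n:
            raise ModelError(
                f"removing {n} x variant {key} from compartment {self.iid} "
                f"which holds {have}")
        if have == n:
            del self.pops[key]
        else:
            self.pops[key] = have - n

    def entity_count(self) -> int:
        """Residual-element count: entities plus child compartments."""
        return sum(self.pops.values()) + len(self.children)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def signature(self) -> Tuple:
        """Canonical content signature, invariant under sibling reordering."""
        pops = tuple(sorted((k, v) for k, v in self.pops.items()))
        nf = tuple(sorted((k, tuple(sorted(map(tuple, vs))))
                          for k, vs in self.nf.items() if vs))
        kids = tuple(sorted(c.signature() for c in self.children))
        return (self.species.sid, tuple(self.attrs), pops, nf, kids)


@dataclass
class StateTree:
    root: CompartmentNode
    model: TypedModel
    next_iid: int = 1

    def new_node(self, species: Species, attrs: List[Any],
                 parent: Optional[CompartmentNode]) -> CompartmentNode:
        node = CompartmentNode(self.next_iid, species, attrs)
        self.next_iid += 1
        if parent is not None:
            parent.children.append(node)
        return node

    def nodes_by_iid(self) -> Dict[int, CompartmentNode]:
        return {n.iid: n for n in self.root.walk()}

    def total_noncompartment_entities(self) -> int:
        return sum(sum(n.pops.values()) for n in self.root.walk())

    def compartment_count(self) -> int:
        """Number of compartment instances, excluding the root scope."""
        return sum(1 for _ in self.root.walk()) - 1

    def signature(self) -> Tuple:
        return self.root.signature()

    def to_json(self) -> str:
        """Serialize the tree to JSON for inspection and debugging.

        Each compartment becomes ``{"id", "species", "attrs", "pops",
        "nf", "children"}``; population keys are rendered as
        ``"Species(v1,v2,...)"``.
        """
        import json

        def key_str(key: VariantKey) -> str:
            sp = self.model.species[key[0]]
            vals = ",".join(str(v) for v in key[1])
            return f"{sp.name}({vals})" if vals else sp.name

        def node_obj(n: CompartmentNode) -> dict:
            return {
                "id": n.iid,
                "species": n.species.name,
                "attrs": {a.name: v for a, v in
                          zip(n.species.attributes, n.attrs)},
                "pops": {key_str(k): c for k, c in sorted(n.pops.items())},
                "nf": {key_str(k): [list(t) for t in vs]
                       for k, vs in sorted(n.nf.items()) if vs},
                "children": [node_obj(c) for c in
                             sorted(n.children, key=lambda c: c.iid)],
            }

        return json.dumps(node_obj(self.root), indent=2)


# --------------------------------------------------------------------------
# initial state
# --------------------------------------------------------------------------


class _InitEnv(R.Env):
    def __init__(self, rng):
        self.rng = rng


def _eval_init(ir: Any, rng) -> Any:
    return R.interpret(ir, _InitEnv(rng))


def build_initial_state(model: TypedModel, rng: np.random.Generator) -> StateTree:
    """Materialize the declared initial state.

    Counts and attribute expressions may contain samplers; they are
    drawn per created copy from *rng*, so two compartments declared by
    one counted term get independent attribute values.
    """

    root = CompartmentNode(0, model.root_species, [])
    tree = StateTree(root, model)
    for node in model.init:
        _materialize(tree, node, root, rng)
    return tree


def _materialize(tree: StateTree, spec: TypedNode, parent: CompartmentNode,
                 rng) -> None:
    n = 1
    if spec.count is not None:
        raw = float(_eval_init(spec.count, rng))
        n = int(round(raw))
        if n < 0:
            raise ModelError(f"negative initial count {raw} for "
                             f"{spec.species.name}", spec.loc)
    sp = spec.species
    if sp.is_compartment:
        for _ in range(n):
            attrs = [coerce_attr(a.kind, _eval_init(spec.assignments[i], rng))
                     for i, a in enumerate(sp.attributes)]
            node = tree.new_node(sp, attrs, parent)
            for child in spec.content or []:
                _materialize(tree, child, node, rng)
    else:
        if spec.content:
            raise ModelError(f"{sp.name} is not a compartment", spec.loc)
        for _ in range(n):
            enum_vals = tuple(
                coerce_attr(sp.attributes[i].kind,
                            _eval_init(spec.assignments[i], rng))
                for i in sp.enum_idx)
            nf_vals = tuple(
                coerce_attr(sp.attributes[i].kind,
                            _eval_init(spec.assignments[i], rng))
                for i in sp.nf_idx)
            key = (sp.sid, enum_vals)
            parent.add(key, 1, [nf_vals] if sp.nf_idx else None)


# --------------------------------------------------------------------------
# flat representation
# --------------------------------------------------------------------------


@dataclass
class InstanceRec:
    iid: int
    species: Species
    parent: int  # parent iid; -1 for root
    child_iids: List[int] = field(default_factory=list)


class FlatState:
    """Index-based state: count array, attribute slots, nf stores."""

    def __init__(self, model: TypedModel, variants: VariantTable):
        self.model = model
        self.variants = variants
        self.instances: Dict[int, InstanceRec] = {}
        self.order: List[int] = []  # iids in deterministic (DFS) order
        self.C: List[float] = []  # counts per slot
        self.slot_of: Dict[Tuple[int, int], int] = {}  # (iid, vid) -> slot
        self.slot_keys: List[Tuple[int, int]] = []
        self.A: List[Any] = []  # per-instance attribute values
        self.attr_slot_of: Dict[Tuple[int, int], int] = {}  # (iid, attr_idx)
        #: (iid, vid) -> list of nf tuples, kept in lock-step with counts
        self.nf_stores: Dict[Tuple[int, int], List[Tuple]] = {}
        self.next_iid = 1
        self.root_iid = 0

    # -- slots -----------------------------------------------------------
    def ensure_slot(self, iid: int, vid: int) -> int:
        key = (iid, vid)
        s = self.slot_of.get(key)
        if s is None:
            if len(self.C) >= self.model.max_indices:
                raise ModelTooLargeError(
                    f"model too large: enumerated index space exceeds "
                    f"{self.model.max_indices} (variants x instances)")
            s = len(self.C)
            self.slot_of[key] = s
            self.slot_keys.append(key)
            self.C.append(0.0)
        return s

    def attr_slot(self, iid: int, attr_idx: int) -> int:
        key = (iid, attr_idx)
        s = self.attr_slot_of.get(key)
        if s is None:
            raise ModelError(f"no attribute slot for instance {iid}")
        return s

    def nf_count(self, store: Tuple[int, int], pred) -> int:
        vs = self.nf_stores.get(store)
        if not vs:
            return 0
        if pred is None:
            return len(vs)
        return sum(1 for t in vs if pred(t))

    def instance_slots(self, iid: int) -> List[int]:
        return [s for (i, v), s in self.slot_of.items() if i == iid]


def tree_to_flat(tree: StateTree, variants: Optional[VariantTable] = None
                 ) -> FlatState:
    """Flatten a compartment tree into index-based arrays.

    The result is exactly reversible by :func:`flat_to_tree`; the
    total entity count and all instance ids are preserved.
    """

    model = tree.model
    flat = FlatState(model, variants if variants is not None else VariantTable())
    flat.next_iid = tree.next_iid
    flat.root_iid = tree.root.iid

    def visit(node: CompartmentNode, parent_iid: int) -> None:
        if node.iid in flat.instances:
            raise ModelError(f"duplicate instance id {node.iid} in tree")
        rec = InstanceRec(node.iid, node.species, parent_iid)
        flat.instances[node.iid] = rec
        flat.order.append(node.iid)
        for ai in range(len(node.species.attributes)):
            flat.attr_slot_of[(node.iid, ai)] = len(flat.A)
            flat.A.append(node.attrs[ai])
        for key in sorted(node.pops):
            vid = flat.variants.vid(key)
            s = flat.ensure_slot(node.iid, vid)
            flat.C[s] = float(node.pops[key])
            if key in node.nf and node.nf[key]:
                flat.nf_stores[(node.iid, vid)] = [tuple(t)
                                                   for t in node.nf[key]]
        for child in sorted(node.children, key=lambda c: c.iid):
            rec.child_iids.append(child.iid)
            visit(child, node.iid)

    visit(tree.root, -1)
    return flat


def flat_to_tree(flat: FlatState) -> StateTree:
    """Reconstruct the compartment tree; isomorphic to the flattened one."""

    model = flat.model
    nodes: Dict[int, CompartmentNode] = {}
    for iid in flat.order:
        rec = flat.instances[iid]
        attrs = [flat.A[flat.attr_slot_of[(iid, ai)]]
                 for ai in range(len(rec.species.attributes))]
        nodes[iid] = CompartmentNode(iid, rec.species, attrs)
    root = nodes.get(flat.root_iid)
    if root is None:
        raise ModelError("corrupted flat state: missing root instance")
    for iid in flat.order:
        rec = flat.instances[iid]
        node = nodes[iid]
        if rec.parent >= 0:
            nodes[rec.parent].children.append(node)
    for (iid, vid), slot in flat.slot_of.items():
        n = flat.C[slot]
        if n < 0:
            raise ModelError(f"negative count {n} at slot {slot}")
        if n:
            if n != int(n):
                raise ModelError(f"non-integer count {n} at slot {slot}")
            key = flat.variants.keys[vid]
            nf = flat.nf_stores.get((iid, vid))
            nodes[iid].pops[key] = int(n)
            if nf:
                if len(nf) != int(n):
                    raise ModelError(
                        f"nf store length {len(nf)} != count {int(n)} "
                        f"for instance {iid}")
                nodes[iid].nf[key] = [tuple(t) for t in nf]
    tree = StateTree(root, model, next_iid=flat.next_iid)
    return tree
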