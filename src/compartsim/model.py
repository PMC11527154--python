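"""Checked model representation.

A :class:`TypedModel` is the output of type checking: all names
resolved, numeric literals rescaled to canonical units, rules paired
(each right-hand-side species occurrence linked to the left-hand-side
occurrence it preserves) and classified as regular or structural.

Attribute kinds split into *enumerated* (``int``, ``real``,
``string``, ``enum`` -- part of the species-variant key that the
reaction network enumerates over) and *network-free* (``nf_int``,
``nf_real`` -- kept out of the network; per-copy values live in
instance vectors).  Compartment species are treated as individuals:
all their attributes are per-instance and none may be network-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Tuple, Union

from .dsl.syntax import Loc
from .dsl.units import Unit

ROOT_SPECIES = "$root"

NF_KINDS = ("nf_int", "nf_real")


class ModelError(ValueError):
    """Semantic model error (type, unit, resolution, enum violation)."""

    def __init__(self, msg: str, loc: Optional[Loc] = None):
        super().__init__(f"{loc}: {msg}" if loc is not None else msg)
        self.loc = loc


@dataclass(frozen=True)
class AttributeDef:
    name: str
    kind: str  # int | real | string | enum | nf_int | nf_real
    unit: Unit
    enum_values: Tuple[str, ...] = ()

    @property
    def is_nf(self) -> bool:
        return self.kind in NF_KINDS

    @property
    def is_numeric(self) -> bool:
        return self.kind not in ("string", "enum")


@dataclass
class Species:
    sid: int
    name: str
    attributes: Tuple[AttributeDef, ...]
    is_compartment: bool = False

    def __post_init__(self) -> None:
        self.attr_index: Dict[str, int] = {
            a.name: i for i, a in enumerate(self.attributes)}
        if len(self.attr_index) != len(self.attributes):
            raise ModelError(f"duplicate attribute name in species {self.name}")
        self.enum_idx: Tuple[int, ...] = tuple(
            i for i, a in enumerate(self.attributes) if not a.is_nf)
        self.nf_idx: Tuple[int, ...] = tuple(
            i for i, a in enumerate(self.attributes) if a.is_nf)

    def __hash__(self) -> int:
        return self.sid

    def __repr__(self) -> str:  # pragma: no cover
        return f"Species({self.name})"


@dataclass
class TypedSeqVar:
    name: str
    weight: Any = None  # rate IR, evaluated at firing time
    parent: Optional["TypedNode"] = None


@dataclass
class TypedNode:
    """One species occurrence in a typed rule side / init / observable."""

    node_id: int
    species: Species
    side: str  # lhs | rhs | init | obs
    #: (attr_idx, op, IR) over enumerated attributes; op in == != < > <= >=
    constraints: List[Tuple[int, str, Any]] = field(default_factory=list)
    #: same, over network-free attributes
    nf_constraints: List[Tuple[int, str, Any]] = field(default_factory=list)
    #: rhs/init assignments attr_idx -> IR
    assignments: Dict[int, Any] = field(default_factory=dict)
    pop_bind: Optional[str] = None
    content: Optional[List[Union["TypedNode", TypedSeqVar]]] = None
    count: Any = None  # IR multiplicity (init / rhs)
    partner: Optional["TypedNode"] = None  # lhs<->rhs preservation link
    parent: Optional["TypedNode"] = None
    loc: Loc = field(default_factory=Loc)

    def __hash__(self) -> int:
        return id(self)


@dataclass
class TypedRule:
    idx: int
    lhs: List[Union[TypedNode, TypedSeqVar]]
    rhs: List[Union[TypedNode, TypedSeqVar]]
    rate: Any  # IR
    kind: str = "regular"  # regular | structural
    loc: Loc = field(default_factory=Loc)
    #: all lhs nodes in DFS order (node_id indexes into this)
    lhs_nodes: List[TypedNode] = field(default_factory=list)
    #: all rhs nodes in DFS order
    rhs_nodes: List[TypedNode] = field(default_factory=list)
    #: population-binding variable -> lhs node
    pop_vars: Dict[str, TypedNode] = field(default_factory=dict)
    #: sequence variable name -> TypedSeqVar (lhs occurrence)
    seq_vars: Dict[str, TypedSeqVar] = field(default_factory=dict)
    #: sequence variable name -> rhs location (parent rhs node or None)
    rhs_seq_parents: Dict[str, Optional[TypedNode]] = field(default_factory=dict)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TypedRule(#{self.idx}, {self.kind})"


@dataclass
class TypedObservable:
    name: str
    species: Species
    constraints: List[Tuple[int, str, Any]]
    nf_constraints: List[Tuple[int, str, Any]]
    scope: Optional[Species] = None


@dataclass
class TypedModel:
    species: List[Species]
    species_by_name: Dict[str, Species]
    constants: Dict[str, float]
    constant_units: Dict[str, Unit]
    rules: List[TypedRule]
    init: List[TypedNode]
    observables: List[TypedObservable]
    #: cap on enumerated (variant x instance) index space
    max_indices: int = 10 ** 6

    @property
    def root_species(self) -> Species:
        return self.species_by_name[ROOT_SPECIES]

    @property
    def regular_rules(self) -> List[TypedRule]:
        return [r for r in self.rules if r.kind == "regular"]

    @property
    def structural_rules(self) -> List[TypedRule]:
        return [r for r in self.rules if r.kind == "structural"]


class ModelTooLargeError(ModelError):
    """Enumerated index space exceeded the configured cap."""
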