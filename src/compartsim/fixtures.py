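"""Bundled models: analytic toys, a synthetic-model generator, and
best-effort transcriptions of the two published case studies.

The toys have closed-form checks (stationary means, exponential
growth, binomial split ratios, conservation laws) and together
exercise every language feature: named attributes, comparisons,
enums, units, network-free attributes, sequence variables, split
weights and nesting.

The synthetic generator produces models that typecheck by
construction and are bounded (every species gets a decay rule), for
randomized engine-vs-oracle comparisons.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Tuple

from .dynamics import SimConfig, TimedEvent

__all__ = ["toy_models", "immigration_death", "pure_death", "dimerization",
           "yule_splitter", "weighted_fission", "protein_shuttle",
           "virus_entry", "netfree_pair", "SyntheticModelSpec",
           "generate_model", "case_studies", "mrna_delivery_config"]


# --------------------------------------------------------------------------
# analytic toys
# --------------------------------------------------------------------------

def immigration_death(k: float = 10.0, d: float = 1.0) -> str:
    """Birth at rate k, per-capita death at rate d.

    Stationary distribution: Poisson(k/d); stationary mean k/d.
    """
    return f"""
const k: {k};
const d: {d};
species A();
init 0 A;
-> A @ k;
A:a -> @ d*#a;
observe nA: A;
"""


def pure_death(n0: int = 100, d: float = 1.0) -> str:
    """Decay of n0 initial copies; terminates quiescent at #A = 0."""
    return f"""
const d: {d};
species A();
init {n0} A;
A:a -> @ d*#a;
observe nA: A;
"""


def dimerization(kf: float = 0.01, kr: float = 1.0, n0: int = 100) -> str:
    """Reversible dimerization 2A <-> B with explicit mass action."""
    return f"""
const kf: {kf};
const kr: {kr};
species A(); species B();
init {n0} A;
A:a + A -> B @ 0.5*kf*#a*(#a-1);
B:b -> A + A @ kr*#b;
observe nA: A;
observe nB: B;
"""


def yule_splitter(k: float = 1.0) -> str:
    """Pure compartment fission at constant rate k per compartment.

    A Yule process: E[#compartments at t] = exp(k t).
    """
    return f"""
const kf: {k};
species C();
init 1 C{{}};
C{{?c1+?c2}} -> C{{?c1}} + C{{?c2}} @ kf;
observe nC: C;
"""


def weighted_fission(r1: float = 3.0, r2: float = 1.0, cargo: int = 10000
                     ) -> str:
    """One fission of a mitochondrion-like compartment with weighted
    content split: each cargo element goes to branch 1 with
    probability r1/(r1+r2)."""
    return f"""
const kf: 1;
const R1: {r1};
const R2: {r2};
species M(); species X();
init 1 M{{{cargo} X}};
M{{?m1[R1]+?m2[R2]}} -> M{{?m1}} + M{{?m2}} @ kf;
observe nM: M;
"""


def protein_shuttle(ks: float = 1.0, n0: int = 50) -> str:
    """Protein import into the nucleus: a count update between two
    static compartments (regular); conserves total protein."""
    return f"""
const ks: {ks};
species Cell(); species Nuc(); species Prot();
init 1 Cell{{ 1 Nuc{{}} + {n0} Prot }};
Cell{{Nuc{{?n}} + Prot:p + ?c}} -> Cell{{Nuc{{Prot+?n}} + ?c}} @ ks*#p;
observe cytosolic: Prot in Cell;
observe nuclear: Prot in Nuc;
"""


def virus_entry(kv: float = 1.0, n0: int = 20) -> str:
    """A virus compartment entering the cell: containment change of a
    whole compartment (structural); conserves compartments and cargo."""
    return f"""
const kv: {kv};
species Cell(); species V(); species G();
init 1 Cell{{}} + {n0} V{{ 1 G }};
Cell{{?c}} + V{{?v}} -> Cell{{V{{?v}}+?c}} @ kv;
observe outside: V;
observe genomes: G;
"""


def netfree_pair(kb: float = 8.0, ku: float = 1.5, kd: float = 1.0,
                 dd: float = 0.8) -> Tuple[str, str]:
    """The same two-state birth/switch/decay model, once with the
    state attribute enumerated and once declared network-free.

    The two variants define the same CTMC, so their observable
    distributions must be statistically indistinguishable.
    """
    body = """
init 2 S(x=1);
-> S(x=1) @ kb;
S(x==1):a -> S(x=2) @ ku*#a;
S(x==2):b -> S(x=1) @ kd*#b;
S(x==2):c -> @ dd*#c;
observe total: S;
observe active: S(x==2);
"""
    consts = f"const kb: {kb};\nconst ku: {ku};\nconst kd: {kd};\nconst dd: {dd};\n"
    enum_text = consts + "species S(x: int);\n" + body
    nf_text = consts + "species S(x: nf_int);\n" + body
    return nf_text, enum_text


def toy_models() -> Dict[str, str]:
    return {
        "immigration_death": immigration_death(),
        "pure_death": pure_death(),
        "dimerization": dimerization(),
        "yule_splitter": yule_splitter(),
        "weighted_fission": weighted_fission(),
        "protein_shuttle": protein_shuttle(),
        "virus_entry": virus_entry(),
        "netfree": netfree_pair()[0],
    }


# --------------------------------------------------------------------------
# synthetic model generator
# --------------------------------------------------------------------------


@dataclass
class SyntheticModelSpec:
    seed: int = 0
    n_species: int = 4
    n_compartment_types: int = 0
    nesting_depth: int = 1
    n_rules: int = 6
    frac_structural: float = 0.0
    enum_domain: int = 0  # values of an enum attribute on species 0
    rate_lo: float = 0.1
    rate_hi: float = 2.0
    init_count: int = 20

    def __post_init__(self) -> None:
        if self.n_species < 1 and self.n_rules > 0:
            raise ValueError("rules need at least one species")
        if self.n_compartment_types == 0:
            self.frac_structural = 0.0


def generate_model(spec: SyntheticModelSpec) -> str:
    """Deterministically generate a model that parses, typechecks and
    runs: every species has a decay rule, so populations stay bounded.
    """

    rnd = random.Random(spec.seed)
    lines: List[str] = ["// synthetic model", f"// seed {spec.seed}"]
    names = [f"S{i}" for i in range(spec.n_species)]
    comp_names = [f"C{i}" for i in range(spec.n_compartment_types)]
    enum_vals = [f"v{i}" for i in range(spec.enum_domain)]

    n_const = 0

    def k() -> str:
        nonlocal n_const
        n_const += 1
        val = round(rnd.uniform(spec.rate_lo, spec.rate_hi), 4)
        lines.append(f"const k{n_const}: {val};")
        return f"k{n_const}"

    decls = []
    for i, nm in enumerate(names):
        if i == 0 and spec.enum_domain:
            decls.append(f"species {nm}(a: enum {{{' '.join(enum_vals)}}});")
        else:
            decls.append(f"species {nm}();")
    for nm in comp_names:
        decls.append(f"species {nm}();")

    def sp_term(i: int, var: str) -> Tuple[str, str]:
        """lhs reactant text and its count reference."""
        if i == 0 and spec.enum_domain:
            v = rnd.choice(enum_vals)
            return f'{names[i]}(a=="{v}"):{var}', v
        return f"{names[i]}:{var}", ""

    def rhs_term(i: int) -> str:
        if i == 0 and spec.enum_domain:
            return f'{names[i]}(a="{rnd.choice(enum_vals)}")'
        return names[i]

    rules: List[str] = []
    # unconstrained decay for every species keeps the dynamics bounded
    for i in range(spec.n_species):
        rules.append(f"{names[i]}:x -> @ {k()}*#x;")
    n_structural = round(spec.frac_structural * spec.n_rules)
    target = max(spec.n_species, spec.n_rules - n_structural)
    while len(rules) < target:
        kind = rnd.choice(["birth", "convert", "bimol"]
                          if spec.n_species > 1 else ["birth", "convert"])
        if kind == "birth":
            rules.append(f"-> {rhs_term(rnd.randrange(spec.n_species))} "
                         f"@ {k()};")
        elif kind == "convert":
            i = rnd.randrange(spec.n_species)
            j = rnd.randrange(spec.n_species)
            lhs, _ = sp_term(i, "x")
            rules.append(f"{lhs} -> {rhs_term(j)} @ {k()}*#x;")
        else:
            i, j = rnd.sample(range(spec.n_species), 2)
            t1, _ = sp_term(i, "x")
            t2, _ = sp_term(j, "y")
            prod = rhs_term(rnd.randrange(spec.n_species))
            rules.append(f"{t1} + {t2} -> {prod} @ {k()}*#x*#y;")
    for _ in range(n_structural):
        cn = rnd.choice(comp_names)
        kind = rnd.choice(["split", "dissolve", "create"])
        # splitting/creation rates are scaled down: compartment counts
        # grow exponentially under fission, and the generator promises
        # models that stay desk-sized
        if kind == "split":
            rules.append(f"{cn}{{?a+?b}} -> {cn}{{?a}} + {cn}{{?b}} "
                         f"@ 0.2*{k()};")
        elif kind == "dissolve":
            rules.append(f"{cn}{{?a}} -> ?a @ {k()};")
        else:
            rules.append(f"-> {cn}{{}} @ 0.2*{k()};")

    init_terms = []
    for i in range(spec.n_species):
        n = rnd.randint(1, spec.init_count)
        if i == 0 and spec.enum_domain:
            init_terms.append(f'{n} {names[i]}(a="{enum_vals[0]}")')
        else:
            init_terms.append(f"{n} {names[i]}")
    for cn in comp_names:
        if spec.enum_domain and spec.n_species == 1:
            inner = f'{rnd.randint(1, 5)} {names[0]}(a="{enum_vals[0]}")'
        else:
            inner = (f"{rnd.randint(1, 5)} "
                     f"{names[rnd.randrange(max(1, spec.n_species - 1)) + 1]}"
                     if spec.n_species > 1 else "")
        term = inner
        for _ in range(max(1, min(spec.nesting_depth, 3))):
            term = f"1 {cn}{{ {term} }}"
        init_terms.append(term)

    lines.extend(decls)
    lines.append("init " + " + ".join(init_terms) + ";")
    lines.extend(rules)
    for i, nm in enumerate(names):
        lines.append(f"observe n{nm}: {nm};")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# case studies (transcribed; stand-in kinetic constants)
# --------------------------------------------------------------------------

def _read_model(fname: str) -> str:
    return (resources.files("compartsim.models") / fname).read_text()


def case_studies() -> Dict[str, str]:
    """Transcriptions of the fission-yeast and mRNA-delivery studies.

    The rule structure follows the published descriptions; kinetic
    constants are synthetic stand-ins (marked in the files), so these
    exercise the engine rather than reproduce published curves.
    """
    return {
        "yeast": _read_model("yeast_synthetic.mlr3"),
        "mrna_delivery": _read_model("mrna_delivery_synthetic.mlr3"),
    }


def mrna_delivery_config(t_end_hours: float = 30.0, seed: int = 0,
                         replications: int = 1) -> SimConfig:
    """Simulation setup for the mRNA delivery model: extracellular
    lipoplexes are washed away after one hour."""
    return SimConfig(
        t_end=t_end_hours * 3600.0,
        seed=seed,
        replications=replications,
        interval=1800.0,
        events=[TimedEvent(time=3600.0, species="L", scope="root")],
    )
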