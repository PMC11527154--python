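"""Rule classification, reaction enumeration and dependency graph."""

import numpy as np
import pytest

from conftest import brute_force_matches, interp_propensity

from compartsim.dsl.typecheck import load_model
from compartsim.fixtures import SyntheticModelSpec, generate_model
from compartsim.matcher import build_dependency_graph, enumerate_reactions
from compartsim.model import ModelTooLargeError
from compartsim.netfree import fire_regular
from compartsim.state import build_initial_state, tree_to_flat


def _setup(text, seed=0, **kw):
    model = load_model(text, **kw)
    tree = build_initial_state(model, np.random.default_rng(seed))
    flat = tree_to_flat(tree)
    return model, tree, flat


# -- classification ---------------------------------------------------------

CLASSIFY_CASES = [
    # weighted fission: redistributes content -> structural
    ("species M(); init 1 M{};\n"
     "M{?m1[3]+?m2[1]} -> M{?m1} + M{?m2} @ 1;", "structural"),
    # pure attribute update on a compartment -> regular
    ("species Cell(phase: int); init 1 Cell(phase=1){};\n"
     "Cell(phase==1) -> Cell(phase=2) @ 1;", "regular"),
    # count change inside an existing compartment -> regular
    ("species E(); species mRNA(); init 1 E{ 3 mRNA };\n"
     "E{mRNA:m+?solE} -> E{?solE} @ 0.1*#m;", "regular"),
    # fusion -> structural
    ("species M(); init 2 M{};\n"
     "M{?a} + M{?b} -> M{?a+?b} @ 1;", "structural"),
    # compartment creation -> structural
    ("species Cell(); species P(); species E(); init 1 Cell{} + 1 P{};\n"
     "Cell{?c} + P{?p} -> Cell{E{?p}+?c} @ 1;", "structural"),
    # molecule moving between two preserved compartments -> regular
    ("species Cell(); species Nuc(); species Prot();\n"
     "init 1 Cell{ 1 Nuc{} + 2 Prot };\n"
     "Cell{Nuc{?n}+Prot:p+?c} -> Cell{Nuc{Prot+?n}+?c} @ 1*#p;", "regular"),
    # dropping a sequence variable destroys content -> structural
    ("species E(); init 1 E{};\n"
     "E{?e} -> @ 1;", "structural"),
]


@pytest.mark.parametrize("text,expected", CLASSIFY_CASES)
def test_classification(text, expected):
    model = load_model(text)
    assert model.rules[0].kind == expected


# -- enumeration ------------------------------------------------------------

def test_endocytosis_over_ten_distinct_pits_yields_ten_reactions():
    """One compact rule against 1 cell + 10 pits with pairwise distinct
    content enumerates exactly the 10 reactions the unrolled model
    needs."""
    text = """
    species Cell(); species P(); species E(); species L(sz: int);
    init 1 Cell{};
    Cell{?c} + P{?p} -> Cell{E{?p}+?c} @ 0.2;
    """
    model, tree, _ = _setup(text)
    lsid = model.species_by_name["L"].sid
    psp = model.species_by_name["P"]
    for i in range(10):
        pit = tree.new_node(psp, [], tree.root)
        pit.add((lsid, (i,)), i + 1)  # pairwise distinct content
    flat = tree_to_flat(tree)
    net = enumerate_reactions(model, flat)
    assert len(net.reactions) == 10
    assert all(r.kind == "structural" for r in net.reactions)


def test_absent_reactant_species_yields_zero_propensity_not_zero_instances():
    model, tree, flat = _setup(
        "species A(); species B(); init 2 B;\nA:a -> B @ 1*#a;")
    net = enumerate_reactions(model, flat)
    assert len(net.reactions) == 1
    assert interp_propensity(net.reactions[0], flat) == 0.0


def test_absent_compartment_reactant_yields_zero_instances():
    model, tree, flat = _setup(
        "species C(); species A(); init 2 A;\nC{?c} -> ?c @ 1;")
    net = enumerate_reactions(model, flat)
    assert len(net.reactions) == 0


def test_model_too_large_error():
    text = "species A(x: int); init 1 A(x=0);\nA -> A(x=A.x+1) @ 1;"
    with pytest.raises(ModelTooLargeError):
        model, tree, flat = _setup(text, max_indices=50)
        enumerate_reactions(model, flat)


@pytest.mark.parametrize("seed", range(40))
def test_enumeration_matches_brute_force(seed):
    """Enumerated instances with satisfiable reactants equal an
    exhaustive recursive matcher on random nested states."""
    spec = SyntheticModelSpec(
        seed=seed, n_species=3, n_rules=6,
        n_compartment_types=1 + seed % 2, nesting_depth=1 + seed % 3,
        frac_structural=0.5, init_count=8)
    model = load_model(generate_model(spec))
    tree = build_initial_state(model, np.random.default_rng(seed))
    flat = tree_to_flat(tree)
    net = enumerate_reactions(model, flat)

    engine = set()
    for rx in net.reactions:
        if interp_propensity(rx, flat) > 0:
            engine.add((rx.rule.idx, rx.binding.ctx_iid,
                        tuple(sorted(rx.binding.comp.items()))))
    oracle = brute_force_matches(model, tree)
    assert engine == oracle


# -- dependency graph -------------------------------------------------------

def test_disjoint_compartments_share_no_edge():
    text = """
    species C(); species A(); species B();
    init 1 C{ 5 A } + 1 C{ 5 B };
    A:a -> @ 1*#a;
    B:b -> @ 1*#b;
    """
    model, tree, flat = _setup(text)
    net = enumerate_reactions(model, flat)
    graph = build_dependency_graph(net)
    live = [rx.rid for rx in net.reactions
            if interp_propensity(rx, flat) > 0]
    a, b = live  # decay of A in cell 1, decay of B in cell 2
    assert b not in graph[a]
    assert a not in graph[b]


def test_chained_conversions_are_linked():
    text = """
    species A(); species B(); species C();
    init 5 A;
    A:a -> B @ 1*#a;
    B:b -> C @ 1*#b;
    """
    model, tree, flat = _setup(text)
    net = enumerate_reactions(model, flat)
    graph = build_dependency_graph(net)
    r_ab = next(r.rid for r in net.reactions if r.rule.idx == 0)
    r_bc = next(r.rid for r in net.reactions if r.rule.idx == 1)
    assert r_bc in graph[r_ab]


@pytest.mark.parametrize("seed", range(15))
def test_firing_changes_only_dependency_successors(seed):
    """Full-recompute oracle: after firing r, only propensities of
    graph successors of r may differ."""
    spec = SyntheticModelSpec(seed=seed, n_species=4, n_rules=8,
                              init_count=10)
    model = load_model(generate_model(spec))
    tree = build_initial_state(model, np.random.default_rng(seed))
    flat = tree_to_flat(tree)
    net = enumerate_reactions(model, flat)
    graph = build_dependency_graph(net)
    rng = np.random.default_rng(seed + 1)
    for rx in net.reactions:
        if interp_propensity(rx, flat) <= 0 or not rx.simple:
            continue
        before = [interp_propensity(r, flat) for r in net.reactions]
        fire_regular(rx, flat, rng)
        after = [interp_propensity(r, flat) for r in net.reactions]
        changed = {i for i, (x, y) in enumerate(zip(before, after)) if x != y}
        assert changed <= set(graph[rx.rid]), \
            f"reaction {rx.rid} changed non-successors {changed}"
        for s, d in rx.delta:  # revert
            flat.C[s] -= d


def test_network_dump_lists_every_reaction():
    model, tree, flat = _setup(
        "species A(); species B(); init 3 A;\nA:a -> B @ 1*#a;")
    net = enumerate_reactions(model, flat)
    dump = net.dump()
    assert "rule=0" in dump and "kind=regular" in dump
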