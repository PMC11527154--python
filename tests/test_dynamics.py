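"""Structural rewriting and the outer hybrid loop."""

import math

import numpy as np
import pytest

from compartsim.dsl.typecheck import load_model
from compartsim.dynamics import (SimConfig, TimedEvent, apply_structural,
                                 run, simulate)
from compartsim.matcher import enumerate_reactions
from compartsim.model import ModelError
from compartsim.state import build_initial_state, tree_to_flat


def _one_structural(text, seed=0):
    model = load_model(text)
    rng = np.random.default_rng(seed)
    tree = build_initial_state(model, rng)
    net = enumerate_reactions(model, tree_to_flat(tree))
    rx = next(r for r in net.reactions if r.kind == "structural")
    apply_structural(tree, rx.rule, rx.binding, rng)
    return model, tree


def test_fusion_takes_union_of_contents():
    model, tree = _one_structural("""
    species M(); species X(); species Y();
    init 1 M{ 3 X } + 1 M{ 2 Y };
    M{?a} + M{?b} -> M{?a+?b} @ 1;
    """)
    ms = [n for n in tree.root.walk() if n.species.name == "M"]
    assert len(ms) == 1
    assert ms[0].iid == 1  # first-matched (lowest) instance id survives
    xs = ms[0].pops[(model.species_by_name["X"].sid, ())]
    ys = ms[0].pops[(model.species_by_name["Y"].sid, ())]
    assert (xs, ys) == (3, 2)


def test_degenerate_split_sends_everything_one_way():
    model, tree = _one_structural("""
    species M(); species X();
    init 1 M{ 50 X };
    M{?m1[1]+?m2[0]} -> M{?m1} + M{?m2} @ 1;
    """)
    counts = sorted(
        (n.pops.get((model.species_by_name["X"].sid, ()), 0)
         for n in tree.root.walk() if n.species.name == "M"),
        reverse=True)
    assert counts == [50, 0]


def test_split_ratio_follows_weights():
    """With weights (3,1) each of 10^4 elements goes to branch 1 with
    probability 3/4 (binomial 3 sigma)."""
    model, tree = _one_structural("""
    species M(); species X();
    init 1 M{ 10000 X };
    M{?m1[3]+?m2[1]} -> M{?m1} + M{?m2} @ 1;
    """, seed=21)
    xk = (model.species_by_name["X"].sid, ())
    counts = [n.pops.get(xk, 0) for n in tree.root.walk()
              if n.species.name == "M"]
    total, p = sum(counts), 0.75
    kept = max(counts)
    sigma = math.sqrt(total * p * (1 - p))
    assert abs(kept - total * p) < 3 * sigma


def test_child_compartments_travel_atomically_in_splits():
    model, tree = _one_structural("""
    species M(); species N(); species G();
    init 1 M{ 1 N{ 7 G } };
    M{?a+?b} -> M{?a} + M{?b} @ 1;
    """)
    ns = [n for n in tree.root.walk() if n.species.name == "N"]
    assert len(ns) == 1
    assert ns[0].pops[(model.species_by_name["G"].sid, ())] == 7


def test_endocytosis_moves_content_and_conserves_entities():
    text = """
    species Cell(); species P(); species E(); species L();
    init 1 Cell{} + 1 P{ 4 L };
    Cell{?c} + P{?p} -> Cell{E{?p}+?c} @ 1;
    """
    model, tree = _one_structural(text)
    assert [n.species.name for n in tree.root.children] == ["Cell"]
    cell = tree.root.children[0]
    endo = cell.children[0]
    assert endo.species.name == "E"
    assert endo.pops[(model.species_by_name["L"].sid, ())] == 4
    assert tree.total_noncompartment_entities() == 4


def test_yule_splitter_mean_matches_exponential():
    """E[#compartments] = exp(k t) for the pure splitter."""
    from compartsim.fixtures import yule_splitter
    model = load_model(yule_splitter(k=1.0))
    t_end, reps = 1.5, 400
    finals = [run(model, SimConfig(t_end=t_end, seed=31), rep)
              .column("nC")[-1] for rep in range(reps)]
    mean = np.mean(finals)
    want = math.exp(t_end)
    var = math.exp(t_end) * (math.exp(t_end) - 1)  # Yule variance
    assert abs(mean - want) < 3 * math.sqrt(var / reps)


def test_zero_structural_rules_build_once():
    model = load_model("const k: 1;\nspecies A();\ninit 5 A;\n"
                       "A:a -> @ k*#a;\nobserve nA: A;\n")
    traj = run(model, SimConfig(t_end=10.0, seed=1))
    assert traj.n_builds == 1 and traj.n_rebuilds == 0


def test_event_log_reports_amortization_counters():
    from compartsim.fixtures import virus_entry
    model = load_model(virus_entry(kv=2.0, n0=5))
    traj = run(model, SimConfig(t_end=50.0, seed=4))
    assert traj.n_structural == 5  # all viruses enter eventually
    assert traj.n_builds == traj.n_structural + 1
    kinds = {e[1] for e in traj.events}
    assert kinds == {"structural"}


def test_shuttle_conserves_protein():
    from compartsim.fixtures import protein_shuttle
    model = load_model(protein_shuttle(ks=3.0, n0=40))
    traj = run(model, SimConfig(t_end=5.0, seed=9, interval=0.5))
    tot = traj.column("cytosolic") + traj.column("nuclear")
    assert (tot == 40).all()
    assert traj.n_rebuilds == 0  # molecule shuttling is regular


def test_rebuild_equals_enumeration_from_scratch():
    """After a structural event the rebuilt network matches a fresh
    enumeration of the post-event tree."""
    model, tree = _one_structural("""
    species C(); species X();
    init 1 C{ 6 X };
    C{?a+?b} -> C{?a} + C{?b} @ 1;
    X:x -> @ 0.3*#x;
    """)
    net1 = enumerate_reactions(model, tree_to_flat(tree))
    net2 = enumerate_reactions(model, tree_to_flat(tree))
    sig = lambda net: sorted(
        (r.rule.idx, r.binding.ctx_iid, tuple(sorted(r.binding.comp.items())))
        for r in net.reactions)
    assert sig(net1) == sig(net2)


# -- timed events -----------------------------------------------------------

def test_purge_event_removes_species_at_root():
    text = """
    const kv: 0.001;
    species Cell(); species L(); species mRNA();
    init 1 Cell{} + 20 L{ 2 mRNA };
    Cell{?c} + L{?l} -> Cell{L{?l}+?c} @ kv;
    observe outside: L;
    """
    model = load_model(text)
    cfg = SimConfig(t_end=10.0, seed=2, interval=1.0,
                    events=[TimedEvent(time=3.0, species="L", scope="root")])
    traj = run(model, SimConfig(t_end=10.0, seed=2, interval=1.0,
                                events=cfg.events))
    times = np.asarray(traj.times)
    outside = traj.column("outside")
    assert (outside[times > 3.0] == 0).all()
    assert any(e[1] == "event" for e in traj.events)


def test_empty_event_list_matches_plain_run():
    from compartsim.fixtures import immigration_death
    model = load_model(immigration_death())
    t1 = run(model, SimConfig(t_end=20.0, seed=5, interval=1.0))
    t2 = run(model, SimConfig(t_end=20.0, seed=5, interval=1.0, events=[]))
    assert t1.values == t2.values


def test_event_at_time_zero_applied_before_first_step():
    from compartsim.fixtures import pure_death
    model = load_model(pure_death(n0=50))
    traj = run(model, SimConfig(
        t_end=5.0, seed=1, interval=1.0,
        events=[TimedEvent(time=0.0, species="A", scope="all")]))
    assert traj.n_regular == 0
    assert traj.column("nA")[-1] == 0.0


def test_event_before_start_rejected():
    with pytest.raises(ModelError):
        SimConfig(t_end=1.0, events=[TimedEvent(time=-1.0, species="A")])


def test_replications_use_distinct_streams_deterministically():
    from compartsim.fixtures import immigration_death
    model = load_model(immigration_death())
    a = simulate(model, SimConfig(t_end=5.0, seed=8, replications=3))
    b = simulate(model, SimConfig(t_end=5.0, seed=8, replications=3))
    assert [t.values for t in a] == [t.values for t in b]
    assert a[0].values != a[1].values


def test_debug_mode_runs_consistency_checks():
    from compartsim.fixtures import yule_splitter
    model = load_model(yule_splitter())
    traj = run(model, SimConfig(t_end=1.0, seed=1, debug=True))
    assert traj.n_builds >= 1
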