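"""Propensity tree, two-phase updates and the flat simulator."""

import math

import numpy as np
import pytest

from compartsim.dsl.typecheck import load_model
from compartsim.dynamics import SimConfig, run
from compartsim.matcher import build_dependency_graph, enumerate_reactions
from compartsim.ssa import (FlatSimulator, PropensityTree, SimClock,
                            build_plans, build_tree)
from compartsim.state import build_initial_state, tree_to_flat


def _plan_for(tree, rids):
    return build_plans({0: tuple(rids)}, tree)[0]


# -- construction -----------------------------------------------------------

def test_single_reaction_tree():
    tree = build_tree([(0, 2.0)])
    assert tree.own == [2.0] and tree.sub == [0.0]
    assert tree.total == 2.0


def test_descending_layout_and_total():
    tree = build_tree([(0, 1.0), (1, 2.0), (2, 3.0)])
    assert tree.rids[0] == 2  # most likely reaction at the root
    assert tree.own == [3.0, 2.0, 1.0]
    assert tree.total == 6.0


@pytest.mark.parametrize("seed", range(10))
def test_total_matches_compensated_sum(seed):
    rng = np.random.default_rng(seed)
    ps = rng.uniform(0, 1e3, size=rng.integers(1, 500)).tolist()
    tree = build_tree(list(enumerate(ps)))
    assert tree.total == pytest.approx(math.fsum(ps), rel=1e-12)


# -- selection --------------------------------------------------------------

def test_single_reaction_always_selected():
    tree = build_tree([(7, 0.4)])
    for r in (0.0, 0.2, 0.399):
        assert tree.sample(r) == 7


def test_selection_frequencies_match_weights():
    tree = build_tree([(0, 1.0), (1, 2.0), (2, 3.0)])
    rng = np.random.default_rng(99)
    n = 300_000
    hits = np.zeros(3)
    for u in rng.random(n):
        hits[tree.sample(u * tree.total)] += 1
    for i, p in enumerate((1 / 6, 2 / 6, 3 / 6)):
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(hits[i] - n * p) < 3 * sigma


@pytest.mark.parametrize("seed", range(8))
def test_tree_descent_equals_linear_scan(seed):
    """The same uniform draw selects the same reaction by tree descent
    and by a linear cumulative scan in the same order."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 200))
    tree = build_tree(list(enumerate(rng.uniform(0, 10, n))))
    for u in rng.random(500):
        r = u * tree.total
        assert tree.sample(r) == tree.select_by_scan(r)


# -- updates ----------------------------------------------------------------

def test_leaf_to_zero_decreases_total_by_old_value():
    ps = [(i, float(i + 1)) for i in range(20)]
    tree = build_tree(ps)
    old_total = tree.total
    plan = _plan_for(tree, [5])
    tree.apply_update(plan, [(5, 0.0)])
    assert tree.total == pytest.approx(old_total - 6.0, rel=1e-12)


def test_sibling_updates_share_ancestor_summations():
    # positions 3 and 4 share all ancestors (1, 0): the two-phase
    # schedule must contain each ancestor exactly once
    tree = build_tree([(i, 10.0 - i) for i in range(7)])  # rid i at pos i
    plan = _plan_for(tree, [tree.rids[3], tree.rids[4]])
    assert sorted(plan.schedule, reverse=True) == list(plan.schedule)
    assert len(plan.schedule) == len(set(plan.schedule)) == 2
    before = tree.sum_ops
    tree.apply_update(plan, [(tree.rids[3], 1.0), (tree.rids[4], 2.0)])
    assert tree.sum_ops - before == 2  # one summation per shared ancestor


def test_negative_propensity_rejected():
    tree = build_tree([(0, 1.0)])
    from compartsim.model import ModelError
    with pytest.raises(ModelError):
        tree.set_own(0, -0.5)


def test_random_update_batches_track_fresh_rebuild():
    rng = np.random.default_rng(2024)
    n = 300
    tree = build_tree(list(enumerate(rng.uniform(0, 5, n))))
    for _ in range(10_000):
        k = int(rng.integers(1, 6))
        rids = rng.choice(n, size=k, replace=False).tolist()
        plan = _plan_for(tree, rids)
        tree.apply_update(plan, [(r, float(rng.uniform(0, 5)))
                                 for r in rids])
    assert tree.total == pytest.approx(tree.fresh_total(), rel=1e-9)


# -- run_static -------------------------------------------------------------

def _simulator(text, seed=0):
    model = load_model(text)
    rng = np.random.default_rng(seed)
    tree = build_initial_state(model, rng)
    flat = tree_to_flat(tree)
    net = enumerate_reactions(model, flat)
    return model, FlatSimulator(net, rng), SimClock(0.0, rng)


def test_immigration_death_time_average():
    """Stationary mean of the immigration-death process is k/d."""
    from compartsim.fixtures import immigration_death
    model = load_model(immigration_death(k=10.0, d=1.0))
    traj = run(model, SimConfig(t_end=1000.0, seed=11, interval=1.0))
    col = traj.column("nA")
    times = np.asarray(traj.times)
    vals = col[(times >= 50.0)]
    # Poisson(10) marginal, correlation time 1/d = 1, samples 1 apart:
    # effective n ~ len/2
    sigma_mean = math.sqrt(10.0 * 2.0 / len(vals))
    assert abs(vals.mean() - 10.0) < 3 * sigma_mean


def test_same_seed_reproduces_event_sequence_exactly():
    text = ("const k: 5;\nconst d: 0.5;\nspecies A(); species B();\n"
            "init 3 A;\n-> A @ k;\nA:a -> B @ d*#a;\nB:b -> @ d*#b;\n")
    traces = []
    for _ in range(2):
        model, sim, clock = _simulator(text, seed=7)
        tr = []
        sim.run(clock, 50.0, trace=tr)
        traces.append(tr)
    assert traces[0] == traces[1]  # bit-identical (dt, reaction) pairs


def test_pure_death_terminates_quiescent_at_zero():
    from compartsim.fixtures import pure_death
    model = load_model(pure_death(n0=100, d=1.0))
    traj = run(model, SimConfig(t_end=100.0, seed=2, interval=10.0))
    assert traj.n_regular == 100
    assert traj.column("nA")[-1] == 0.0
    assert traj.times[-1] == 100.0  # grid filled to t_end after quiescence
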