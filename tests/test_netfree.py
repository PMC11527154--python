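"""Network-free attribute stores: eligibility, firing, lock-step."""

import numpy as np
import pytest
from scipy import stats

from compartsim.dsl.typecheck import load_model
from compartsim.dynamics import SimConfig, run
from compartsim.matcher import enumerate_reactions
from compartsim.netfree import choose_and_remove, eligible_count
from compartsim.ssa import FlatSimulator, SimClock
from compartsim.state import build_initial_state, tree_to_flat


def test_empty_store_has_zero_eligible():
    assert eligible_count([], lambda t: True) == 0


def test_threshold_constraint_counts_matching_instances():
    store = [(50.0,), (150.0,), (200.0,)]
    assert eligible_count(store, lambda t: t[0] > 100) == 2
    assert eligible_count(store, None) == 3


@pytest.mark.parametrize("seed", range(20))
def test_eligible_count_equals_brute_force_filter(seed):
    rng = np.random.default_rng(seed)
    store = [tuple(rng.integers(0, 10, 2)) for _ in range(rng.integers(0, 30))]

    def pred(t):
        return t[0] > 4 and t[1] <= 7

    assert eligible_count(store, pred) == len([t for t in store if pred(t)])


def test_single_eligible_instance_deterministically_chosen():
    rng = np.random.default_rng(0)
    store = [(1.0,), (99.0,), (2.0,)]
    got = choose_and_remove(store, lambda t: t[0] > 50, rng)
    assert got == (99.0,)
    assert len(store) == 2


def test_uniform_choice_among_equally_eligible():
    """10^5 draws over 4 eligible instances are uniform (chi-square)."""
    rng = np.random.default_rng(7)
    counts = np.zeros(4)
    for _ in range(100_000):
        store = [(0, 0), (1, 0), (2, 0), (3, 0)]
        t = choose_and_remove(store, None, rng)
        counts[t[0]] += 1
    chi2 = ((counts - 25_000.0) ** 2 / 25_000.0).sum()
    assert chi2 < stats.chi2.ppf(0.99, df=3)


def test_rhs_update_on_chosen_instance():
    """S(a1=7) fired through a1 = S.a1 + 1 yields an instance with 8."""
    text = """
    species S(a1: nf_int);
    init 1 S(a1=7);
    S:s -> S(a1=S.a1+1) @ 1*#s;
    """
    model = load_model(text)
    rng = np.random.default_rng(1)
    tree = build_initial_state(model, rng)
    flat = tree_to_flat(tree)
    sim = FlatSimulator(enumerate_reactions(model, flat), rng)
    sim.run(SimClock(0.0, rng), 1e9, max_steps=1)
    store = next(iter(flat.nf_stores.values()))
    assert store == [(8,)]


def test_store_stays_in_lock_step_with_counts():
    text = """
    const kb: 4; const kd: 1;
    species S(x: nf_real);
    init 3 S(x=unif(0,1));
    -> S(x=unif(0,1)) @ kb;
    S:a -> @ kd*#a;
    observe nS: S;
    """
    model = load_model(text)
    rng = np.random.default_rng(3)
    tree = build_initial_state(model, rng)
    flat = tree_to_flat(tree)
    sim = FlatSimulator(enumerate_reactions(model, flat), rng)
    sim.run(SimClock(0.0, rng), 1e9, max_steps=500)
    (key, slot), = [(k, s) for k, s in flat.slot_of.items()]
    assert len(flat.nf_stores.get(key, [])) == int(flat.C[slot])


def test_constrained_rate_semantics_exact_not_rejection():
    """Propensity of an nf-constrained rule equals rate x eligible
    count, tracked incrementally."""
    text = """
    species S(x: nf_int);
    init 2 S(x=1) + 3 S(x=5);
    S(x>3):a -> @ 0.5*#a;
    """
    model = load_model(text)
    rng = np.random.default_rng(0)
    flat = tree_to_flat(build_initial_state(model, rng))
    sim = FlatSimulator(enumerate_reactions(model, flat), rng)
    assert sim.tree.total == pytest.approx(0.5 * 3)
    sim.run(SimClock(0.0, rng), 1e9, max_steps=1)
    assert sim.tree.total == pytest.approx(0.5 * 2)


def test_netfree_vs_enumerated_quick_equivalence():
    """Shortened two-sample check; the full KS comparison runs in the
    acceptance suite."""
    from compartsim.fixtures import netfree_pair
    nf_text, enum_text = netfree_pair()
    finals = {}
    for label, text in (("nf", nf_text), ("enum", enum_text)):
        model = load_model(text)
        vals = [run(model, SimConfig(t_end=4.0, seed=17), rep)
                .column("active")[-1] for rep in range(120)]
        finals[label] = vals
    p = stats.ks_2samp(finals["nf"], finals["enum"]).pvalue
    assert p > 0.01
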