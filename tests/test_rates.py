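"""Rate evaluation and performance templates: interpreter agreement,
shape-keyed caching, zero recompilation across rebuilds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from compartsim import rates as R
from compartsim.dsl.typecheck import load_model
from compartsim.dynamics import SimConfig, run


class _Env(R.Env):
    def __init__(self, C=(), A=()):
        self.C = list(C)
        self.A = list(A)


def test_arithmetic_and_count():
    # dM * #m with dM = 0.1/s and #m = 5 -> 0.5/s
    e = R.B("*", R.Lit(0.1), R.CountSlot(0))
    assert R.interpret(e, _Env(C=[5.0])) == pytest.approx(0.5)


def test_conditional_on_attribute():
    e = R.Cond(R.B(">", R.AttrSlot(0), R.Lit(100.0)), R.Lit(7.0), R.Lit(0.0))
    assert R.interpret(e, _Env(A=[150.0])) == 7.0
    assert R.interpret(e, _Env(A=[50.0])) == 0.0


def test_hill_half_saturation():
    e = R.Fn("hill", (R.Lit(3.0), R.Lit(3.0), R.Lit(4.0)))
    assert R.interpret(e, _Env()) == pytest.approx(0.5)


def test_division_by_zero_reported():
    e = R.B("/", R.Lit(1.0), R.Lit(0.0))
    with pytest.raises(R.EvalError):
        R.interpret(e, _Env())


def test_cache_miss_then_hit_and_shared_shape():
    cache = R.TemplateCache()
    e1 = R.B("*", R.Lit(0.5), R.CountSlot(3))
    e2 = R.B("*", R.Lit(2.5), R.CountSlot(7))  # same shape, new parameters
    t1, p1 = cache.get_or_compile(e1)
    t2, p2 = cache.get_or_compile(e2)
    assert cache.compilations == 1 and cache.hits == 1
    assert t1 is t2
    assert p1 != p2
    C = [0.0] * 8
    C[3], C[7] = 4.0, 4.0
    assert t1.fn(p1, C, [], None) == pytest.approx(2.0)
    assert t2.fn(p2, C, [], None) == pytest.approx(10.0)


# random bound-expression generator ----------------------------------------

leaf = st.one_of(
    st.floats(min_value=0.1, max_value=20.0).map(lambda v: R.Lit(round(v, 3))),
    st.integers(0, 4).map(R.CountSlot),
    st.integers(0, 2).map(R.AttrSlot),
)


def exprs(depth=3):
    if depth == 0:
        return leaf
    sub = exprs(depth - 1)
    return st.one_of(
        leaf,
        st.tuples(st.sampled_from("+-*/"), sub, sub).map(
            lambda t: R.B(t[0], t[1], t[2])),
        st.tuples(sub, sub, sub).map(
            lambda t: R.Cond(R.B("<", t[0], t[1]), t[1], t[2])),
        st.tuples(sub, sub).map(lambda t: R.Fn("min", (t[0], t[1]))),
        st.tuples(sub, sub).map(lambda t: R.Fn("max", (t[0], t[1]))),
        sub.map(lambda x: R.U("-", x)),
        st.tuples(sub, sub, sub).map(
            lambda t: R.Fn("hill", (t[0], t[1], R.Lit(2.0)))),
    )


@settings(max_examples=1000, deadline=None)
@given(exprs(), st.integers(0, 10 ** 6))
def test_template_matches_interpreter(e, state_seed):
    """Compiled templates agree with the interpreter to 1e-12 relative."""
    rng = np.random.default_rng(state_seed)
    env = _Env(C=rng.uniform(0, 50, 5).tolist(),
               A=rng.uniform(0, 50, 3).tolist())
    cache = R.TemplateCache()
    tmpl, params = cache.get_or_compile(e)
    try:
        want = R.interpret(e, env)
    except R.EvalError:
        with pytest.raises(ZeroDivisionError):
            tmpl.fn(params, env.C, env.A, None)
        return
    got = tmpl.fn(params, env.C, env.A, None)
    assert got == pytest.approx(want, rel=1e-12, abs=1e-300)


def test_sampler_not_compilable():
    cache = R.TemplateCache()
    with pytest.raises(R.EvalError):
        cache.get_or_compile(R.Fn("norm", (R.Lit(1.0), R.Lit(0.1))))


def test_rebuilds_reuse_templates():
    """After the first build, later rebuilds of an unchanged rule set
    compile nothing new (content-addressed cache)."""
    text = """
    const kf: 1;
    const kd: 0.5;
    species C(); species X();
    init 1 C{ 6 X };
    C{?a+?b} -> C{?a} + C{?b} @ kf;
    X:x -> @ kd*#x;
    observe nC: C;
    """
    model = load_model(text)
    import numpy as np
    from compartsim import rates
    from compartsim.matcher import enumerate_reactions
    from compartsim.state import build_initial_state, tree_to_flat

    rng = np.random.default_rng(0)
    tree = build_initial_state(model, rng)
    cache = rates.TemplateCache()
    flat = tree_to_flat(tree)
    enumerate_reactions(model, flat, cache)
    before = cache.compilations
    enumerate_reactions(model, tree_to_flat(tree), cache)
    assert cache.compilations == before


def test_full_run_uses_one_cache_across_rebuilds():
    text = """
    const kf: 2;
    species C();
    init 1 C{};
    C{?a+?b} -> C{?a} + C{?b} @ kf;
    observe nC: C;
    """
    model = load_model(text)
    traj = run(model, SimConfig(t_end=1.2, seed=3))
    assert traj.n_structural >= 1
    assert traj.n_builds == traj.n_structural + 1
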