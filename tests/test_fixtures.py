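"""Bundled models and the synthetic generator."""

import numpy as np
import pytest

from compartsim.dsl.parser import parse
from compartsim.dsl.typecheck import load_model
from compartsim.dynamics import SimConfig, run
from compartsim.fixtures import (SyntheticModelSpec, case_studies,
                                 generate_model, mrna_delivery_config,
                                 toy_models)
from compartsim.state import build_initial_state


def test_all_toys_load_and_run_briefly():
    for name, text in toy_models().items():
        model = load_model(text)
        traj = run(model, SimConfig(t_end=0.5, seed=1))
        assert traj.n_builds >= 1, name


def test_generator_is_deterministic():
    spec = SyntheticModelSpec(seed=42, n_species=4, n_rules=7,
                              n_compartment_types=1, frac_structural=0.3)
    assert generate_model(spec) == generate_model(spec)


def test_fraction_structural_zero_yields_no_structural_rules():
    spec = SyntheticModelSpec(seed=3, n_species=3, n_rules=8,
                              n_compartment_types=1, frac_structural=0.0)
    model = load_model(generate_model(spec))
    assert all(r.kind == "regular" for r in model.rules)


@pytest.mark.parametrize("seed", range(60))
def test_random_specs_parse_typecheck_and_run(seed):
    spec = SyntheticModelSpec(
        seed=seed,
        n_species=2 + seed % 4,
        n_rules=4 + seed % 6,
        n_compartment_types=seed % 3,
        nesting_depth=1 + seed % 3,
        frac_structural=0.3 * (seed % 2),
        enum_domain=(seed // 2) % 3,
    )
    model = load_model(generate_model(spec))
    traj = run(model, SimConfig(t_end=1.0, seed=seed))
    assert traj.times[-1] == 1.0


def test_language_feature_coverage_matrix():
    """Every language feature appears in at least one bundled model."""
    corpus = list(toy_models().values()) + list(case_studies().values())
    asts = [parse(t) for t in corpus]

    def any_rule(pred):
        return any(pred(r) for a in asts for r in a.rules)

    def walk(p):
        for el in p:
            yield el
            if getattr(el, "content", None):
                yield from walk(el.content)

    from compartsim.dsl.syntax import PatternNode, SeqVar
    elems = [el for a in asts for r in a.rules
             for el in walk(r.lhs + r.rhs)]
    attrs = [c for el in elems if isinstance(el, PatternNode)
             for c in el.attrs]
    decls = [ad for a in asts for sd in a.species for ad in sd.attributes]

    assert any(c.op in ("<", ">", "<=", ">=") for c in attrs)  # comparisons
    assert any(c.op == "=" for c in attrs)                     # named updates
    assert any(ad.kind == "enum" for ad in decls)              # enums
    assert any(ad.kind in ("nf_int", "nf_real") for ad in decls)  # nf
    assert any(ad.unit_text or False for ad in decls) or \
        any(c.expr and "unit" for c in attrs)  # units appear in constants:
    assert any("/ h" in t or "/ min" in t or "/ s" in t for t in corpus)
    assert any(isinstance(el, SeqVar) and el.weight is not None
               for el in elems)                                # split weights
    # nesting depth >= 3 somewhere (Cell{E{L{...}}})
    def depth(p, d=0):
        best = d
        for el in p:
            if getattr(el, "content", None):
                best = max(best, depth(el.content, d + 1))
        return best
    assert max(depth(r.lhs) for a in asts for r in a.rules) >= 2


def test_yeast_transcription_declares_published_structure():
    model = load_model(case_studies()["yeast"])
    assert len([s for s in model.species if s.name != "$root"]) == 7
    assert len(model.rules) == 20
    division = [r for r in model.rules if r.kind == "structural"]
    assert len(division) == 1  # only cell division changes the tree


def test_mrna_transcription_declares_published_structure():
    model = load_model(case_studies()["mrna_delivery"])
    assert len([s for s in model.species if s.name != "$root"]) == 8
    assert len(model.rules) == 12
    tree = build_initial_state(model, np.random.default_rng(0))
    assert tree.compartment_count() == 201  # 1 cell + 200 lipoplexes


def test_mrna_unpack_rule_is_the_printed_form():
    text = case_studies()["mrna_delivery"]
    flat = "".join(text.split())
    assert "Cell{L{?sl}+?c}->Cell{?sl+?c}@kU;" in flat


def test_mrna_config_includes_washing_event():
    cfg = mrna_delivery_config(t_end_hours=2.0, seed=1)
    assert cfg.events[0].time == 3600.0
    assert cfg.events[0].species == "L"
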