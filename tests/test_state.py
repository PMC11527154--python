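"""State tree construction, flattening and exact reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from compartsim.dsl.typecheck import load_model
from compartsim.model import ModelError
from compartsim.state import (CompartmentNode, StateTree, VariantTable,
                              build_initial_state, flat_to_tree, tree_to_flat)


def _tree(text, seed=0):
    model = load_model(text)
    return build_initial_state(model, np.random.default_rng(seed))


def test_simple_init_counts():
    tree = _tree("species A();\ninit 10 A;\n")
    sid = tree.model.species_by_name["A"].sid
    assert tree.root.pops == {(sid, ()): 10}
    assert tree.compartment_count() == 0


def test_constant_expression_count():
    tree = _tree("species A();\ninit (2+3) A;\n")
    sid = tree.model.species_by_name["A"].sid
    assert tree.root.pops[(sid, ())] == 5


def test_cell_plus_200_lipoplexes_gives_201_compartments():
    tree = _tree("species Cell(); species L(); species mRNA();\n"
                 "init 1 Cell{} + 200 L{ 3 mRNA };\n")
    assert tree.compartment_count() == 201


def test_negative_initial_count_rejected():
    with pytest.raises(ModelError, match="negative"):
        _tree("species A();\ninit (0-4) A;\n")


def test_per_copy_sampling_differs_between_instances():
    tree = _tree("species L(n: nf_int); species R();\n"
                 "init 20 L(n=norm(100, 15));\n", seed=5)
    sid = tree.model.species_by_name["L"].sid
    values = [t[0] for t in tree.root.nf[(sid, ())]]
    assert len(values) == 20
    assert len(set(values)) > 1  # independent draws per copy


def test_flatten_conserves_totals_and_reconstructs():
    text = """
    species Cell(vol: real); species Nuc(); species P(); species Q(x: int);
    init 2 Cell(vol=1.5){ 1 Nuc{ 4 P } + 3 Q(x=2) } + 7 P;
    """
    tree = _tree(text)
    n_entities = tree.total_noncompartment_entities()
    flat = tree_to_flat(tree)
    assert sum(flat.C) == n_entities
    back = flat_to_tree(flat)
    assert back.signature() == tree.signature()
    assert sorted(n.iid for n in back.root.walk()) == \
        sorted(n.iid for n in tree.root.walk())


def test_identical_cells_get_distinct_instances_shared_variants():
    tree = _tree("species Cell(); species A();\n init 2 Cell{ 3 A };\n")
    flat = tree_to_flat(tree)
    cells = [iid for iid, rec in flat.instances.items()
             if rec.species.name == "Cell"]
    assert len(cells) == 2
    # one shared variant id for A, two slots (one per instance)
    a_sid = tree.model.species_by_name["A"].sid
    vids = {vid for (iid, vid) in flat.slot_of
            if flat.variants.keys[vid][0] == a_sid}
    assert len(vids) == 1


def test_sibling_reordering_canonicalizes():
    text = "species C(); species A(); species B();\n" \
           "init 1 C{ 2 A + 1 B } + 1 C{ 1 B + 2 A };\n"
    tree = _tree(text)
    a, b = tree.root.children
    assert a.signature()[2:] == b.signature()[2:]  # same canonical content


# randomized round-trip oracle ---------------------------------------------

@st.composite
def random_trees(draw):
    from compartsim.model import Species, TypedModel
    sp_a = Species(1, "A", ())
    sp_b = Species(2, "B", ())
    sp_c = Species(3, "C", (), is_compartment=True)
    root_sp = Species(0, "$root", (), is_compartment=True)
    model = TypedModel([root_sp, sp_a, sp_b, sp_c],
                       {s.name: s for s in [root_sp, sp_a, sp_b, sp_c]},
                       {}, {}, [], [], [])
    tree = StateTree(CompartmentNode(0, root_sp, []), model)

    def fill(node, depth):
        node.pops = {}
        for sp in (sp_a, sp_b):
            n = draw(st.integers(0, 5))
            if n:
                node.pops[(sp.sid, ())] = n
        if depth < 3:
            for _ in range(draw(st.integers(0, 2))):
                child = tree.new_node(sp_c, [], node)
                fill(child, depth + 1)

    fill(tree.root, 0)
    return tree


@settings(max_examples=100, deadline=None)
@given(random_trees())
def test_random_round_trip_isomorphic(tree):
    flat = tree_to_flat(tree)
    back = flat_to_tree(flat)
    assert back.signature() == tree.signature()
    assert back.next_iid == tree.next_iid
    # conservation of the (path-grouped) multiset
    assert back.total_noncompartment_entities() == \
        tree.total_noncompartment_entities()


def test_attribute_values_bit_exact_through_round_trip():
    tree = _tree("species C(v: real); \ninit 1 C(v=0.1){} + 1 C(v=0.3){};\n")
    flat = tree_to_flat(tree)
    back = flat_to_tree(flat)
    vals = sorted(c.attrs[0] for c in back.root.children)
    assert vals == sorted(c.attrs[0] for c in tree.root.children)
    assert vals[0] == 0.1  # exact, no rescaling noise


def test_shared_variant_table_across_flattenings():
    tree = _tree("species A();\ninit 2 A;\n")
    table = VariantTable()
    f1 = tree_to_flat(tree, table)
    f2 = tree_to_flat(tree, table)
    assert f1.variants is f2.variants
    assert len(table) == 1
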