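"""Surface-syntax parsing: printed-rule forms, round trips, errors."""

import pytest
from hypothesis import given, settings, strategies as st

from compartsim.dsl.parser import ParseError, parse
from compartsim.dsl.syntax import (BinOp, CountRef, Name, PatternNode,
                                   SeqVar, pretty_print)

# Rule forms the language must accept (named-attribute updates,
# comparison constraints, nested contents, sequence variables with
# weights, population bindings, compact endocytosis).
GOLDEN_RULES = [
    'S()->S(a1=S.a1+1) @ k;',
    'Cell(phase==1)->Cell(phase=2) @ k;',
    'Cell(vol>100,phase=="M")->Cell(phase="G1") @ k1;',
    'C(?c1+?c2)->C(?c1)+C(?c2) @ k;',
    'Mito(?m1[R1]+?m2[R2])->Mito(?m1)+Mito(?m2) @ k;',
    'Cell(Nucleus(?n)+Protein+?c)->Cell(Nucleus(Protein+?n)+?c) @ k;',
    'Cell{L{?solL}+?solC}->Cell{?solL+?solC}@kU;',
    'Cell{L+?solC}->Cell{(L.NmRNA)mRNA+?solC}@kU;',
    'Cell{E{L{?solL}+?solE}+?solC}->Cell{E{?solL+?solE}+?solC}@kU;',
    'E{mRNA:m+?solE}->E{?solE}@dM*#m;',
    # repaired form (the source prints it with an unbalanced brace)
    'Cell{?solC}+P{?solP}->Cell{E{?solP}+?solC} @ k;',
]


@pytest.mark.parametrize("text", GOLDEN_RULES)
def test_printed_rule_forms_parse(text):
    ast = parse(text)
    assert len(ast.rules) == 1
    rule = ast.rules[0]
    assert rule.lhs and rule.rhs


def test_attribute_update_rule_shape():
    rule = parse("S()->S(a1=S.a1+1) @ k;").rules[0]
    (lhs,), (rhs,) = rule.lhs, rule.rhs
    assert lhs.species == "S" and lhs.attrs == () and lhs.content is None
    assert rhs.attrs[0].name == "a1" and rhs.attrs[0].op == "="


def test_nested_rule_with_sequence_variables():
    rule = parse("Cell{L{?solL}+?solC}->Cell{?solL+?solC}@kU;").rules[0]
    cell = rule.lhs[0]
    assert isinstance(cell, PatternNode) and cell.species == "Cell"
    inner = cell.content
    assert isinstance(inner[0], PatternNode) and inner[0].species == "L"
    assert isinstance(inner[1], SeqVar) and inner[1].name == "solC"
    assert isinstance(rule.rate, Name) and rule.rate.ident == "kU"


def test_population_binding_and_count_rate():
    rule = parse("E{mRNA:m+?solE}->E{?solE}@dM*#m;").rules[0]
    mrna = rule.lhs[0].content[0]
    assert mrna.bind == "m"
    assert isinstance(rule.rate, BinOp)
    assert isinstance(rule.rate.right, CountRef)
    assert rule.rate.right.var == "m"


def test_split_weights_parse():
    rule = parse("Mito(?m1[R1]+?m2[R2])->Mito(?m1)+Mito(?m2)@k;").rules[0]
    sv1, sv2 = rule.lhs[0].content
    assert sv1.weight is not None and sv2.weight is not None


def test_declarations_without_rules():
    ast = parse("species A();\nconst k: 2;\ninit 3 A;\n")
    assert ast.rules == ()
    assert len(ast.species) == 1 and len(ast.constants) == 1


def test_syntax_error_carries_position():
    with pytest.raises(ParseError) as err:
        parse("species A(;\n")
    assert err.value.line == 1
    assert err.value.col > 0


def test_comments_and_curly_quotes():
    ast = parse('// a comment\nCell(phase==“M”)->Cell(phase="G1")@k;\n')
    assert len(ast.rules) == 1


MODELS = [
    "const k: 0.5;\nspecies A();\ninit 10 A;\nA:a -> @ k*#a;\nobserve nA: A;\n",
    "species C(); species X();\ninit 1 C{ 5 X };\n"
    "C{?a+?b} -> C{?a} + C{?b} @ 2;\n",
    'species S(x: enum {u v});\ninit 4 S(x="u");\n'
    'S(x=="u"):a -> S(x="v") @ 1.5*#a;\n',
    "const k1: 0.1 / s;\nspecies A();\ninit (2+3) A;\n-> A @ k1;\n",
]


@pytest.mark.parametrize("text", MODELS)
def test_pretty_print_round_trip(text):
    ast = parse(text)
    printed = pretty_print(ast)
    assert parse(printed) == ast


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 10 ** 6))
def test_generated_models_round_trip(seed):
    from compartsim.fixtures import SyntheticModelSpec, generate_model
    text = generate_model(SyntheticModelSpec(
        seed=seed, n_species=3, n_rules=5, enum_domain=seed % 3,
        n_compartment_types=seed % 2, frac_structural=0.4 * (seed % 2)))
    ast = parse(text)
    assert parse(pretty_print(ast)) == ast
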