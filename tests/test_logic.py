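"""Expression parsing, evaluation, substitution and canonical forms."""

import pytest
from hypothesis import given, settings, strategies as st

from lglnet.logic import (
    And,
    Const,
    Not,
    Or,
    ParseError,
    Var,
    dnf_clauses,
    clauses_to_expr,
    evaluate,
    negate_rule,
    parse_expression,
    substitute_simplify,
    to_canonical,
    truth_table_equal,
    variables,
    write_expression,
)

DISC_RULE = "(Ceramide OR (Fas AND NOT FLIP)) AND NOT Apoptosis"
VOCAB = {"Ceramide", "Fas", "FLIP", "Apoptosis", "S1P", "DISC", "Stimuli", "CTLA4", "A", "B", "C"}


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def test_parse_negated_disjunction_structure():
    expr = parse_expression("NOT (Ceramide OR Apoptosis)", VOCAB)
    assert expr == Not(Or((Var("Ceramide"), Var("Apoptosis"))))


def test_parse_single_variable_identity():
    assert parse_expression("A", {"A"}) == Var("A")


def test_parse_disc_rule_truth_table():
    expr = parse_expression(DISC_RULE, VOCAB)
    assert variables(expr) == {"Ceramide", "Fas", "FLIP", "Apoptosis"}
    for bits in range(16):
        asg = {
            "Ceramide": bits & 1,
            "Fas": (bits >> 1) & 1,
            "FLIP": (bits >> 2) & 1,
            "Apoptosis": (bits >> 3) & 1,
        }
        direct = int(
            (asg["Ceramide"] or (asg["Fas"] and not asg["FLIP"]))
            and not asg["Apoptosis"]
        )
        assert evaluate(expr, asg) == direct


def test_parse_precedence_not_over_and_over_or():
    # NOT binds tightest, then AND, then OR
    expr = parse_expression("NOT A AND B OR C", {"A", "B", "C"})
    assert expr == Or((And((Not(Var("A")), Var("B"))), Var("C")))


@pytest.mark.parametrize(
    "text, fragment",
    [
        ("Ceramide OR Unknown", "Unknown"),
        ("(Ceramide OR Fas", "unbalanced"),
        ("Ceramide OR", "end of expression"),
        ("", "empty"),
        ("Ceramide Fas", "trailing"),
    ],
)
def test_parse_errors(text, fragment):
    with pytest.raises(ParseError, match=fragment):
        parse_expression(text, VOCAB)


def test_keywords_case_insensitive():
    a = parse_expression("not (A and B) or C", {"A", "B", "C"})
    b = parse_expression("NOT (A AND B) OR C", {"A", "B", "C"})
    assert truth_table_equal(a, b)


# ---------------------------------------------------------------------------
# Evaluation and substitution
# ---------------------------------------------------------------------------

def test_evaluate_examples():
    disc = parse_expression(DISC_RULE, VOCAB)
    assert evaluate(disc, {"Ceramide": 0, "Fas": 1, "FLIP": 1, "Apoptosis": 0}) == 0
    assert evaluate(Const(1), {}) == 1
    apop = parse_expression("DISC OR Apoptosis", VOCAB)
    assert evaluate(apop, {"DISC": 0, "Apoptosis": 1}) == 1


def test_evaluate_missing_variable():
    with pytest.raises(KeyError, match="Fas"):
        evaluate(parse_expression("Fas", VOCAB), {})


def test_substitute_examples():
    tcr = parse_expression("Stimuli AND NOT CTLA4", VOCAB)
    assert substitute_simplify(tcr, {"Stimuli": 1}) == Not(Var("CTLA4"))
    assert substitute_simplify(parse_expression("A AND NOT A", VOCAB), {}) == Const(0)
    disc = parse_expression(DISC_RULE, VOCAB)
    assert substitute_simplify(disc, {"Apoptosis": 1}) == Const(0)


# ---------------------------------------------------------------------------
# Canonical OR-of-ANDs form
# ---------------------------------------------------------------------------

def _clauses(rule):
    return {frozenset(c) for c in rule.clauses}


def test_to_canonical_examples():
    r = to_canonical(parse_expression("(A AND B) OR C", VOCAB))
    assert _clauses(r) == {
        frozenset({("A", True), ("B", True)}),
        frozenset({("C", True)}),
    }
    r = to_canonical(parse_expression("NOT (A OR B)", VOCAB))
    assert _clauses(r) == {frozenset({("A", False), ("B", False)})}
    r = to_canonical(parse_expression(DISC_RULE, VOCAB))
    assert _clauses(r) == {
        frozenset({("Ceramide", True), ("Apoptosis", False)}),
        frozenset({("Fas", True), ("FLIP", False), ("Apoptosis", False)}),
    }


def test_to_canonical_applies_absorption():
    r = to_canonical(parse_expression("A OR (A AND B)", VOCAB))
    assert _clauses(r) == {frozenset({("A", True)})}


def test_to_canonical_rejects_constants():
    with pytest.raises(ValueError):
        to_canonical(parse_expression("A AND NOT A", VOCAB))
    with pytest.raises(ValueError):
        to_canonical(Const(1))


def test_negate_rule_examples():
    r = to_canonical(parse_expression("A", VOCAB))
    assert _clauses(negate_rule(r)) == {frozenset({("A", False)})}
    r = to_canonical(parse_expression("A AND B", VOCAB))
    assert _clauses(negate_rule(r)) == {
        frozenset({("A", False)}),
        frozenset({("B", False)}),
    }
    disc = to_canonical(parse_expression(DISC_RULE, VOCAB))
    assert truth_table_equal(
        negate_rule(disc).to_expr(),
        Not(parse_expression(DISC_RULE, VOCAB)),
    )


# ---------------------------------------------------------------------------
# Property tests on random expressions
# ---------------------------------------------------------------------------

NAMES = ("A", "B", "C", "D")

exprs = st.recursive(
    st.sampled_from([Var(n) for n in NAMES] + [Const(0), Const(1)]),
    lambda sub: st.one_of(
        sub.map(Not),
        st.tuples(sub, sub).map(lambda t: And(t)),
        st.tuples(sub, sub).map(lambda t: Or(t)),
    ),
    max_leaves=12,
)


@given(exprs)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_write_parse_round_trip_preserves_semantics(expr):
    text = write_expression(expr)
    assert truth_table_equal(parse_expression(text, NAMES), expr)


@given(exprs)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_canonical_form_preserves_semantics(expr):
    assert truth_table_equal(clauses_to_expr(dnf_clauses(expr)), expr)


@given(exprs)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_double_negation_is_semantic_identity(expr):
    clauses = dnf_clauses(expr)
    if isinstance(clauses, Const):
        return
    rule = to_canonical(expr)
    try:
        double = negate_rule(negate_rule(rule))
    except ValueError:
        return  # negation collapsed to a constant (tautology/contradiction)
    assert truth_table_equal(double.to_expr(), expr)


@given(exprs, st.dictionaries(st.sampled_from(NAMES), st.integers(0, 1)))
@settings(max_examples=150, deadline=None, derandomize=True)
def test_substitution_is_idempotent_and_sound(expr, partial):
    once = substitute_simplify(expr, partial)
    assert variables(once).isdisjoint(partial)
    assert substitute_simplify(once, partial) == once
    # agrees with the original on every completion of the partial assignment
    rest = sorted(variables(expr) - set(partial))
    for bits in range(2 ** len(rest)):
        asg = {**partial, **{n: (bits >> i) & 1 for i, n in enumerate(rest)}}
        assert evaluate(once, asg) == evaluate(expr, asg)
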