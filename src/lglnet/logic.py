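"""Boolean expression trees, parsing, evaluation and canonical forms.

Rules of a logical network are propositional formulas over node names built
from AND, OR and NOT.  This module provides the expression substrate used by
every other part of the package:

* a small immutable AST (:class:`Var`, :class:`Const`, :class:`Not`,
  :class:`And`, :class:`Or`),
* a recursive-descent parser for the conventional rule dialect
  (``NOT (Ceramide OR Apoptosis)``), with precedence NOT > AND > OR,
* evaluation and partial substitution with simplification,
* a deterministic canonical OR-of-ANDs (disjunctive normal) form with
  complement elimination and absorption, on which network expansion and
  rule negation are built.

Simplification is deliberately limited to constant propagation, idempotence,
complement laws and absorption; no full minimisation is attempted, which
keeps canonical forms deterministic and cheap for the small per-node rules
found in signaling models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Union

__all__ = [
    "Expr",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "ParseError",
    "EvaluationError",
    "CanonicalRule",
    "parse_expression",
    "write_expression",
    "variables",
    "evaluate",
    "substitute_simplify",
    "to_canonical",
    "negate_rule",
    "clauses_to_expr",
    "dnf_clauses",
    "truth_table_equal",
]


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Var:
    name: str

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Var({self.name})"


@dataclass(frozen=True)
class Const:
    value: int  # 0 or 1

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"Boolean constant must be 0 or 1, got {self.value!r}")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Const({self.value})"


@dataclass(frozen=True)
class Not:
    operand: "Expr"


@dataclass(frozen=True)
class And:
    args: tuple["Expr", ...]

    def __post_init__(self) -> None:
        if len(self.args) < 2:
            raise ValueError("And requires at least two operands")


@dataclass(frozen=True)
class Or:
    args: tuple["Expr", ...]

    def __post_init__(self) -> None:
        if len(self.args) < 2:
            raise ValueError("Or requires at least two operands")


Expr = Union[Var, Const, Not, And, Or]

#: literal = (node name, polarity); polarity True means the plain variable,
#: False the negated one.
Literal = tuple[str, bool]
Clause = frozenset  # frozenset[Literal]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    """Raised for malformed rule text; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


_KEYWORDS = {"AND", "OR", "NOT"}
_CONSTS = {"0": 0, "1": 1, "TRUE": 1, "FALSE": 0}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append(("paren", c, i))
            i += 1
            continue
        if c.isalnum() or c == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            word = text[i:j]
            upper = word.upper()
            if upper in _KEYWORDS:
                tokens.append(("kw", upper, i))
            elif upper in _CONSTS:
                tokens.append(("const", str(_CONSTS[upper]), i))
            else:
                tokens.append(("name", word, i))
            i = j
            continue
        raise ParseError(f"unexpected character {c!r}", i)
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]], vocabulary: Iterable[str] | None):
        self.tokens = tokens
        self.pos = 0
        self.vocabulary = None if vocabulary is None else frozenset(vocabulary)

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse_or(self) -> Expr:
        args = [self.parse_and()]
        while (tok := self.peek()) is not None and tok[:2] == ("kw", "OR"):
            self.next()
            args.append(self.parse_and())
        return args[0] if len(args) == 1 else Or(tuple(args))

    def parse_and(self) -> Expr:
        args = [self.parse_not()]
        while (tok := self.peek()) is not None and tok[:2] == ("kw", "AND"):
            self.next()
            args.append(self.parse_not())
        return args[0] if len(args) == 1 else And(tuple(args))

    def parse_not(self) -> Expr:
        tok = self.peek()
        if tok is not None and tok[:2] == ("kw", "NOT"):
            self.next()
            return Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> Expr:
        kind, value, pos = self.next()
        if kind == "paren" and value == "(":
            inner = self.parse_or()
            tok = self.peek()
            if tok is None or tok[:2] != ("paren", ")"):
                raise ParseError("unbalanced parentheses: expected ')'", pos)
            self.next()
            return inner
        if kind == "const":
            return Const(int(value))
        if kind == "name":
            if self.vocabulary is not None and value not in self.vocabulary:
                raise ParseError(f"undeclared name {value!r}", pos)
            return Var(value)
        raise ParseError(f"unexpected token {value!r}", pos)


def parse_expression(text: str, vocabulary: Iterable[str] | None = None) -> Expr:
    """Parse a rule expression.

    ``vocabulary``, when given, is the set of declared node names; any other
    name raises :class:`ParseError` naming the token.  Keywords are
    case-insensitive, precedence is NOT > AND > OR, parentheses override.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ParseError("empty expression")
    parser = _Parser(tokens, vocabulary)
    expr = parser.parse_or()
    if (tok := parser.peek()) is not None:
        if tok[0] == "paren" and tok[1] == ")":
            raise ParseError("unbalanced parentheses: unmatched ')'", tok[2])
        raise ParseError(f"trailing input {tok[1]!r}", tok[2])
    return expr


def write_expression(expr: Expr) -> str:
    """Render an expression in the rule dialect; round-trips through the parser."""
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Const):
        return str(expr.value)
    if isinstance(expr, Not):
        inner = write_expression(expr.operand)
        if isinstance(expr.operand, (And, Or)):
            inner = f"({inner})"
        return f"NOT {inner}"
    if isinstance(expr, And):
        parts = [
            f"({write_expression(a)})" if isinstance(a, Or) else write_expression(a)
            for a in expr.args
        ]
        return " AND ".join(parts)
    if isinstance(expr, Or):
        return " OR ".join(write_expression(a) for a in expr.args)
    raise TypeError(f"not an expression: {expr!r}")


# ---------------------------------------------------------------------------
# Evaluation and substitution
# ---------------------------------------------------------------------------

class EvaluationError(KeyError):
    pass


def variables(expr: Expr) -> frozenset[str]:
    """The set of node names appearing in ``expr``."""
    out: set[str] = set()
    stack: list[Expr] = [expr]
    while stack:
        e = stack.pop()
        if isinstance(e, Var):
            out.add(e.name)
        elif isinstance(e, Not):
            stack.append(e.operand)
        elif isinstance(e, (And, Or)):
            stack.extend(e.args)
    return frozenset(out)


def evaluate(expr: Expr, assignment: Mapping[str, int]) -> int:
    """Evaluate under a total assignment of the expression's variables."""
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Var):
        try:
            return 1 if assignment[expr.name] else 0
        except KeyError:
            raise EvaluationError(f"no value for variable {expr.name!r}") from None
    if isinstance(expr, Not):
        return 1 - evaluate(expr.operand, assignment)
    if isinstance(expr, And):
        for a in expr.args:
            if not evaluate(a, assignment):
                return 0
        return 1
    if isinstance(expr, Or):
        for a in expr.args:
            if evaluate(a, assignment):
                return 1
        return 0
    raise TypeError(f"not an expression: {expr!r}")


def _substitute(expr: Expr, partial: Mapping[str, int]) -> Expr:
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Var):
        if expr.name in partial:
            return Const(1 if partial[expr.name] else 0)
        return expr
    if isinstance(expr, Not):
        return Not(_substitute(expr.operand, partial))
    if isinstance(expr, And):
        return And(tuple(_substitute(a, partial) for a in expr.args))
    if isinstance(expr, Or):
        return Or(tuple(_substitute(a, partial) for a in expr.args))
    raise TypeError(f"not an expression: {expr!r}")


def substitute_simplify(expr: Expr, partial: Mapping[str, int]) -> Expr:
    """Substitute a partial assignment and simplify.

    The result contains none of the substituted variables, agrees with the
    original on every completion of ``partial``, and collapses to a
    :class:`Const` whenever the substitution determines the value.  The
    operation is idempotent for a fixed partial assignment.
    """
    clauses = dnf_clauses(_substitute(expr, partial))
    return clauses_to_expr(clauses)


# ---------------------------------------------------------------------------
# Canonical OR-of-ANDs form
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CanonicalRule:
    """A rule in canonical OR-of-ANDs form.

    ``clauses`` is a tuple of AND-clauses; each clause a tuple of literals
    ``(name, polarity)`` with polarity ``True`` for the plain variable.
    Literals within a clause and the clauses themselves are sorted
    lexicographically, making the form deterministic.  No clause contains a
    literal together with its negation and no clause is a superset of
    another (absorption).
    """

    target: str | None
    clauses: tuple[tuple[Literal, ...], ...]

    def clause_sets(self) -> tuple[Clause, ...]:
        return tuple(frozenset(c) for c in self.clauses)

    def to_expr(self) -> Expr:
        return clauses_to_expr(frozenset(frozenset(c) for c in self.clauses))


def _nnf(expr: Expr, negate: bool) -> Expr:
    """Negation normal form with constant elimination."""
    if isinstance(expr, Const):
        return Const(1 - expr.value) if negate else expr
    if isinstance(expr, Var):
        return Not(expr) if negate else expr
    if isinstance(expr, Not):
        return _nnf(expr.operand, not negate)
    if isinstance(expr, And):
        args = tuple(_nnf(a, negate) for a in expr.args)
        return Or(args) if negate else And(args)
    if isinstance(expr, Or):
        args = tuple(_nnf(a, negate) for a in expr.args)
        return And(args) if negate else Or(args)
    raise TypeError(f"not an expression: {expr!r}")


def _dnf_sets(expr: Expr) -> set[Clause] | int:
    """DNF of an NNF expression as a set of clauses, or a constant 0/1."""
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Var):
        return {frozenset({(expr.name, True)})}
    if isinstance(expr, Not):
        assert isinstance(expr.operand, Var), "input must be in NNF"
        return {frozenset({(expr.operand.name, False)})}
    if isinstance(expr, Or):
        acc: set[Clause] = set()
        for a in expr.args:
            sub = _dnf_sets(a)
            if sub == 1:
                return 1
            if sub == 0:
                continue
            acc |= sub
        return acc if acc else 0
    if isinstance(expr, And):
        acc = {frozenset()}
        for a in expr.args:
            sub = _dnf_sets(a)
            if sub == 0:
                return 0
            if sub == 1:
                continue
            nxt: set[Clause] = set()
            for c1 in acc:
                for c2 in sub:
                    merged = c1 | c2
                    # complement law: drop clauses containing x and NOT x
                    if any((name, not pol) in merged for name, pol in c2):
                        continue
                    nxt.add(merged)
            if not nxt:
                return 0
            acc = nxt
        if frozenset() in acc:
            return 1
        return acc
    raise TypeError(f"not an expression: {expr!r}")


def _absorb(clauses: set[Clause]) -> set[Clause]:
    """Remove any clause that is a (proper) superset of another."""
    kept: set[Clause] = set()
    for c in sorted(clauses, key=len):
        if not any(k <= c for k in kept):
            kept.add(c)
    return kept


def dnf_clauses(expr: Expr) -> frozenset[Clause] | Const:
    """Canonical DNF clause sets of ``expr``, or a :class:`Const`."""
    res = _dnf_sets(_nnf(expr, negate=False))
    if isinstance(res, int):
        return Const(res)
    return frozenset(_absorb(res))


def _sorted_clauses(clauses: Iterable[Clause]) -> tuple[tuple[Literal, ...], ...]:
    def lit_key(lit: Literal) -> tuple[str, bool]:
        return (lit[0], not lit[1])  # plain literal before negated, by name

    sorted_each = [tuple(sorted(c, key=lit_key)) for c in clauses]
    return tuple(sorted(sorted_each))


def clauses_to_expr(clauses: frozenset[Clause] | Const) -> Expr:
    """Rebuild a (sorted, deterministic) expression from DNF clauses."""
    if isinstance(clauses, Const):
        return clauses
    terms: list[Expr] = []
    for clause in _sorted_clauses(clauses):
        lits: list[Expr] = [
            Var(name) if pol else Not(Var(name)) for name, pol in clause
        ]
        terms.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
    if not terms:
        return Const(0)
    return terms[0] if len(terms) == 1 else Or(tuple(terms))


def to_canonical(expr: Expr, target: str | None = None) -> CanonicalRule:
    """Canonical OR-of-ANDs form of a non-constant expression.

    Raises :class:`ValueError` for expressions that simplify to a constant;
    callers dealing with stabilized nodes must handle constants themselves.
    """
    clauses = dnf_clauses(expr)
    if isinstance(clauses, Const):
        raise ValueError(
            f"expression simplifies to the constant {clauses.value}; "
            "canonical clause form is defined for non-constant rules only"
        )
    return CanonicalRule(target=target, clauses=_sorted_clauses(clauses))


def negate_rule(rule: CanonicalRule) -> CanonicalRule:
    """Canonical form of the logical complement of ``rule``."""
    expr = Not(rule.to_expr())
    clauses = dnf_clauses(expr)
    if isinstance(clauses, Const):
        raise ValueError("negation simplifies to a constant")
    return CanonicalRule(target=rule.target, clauses=_sorted_clauses(clauses))


# ---------------------------------------------------------------------------
# Truth-table utilities (used throughout the test oracles as well)
# ---------------------------------------------------------------------------

def _assignments(names: tuple[str, ...]) -> Iterator[dict[str, int]]:
    for bits in range(2 ** len(names)):
        yield {name: (bits >> i) & 1 for i, name in enumerate(names)}

def truth_table_equal(a: Expr, b: Expr, max_vars: int = 16) -> bool:
    """Exhaustive semantic equality over the union of the two variable sets."""
    names = tuple(sorted(variables(a) | variables(b)))
    if len(names) > max_vars:
        raise ValueError(f"too many variables for exhaustive comparison: {len(names)}")
    return all(
        evaluate(a, asg) == evaluate(b, asg) for asg in _assignments(names)
    )
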