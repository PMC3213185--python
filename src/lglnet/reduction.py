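"""Network reduction: stabilization analysis and mediator-node elimination.

Two complementary reduction steps shrink a Boolean network without losing
its stationary behaviour:

1. **Logical steady state analysis** — iterative constant propagation from
   clamped inputs.  A node whose rule simplifies to a constant is
   *stabilized*: it holds that value in every attractor, independent of
   update order, and can be eliminated.

2. **Mediator elimination** — iterative removal of *simple mediator* nodes
   (no self-loop, and at most one regulator or at most one target) by
   substituting their rule into their targets.  Removal of non-self-
   regulating nodes preserves the fixed points of the network, so the
   reduced model's fixed points are exactly the projections of the full
   model's fixed points.

Both steps record a :class:`ReductionTrace` from which full-network fixed
points are reconstructed by back-substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .logic import (
    And,
    Const,
    Expr,
    Not,
    Or,
    Var,
    clauses_to_expr,
    dnf_clauses,
    evaluate,
    substitute_simplify,
    variables,
)
from .network import BooleanNetwork

__all__ = [
    "ReductionTrace",
    "ReductionError",
    "strip_apoptosis_clause",
    "logical_steady_state",
    "live_branch_steady_state",
    "remove_mediators",
    "remove_node_with_value",
    "reconstruct_full_attractor",
]


class ReductionError(ValueError):
    pass


@dataclass(frozen=True)
class ReductionTrace:
    """Replayable record of a reduction.

    ``inputs`` are the clamped values the reduction started from;
    ``stabilized`` maps each node that acquired a constant to
    ``(value, round)``; ``removed`` lists eliminated nodes in elimination
    order together with the rule each had at removal time (referencing only
    nodes still present then) and the removal kind (``"mediator"`` or
    ``"explicit"``); ``skipped`` records removal requests that were refused.
    """

    inputs: Mapping[str, int]
    stabilized: Mapping[str, tuple[int, int]]
    removed: tuple[tuple[str, Expr, str], ...]
    residual: BooleanNetwork
    skipped: tuple[str, ...] = ()

    @property
    def stabilized_values(self) -> dict[str, int]:
        return {n: v for n, (v, _) in self.stabilized.items()}

    def then(self, later: "ReductionTrace") -> "ReductionTrace":
        """Compose with a trace produced from this trace's residual."""
        stabilized = dict(self.stabilized)
        stabilized.update(later.stabilized)
        return ReductionTrace(
            inputs={**self.inputs, **later.inputs},
            stabilized=stabilized,
            removed=self.removed + later.removed,
            residual=later.residual,
            skipped=self.skipped + later.skipped,
        )


# ---------------------------------------------------------------------------
# Step 0: the death-clause convention
# ---------------------------------------------------------------------------

def strip_apoptosis_clause(
    network: BooleanNetwork, node: str = "Apoptosis"
) -> BooleanNetwork:
    """Remove the ``AND NOT Apoptosis`` clause from every other rule.

    Semantically this substitutes ``Apoptosis = 0`` inside all rules except
    the named node's own, restricting the model to the live-cell branch so
    that the stationary states of nodes in a cell that has not yet committed
    to death can be identified.  The node's own rule is untouched.
    """
    if node not in network.nodes:
        raise ReductionError(f"network has no node named {node!r}")
    rules = {}
    for name, expr in network.rules.items():
        if name == node:
            rules[name] = expr
        else:
            rules[name] = substitute_simplify(expr, {node: 0})
    return BooleanNetwork(network.nodes, rules, network.frozen)


# ---------------------------------------------------------------------------
# Step 1: logical steady state analysis
# ---------------------------------------------------------------------------

def logical_steady_state(
    network: BooleanNetwork, frozen: Mapping[str, int] | None = None
) -> ReductionTrace:
    """Iteratively propagate clamped constants until no rule stabilizes.

    ``frozen`` supplies values for sources beyond those already clamped in
    the network; a conflict with an existing clamp raises
    :class:`ReductionError`.  The residual network contains the
    non-stabilized nodes with fully simplified rules.  Stabilized values are
    independent of update order and hold in every attractor.
    """
    known: dict[str, int] = dict(network.frozen)
    for name, value in (frozen or {}).items():
        if name not in network.nodes:
            raise ReductionError(f"unknown node {name!r}")
        if name in known and known[name] != value:
            raise ReductionError(
                f"node {name!r} frozen to conflicting values {known[name]} and {value}"
            )
        known[name] = value

    inputs = dict(known)
    pending = {
        n: substitute_simplify(network.rules[n], known)
        for n in network.nodes
        if n in network.rules and n not in known
    }
    stabilized: dict[str, tuple[int, int]] = {}
    rnd = 0
    while True:
        rnd += 1
        newly = {
            n: e.value for n, e in pending.items() if isinstance(e, Const)
        }
        if not newly:
            break
        for n, v in newly.items():
            stabilized[n] = (v, rnd)
            known[n] = v
            del pending[n]
        pending = {n: substitute_simplify(e, newly) for n, e in pending.items()}

    keep = tuple(n for n in network.nodes if n not in known)
    residual = BooleanNetwork(
        keep,
        {n: pending[n] for n in keep if n in pending},
        {},
    )
    return ReductionTrace(
        inputs=inputs, stabilized=stabilized, removed=(), residual=residual
    )


def live_branch_steady_state(
    network: BooleanNetwork,
    frozen: Mapping[str, int] | None = None,
    output: str = "Apoptosis",
) -> ReductionTrace:
    """Steady state analysis of the live-cell branch.

    Runs :func:`logical_steady_state` on the network with the death clause
    stripped (``output = 0`` substituted into all other rules), then rebuilds
    the residual from the *original* rules with the stabilized constants
    substituted — so the residual keeps its ``AND NOT Apoptosis`` clauses and
    remains a faithful sub-model of the full network.
    """
    trace = logical_steady_state(strip_apoptosis_clause(network, output), frozen)
    known = {**trace.inputs, **trace.stabilized_values}
    residual = network.substituted(known)
    return replace(trace, residual=residual)


# ---------------------------------------------------------------------------
# Step 2: mediator elimination
# ---------------------------------------------------------------------------

def _replace_var(expr: Expr, name: str, replacement: Expr) -> Expr:
    if isinstance(expr, Var):
        return replacement if expr.name == name else expr
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Not):
        return Not(_replace_var(expr.operand, name, replacement))
    if isinstance(expr, And):
        return And(tuple(_replace_var(a, name, replacement) for a in expr.args))
    if isinstance(expr, Or):
        return Or(tuple(_replace_var(a, name, replacement) for a in expr.args))
    raise TypeError(f"not an expression: {expr!r}")


def _simplify(expr: Expr) -> Expr:
    return clauses_to_expr(dnf_clauses(expr))


def _supports(network: BooleanNetwork) -> dict[str, frozenset[str]]:
    return {n: variables(e) for n, e in network.rules.items()}


def _eligible(
    network: BooleanNetwork,
    supports: dict[str, frozenset[str]],
    name: str,
    protected: frozenset[str],
    criterion: str,
    ignored: frozenset[str],
) -> bool:
    if name not in network.rules or name in protected:
        return False
    support = supports[name]
    if name in support:  # self-loop
        return False
    in_deg = len(support - ignored)
    out_deg = sum(1 for t, s in supports.items() if t != name and name in s)
    if criterion == "and":
        return in_deg <= 1 and out_deg <= 1
    return in_deg <= 1 or out_deg <= 1


def _substitute_out(network: BooleanNetwork, name: str, value_expr: Expr) -> BooleanNetwork:
    rules = {}
    for t in network.nodes:
        if t == name or t not in network.rules:
            continue
        expr = network.rules[t]
        if name in variables(expr):
            expr = _simplify(_replace_var(expr, name, value_expr))
        rules[t] = expr
    nodes = tuple(n for n in network.nodes if n != name)
    frozen = {n: v for n, v in network.frozen.items() if n != name}
    return BooleanNetwork(nodes, rules, frozen)


def remove_mediators(
    network: BooleanNetwork,
    protected: Iterable[str] = (),
    order: Sequence[str] | None = None,
    only_listed: bool = False,
    criterion: str = "and",
    ignore_regulators: Iterable[str] = (),
) -> ReductionTrace:
    """Iteratively eliminate simple mediator nodes.

    A node is eligible when it has a rule, is not protected, does not
    regulate itself, and — with the default ``criterion="and"`` — has at
    most one regulator and at most one target (a simple mediator that only
    delays signal propagation).  ``criterion="or"`` relaxes this to at most
    one regulator *or* at most one target; any elimination of a
    non-self-regulating node preserves fixed points, so the relaxed rule is
    safe when a stronger reduction is needed.  ``ignore_regulators`` names
    nodes whose incoming influence is not counted toward in-degrees
    (typically a committed output such as Apoptosis whose inhibitory clause
    reaches every rule).

    Elimination substitutes the node's rule into its targets and
    re-simplifies.  ``order`` prioritises candidates (useful for
    reproducing a published elimination sequence); with ``only_listed=True``
    exactly the listed nodes are attempted and nothing else.  A listed node
    that turns out to be self-regulating or otherwise ineligible is skipped
    and recorded in the trace.  Constant rules must be eliminated
    beforehand (run :func:`logical_steady_state` first).
    """
    for n, e in network.rules.items():
        if isinstance(e, Const):
            raise ReductionError(
                f"rule of {n!r} is constant; run logical_steady_state first"
            )
    if criterion not in ("and", "or"):
        raise ValueError("criterion must be 'and' or 'or'")
    ignored = frozenset(ignore_regulators)
    protected_set = frozenset(protected)
    removed: list[tuple[str, Expr, str]] = []
    skipped: list[str] = []
    stabilized: dict[str, tuple[int, int]] = {}
    current = network

    def sweep_constants(net: BooleanNetwork) -> BooleanNetwork:
        # substitution may collapse downstream rules to constants (the
        # substituted steady relation resolves a lagged pair); fold these
        # into the stabilized set and propagate
        while True:
            consts = {
                n: e.value for n, e in net.rules.items() if isinstance(e, Const)
            }
            if not consts:
                return net
            for n, v in consts.items():
                stabilized[n] = (v, len(stabilized) + 1)
            net = net.substituted(consts)

    queue = list(order or ())
    while True:
        current = sweep_constants(current)
        supports = _supports(current)
        candidate = None
        while queue:
            name = queue.pop(0)
            if name not in current.nodes:
                skipped.append(name)
                continue
            if _eligible(current, supports, name, protected_set, criterion, ignored):
                candidate = name
                break
            skipped.append(name)
        if candidate is None and not only_listed:
            for name in current.nodes:
                if _eligible(current, supports, name, protected_set, criterion, ignored):
                    candidate = name
                    break
        if candidate is None:
            break
        rule = current.rules[candidate]
        removed.append((candidate, rule, "mediator"))
        current = _substitute_out(current, candidate, rule)

    return ReductionTrace(
        inputs={},
        stabilized=stabilized,
        removed=tuple(removed),
        residual=current,
        skipped=tuple(skipped),
    )


def remove_node_with_value(
    network: BooleanNetwork, name: str, value: int
) -> ReductionTrace:
    """Explicitly eliminate a node by substituting a constant for it.

    Intended for self-sustaining memory nodes (a positive self-loop whose
    only effect is to remember a transient), where attractors differing only
    in that node's state are considered equivalent: the node is dropped and
    the given value substituted into all other rules.  Recorded as an
    ``"explicit"`` removal; reconstruction re-evaluates the node's original
    rule with its own state set to ``value``.
    """
    if name not in network.rules:
        raise ReductionError(f"node {name!r} has no rule to remove")
    if value not in (0, 1):
        raise ReductionError("value must be 0 or 1")
    recorded = substitute_simplify(network.rules[name], {name: value})
    reduced = _substitute_out(network, name, Const(value))
    return ReductionTrace(
        inputs={},
        stabilized={},
        removed=((name, recorded, "explicit"),),
        residual=reduced,
    )


# ---------------------------------------------------------------------------
# Back-substitution
# ---------------------------------------------------------------------------

def reconstruct_full_attractor(
    trace: ReductionTrace | Sequence[ReductionTrace],
    reduced_state: int,
    full_network: BooleanNetwork,
    max_rounds: int | None = None,
) -> int:
    """Extend a residual-network fixed point to a full-network fixed point.

    The reduced state is combined with the trace's clamped inputs and
    stabilized values; eliminated nodes are evaluated from their recorded
    rules in reverse elimination order.  Because stabilized values are
    derived on the live-cell branch, the candidate is then relaxed by
    synchronous iteration of the full rules until self-consistent.  The
    result must be a fixed point of the full network that agrees with
    ``reduced_state`` on the residual nodes; otherwise (an oscillatory
    reduced state) a :class:`ReductionError` directs the caller to state
    transition graph analysis.
    """
    if isinstance(trace, ReductionTrace):
        traces: list[ReductionTrace] = [trace]
    else:
        traces = list(trace)
    if not traces:
        raise ReductionError("no trace given")
    residual = traces[-1].residual

    asg: dict[str, int] = {}
    for t in traces:
        asg.update(t.inputs)
        asg.update(t.stabilized_values)
    for i, name in enumerate(residual.nodes):
        asg[name] = (reduced_state >> i) & 1
    for t in reversed(traces):
        for name, rule, _kind in reversed(t.removed):
            asg[name] = evaluate(rule, asg)

    missing = [n for n in full_network.nodes if n not in asg]
    if missing:
        raise ReductionError(
            f"trace does not cover full network; missing {missing}"
        )

    # Relax to self-consistency: stabilized values hold on the live branch,
    # so a reduced state on the death branch needs a few synchronous sweeps.
    limit = max_rounds if max_rounds is not None else 4 * full_network.n + 4
    for _ in range(limit):
        nxt = {
            n: evaluate(full_network.rule_of(n), asg) for n in full_network.nodes
        }
        if nxt == asg:
            break
        asg = nxt
    else:
        raise ReductionError(
            "reconstruction did not converge to a fixed point; the reduced "
            "state is oscillatory — use state transition graph analysis"
        )

    for i, name in enumerate(residual.nodes):
        if asg[name] != (reduced_state >> i) & 1:
            raise ReductionError(
                "reconstructed state disagrees with the reduced state on "
                f"residual node {name!r}; use state transition graph analysis"
            )
    state = sum(asg[n] << i for i, n in enumerate(full_network.nodes))
    if not full_network.is_fixed_point(state):
        raise ReductionError(
            "reconstruction yielded a non-fixed-point; the reduced state is "
            "oscillatory — use state transition graph analysis"
        )
    return state
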