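"""Boolean networks: named nodes, transfer rules and frozen source inputs.

A :class:`BooleanNetwork` is an ordered collection of nodes.  Every
non-source node carries a Boolean transfer rule over declared node names;
source nodes carry no rule and either hold a frozen value (an external
input clamped ON or OFF) or are free, in which case they simply hold their
state (self-sustaining, equivalent to the rule ``X* = X``).

States are encoded as Python integers: bit ``i`` is the value of the
``i``-th node in the network's node order.  The printable rendering puts
the first node leftmost, so the 6-node state ``110000`` has the first two
nodes ON.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping

from .logic import (
    Const,
    Expr,
    Var,
    evaluate,
    substitute_simplify,
    variables,
    write_expression,
)

__all__ = ["BooleanNetwork", "NetworkError", "state_to_string", "state_from_string"]


class NetworkError(ValueError):
    pass


def state_to_string(state: int, n_nodes: int) -> str:
    """Render a state integer as a bit string, first node leftmost."""
    return "".join(str((state >> i) & 1) for i in range(n_nodes))


def state_from_string(bits: str) -> int:
    """Parse a bit string (first node leftmost) into a state integer."""
    if not bits or any(c not in "01" for c in bits):
        raise ValueError(f"not a bit string: {bits!r}")
    return sum(1 << i for i, c in enumerate(bits) if c == "1")


@dataclass(frozen=True)
class BooleanNetwork:
    """An ordered Boolean network with optional frozen source inputs.

    Parameters
    ----------
    nodes:
        Node names in canonical order (the bit order of state encodings).
    rules:
        Transfer rule per non-source node.
    frozen:
        Value per clamped source node.  Sources absent from this mapping are
        free and hold their state.
    """

    nodes: tuple[str, ...]
    rules: Mapping[str, Expr]
    frozen: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nodes = tuple(self.nodes)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "rules", MappingProxyType(dict(self.rules)))
        object.__setattr__(self, "frozen", MappingProxyType(dict(self.frozen)))
        if len(set(nodes)) != len(nodes):
            dupes = sorted({n for n in nodes if nodes.count(n) > 1})
            raise NetworkError(f"duplicate node names: {dupes}")
        declared = set(nodes)
        for name, expr in self.rules.items():
            if name not in declared:
                raise NetworkError(f"rule for undeclared node {name!r}")
            missing = variables(expr) - declared
            if missing:
                raise NetworkError(
                    f"rule for {name!r} references undeclared node(s): "
                    f"{sorted(missing)}"
                )
        for name, value in self.frozen.items():
            if name not in declared:
                raise NetworkError(f"frozen value for undeclared node {name!r}")
            if name in self.rules:
                raise NetworkError(
                    f"node {name!r} has a rule and cannot be frozen; "
                    "remove the rule to treat it as a clamped source"
                )
            if value not in (0, 1):
                raise NetworkError(f"frozen value for {name!r} must be 0 or 1")

    # -- basic views --------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def sources(self) -> tuple[str, ...]:
        """Nodes without a rule (external inputs), in node order."""
        return tuple(n for n in self.nodes if n not in self.rules)

    @property
    def free_nodes(self) -> tuple[str, ...]:
        """Nodes that participate in the dynamics (everything not frozen)."""
        return tuple(n for n in self.nodes if n not in self.frozen)

    def index(self, name: str) -> int:
        try:
            return self.nodes.index(name)
        except ValueError:
            raise NetworkError(f"unknown node {name!r}") from None

    def rule_of(self, name: str) -> Expr:
        """Effective transfer rule: declared rule, frozen constant, or self."""
        if name in self.rules:
            return self.rules[name]
        if name in self.frozen:
            return Const(self.frozen[name])
        return Var(name)  # free source holds its state

    def state_string(self, state: int) -> str:
        return state_to_string(state, self.n)

    def assignment(self, state: int) -> dict[str, int]:
        return {name: (state >> i) & 1 for i, name in enumerate(self.nodes)}

    def is_fixed_point(self, state: int) -> bool:
        asg = self.assignment(state)
        return all(
            evaluate(self.rule_of(n), asg) == asg[n] for n in self.free_nodes
        )

    # -- derived networks ---------------------------------------------------

    def with_frozen(self, assignment: Mapping[str, int]) -> "BooleanNetwork":
        """Clamp additional nodes (sources or rule nodes) to fixed values.

        A clamped rule node has its rule removed; it is thereafter excluded
        from the update set, which models a permanent knockout (value 0) or
        constitutive over-expression (value 1).
        """
        frozen = dict(self.frozen)
        for name, value in assignment.items():
            if name not in self.nodes:
                raise NetworkError(f"unknown node {name!r}")
            if name in frozen and frozen[name] != value:
                raise NetworkError(
                    f"node {name!r} frozen to conflicting values "
                    f"{frozen[name]} and {value}"
                )
            frozen[name] = value
        rules = {n: e for n, e in self.rules.items() if n not in frozen}
        return BooleanNetwork(self.nodes, rules, frozen)

    def substituted(self, partial: Mapping[str, int]) -> "BooleanNetwork":
        """Substitute fixed values into every rule and drop those nodes.

        The substituted nodes disappear from the node list; remaining rules
        are simplified.  Used for building state spaces over free nodes only.
        """
        unknown = set(partial) - set(self.nodes)
        if unknown:
            raise NetworkError(f"unknown node(s): {sorted(unknown)}")
        keep = tuple(n for n in self.nodes if n not in partial)
        rules = {}
        for name in keep:
            if name in self.rules:
                rules[name] = substitute_simplify(self.rules[name], partial)
        frozen = {n: v for n, v in self.frozen.items() if n in keep}
        return BooleanNetwork(keep, rules, frozen)

    def restricted(self, keep: Iterable[str]) -> "BooleanNetwork":
        """Sub-network over ``keep`` (rules must not reference dropped nodes)."""
        keep_set = set(keep)
        nodes = tuple(n for n in self.nodes if n in keep_set)
        rules = {n: self.rules[n] for n in nodes if n in self.rules}
        frozen = {n: v for n, v in self.frozen.items() if n in keep_set}
        return BooleanNetwork(nodes, rules, frozen)

    # -- misc ---------------------------------------------------------------

    def describe(self) -> str:
        lines = []
        for name in self.nodes:
            if name in self.rules:
                lines.append(f"{name}* = {write_expression(self.rules[name])}")
            elif name in self.frozen:
                lines.append(f"{name} (source, frozen {self.frozen[name]})")
            else:
                lines.append(f"{name} (source, free)")
        return "\n".join(lines)
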