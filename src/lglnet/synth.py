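"""Random Boolean networks and canned motifs for testing and validation.

The generator emulates the structural features of curated signaling
models: a few clamped source inputs, bounded in-degree, a mix of
activating and inhibiting regulation, occasional self-loops (memory
nodes), and rules written directly in OR-of-ANDs form.  Identical
configuration and seed give byte-identical networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .logic import Expr, Not, Var, clauses_to_expr, dnf_clauses
from .network import BooleanNetwork

__all__ = ["GeneratorConfig", "random_network", "motif_network", "MOTIFS"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random-network generator.

    ``negation_p`` is the per-literal probability of negated (inhibitory)
    regulation; ``max_clauses`` bounds the number of OR-ed AND clauses per
    rule; ``self_loop_p`` is the probability that a node regulates itself.
    """

    n_nodes: int
    n_sources: int = 0
    max_in_degree: int = 3
    negation_p: float = 0.3
    max_clauses: int = 2
    self_loop_p: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("need at least one node")
        if self.n_sources >= self.n_nodes:
            raise ValueError("source count must be below the node count")
        if self.max_in_degree < 1:
            raise ValueError("max in-degree must be at least 1")
        for p in (self.negation_p, self.self_loop_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def random_network(config: GeneratorConfig) -> BooleanNetwork:
    """Draw a random Boolean network under ``config`` (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    width = max(2, len(str(config.n_nodes - 1)))
    names = tuple(f"n{i:0{width}d}" for i in range(config.n_nodes))
    sources = names[: config.n_sources]

    frozen = {s: int(rng.integers(0, 2)) for s in sources}
    rules: dict[str, Expr] = {}
    for name in names[config.n_sources:]:
        pool = [n for n in names if n != name]
        k = int(rng.integers(1, config.max_in_degree + 1))
        k = min(k, len(pool))
        regs = sorted(rng.choice(pool, size=k, replace=False).tolist())
        if rng.random() < config.self_loop_p:
            regs = sorted(set(regs[: k - 1]) | {name})
        n_clauses = int(rng.integers(1, config.max_clauses + 1))
        clauses: set[frozenset] = set()
        for _ in range(n_clauses):
            size = int(rng.integers(1, len(regs) + 1))
            chosen = rng.choice(regs, size=size, replace=False).tolist()
            clauses.add(
                frozenset(
                    (r, bool(rng.random() >= config.negation_p)) for r in chosen
                )
            )
        # normalise (absorption) so emitted rules are canonical OR-of-ANDs
        rules[name] = clauses_to_expr(dnf_clauses(clauses_to_expr(frozenset(clauses))))
    return BooleanNetwork(names, rules, frozen)


def _chain(k: int) -> BooleanNetwork:
    names = tuple(f"c{i}" for i in range(k))
    rules = {names[i]: Var(names[i - 1]) for i in range(1, k)}
    return BooleanNetwork(names, rules, {})


MOTIFS = {
    # classic toggle switch: two stable states 10 and 01
    "mutual-inhibition": BooleanNetwork(
        ("A", "B"), {"A": Not(Var("B")), "B": Not(Var("A"))}
    ),
    # two-node negative feedback: a single 4-state complex attractor
    "negative-feedback-2": BooleanNetwork(
        ("A", "B"), {"A": Not(Var("B")), "B": Var("A")}
    ),
    # positive self-loop: both constant states are fixed points
    "self-activation": BooleanNetwork(("A",), {"A": Var("A")}),
}


def motif_network(name: str) -> BooleanNetwork:
    """Canned motifs with known attractor structure (``chain-k`` supported)."""
    if name in MOTIFS:
        return MOTIFS[name]
    if name.startswith("chain-"):
        k = int(name.split("-", 1)[1])
        if k < 2:
            raise KeyError("chain length must be at least 2")
        return _chain(k)
    raise KeyError(
        f"unknown motif {name!r}; available: "
        f"{sorted(MOTIFS) + ['chain-k']}"
    )
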