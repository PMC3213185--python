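"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorized/graph code
paths: they enumerate states and evaluate rules one by one through the
plain expression evaluator, so they can serve as references for the
optimized implementations.
"""

from __future__ import annotations

import itertools

import pytest

from lglnet.io import load_fixture
from lglnet.logic import evaluate
from lglnet.network import BooleanNetwork


@pytest.fixture(scope="session")
def tlgl6() -> BooleanNetwork:
    return load_fixture("tlgl6")


@pytest.fixture(scope="session")
def tlgl18() -> BooleanNetwork:
    return load_fixture("tlgl18")


@pytest.fixture(scope="session")
def tlgl60() -> BooleanNetwork:
    return load_fixture("tlgl60")


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def free_view(network: BooleanNetwork) -> BooleanNetwork:
    """Network over the free nodes only (clamped sources substituted)."""
    return (
        network.substituted(dict(network.frozen)) if network.frozen else network
    )


def fixed_points_bruteforce(network: BooleanNetwork) -> list[int]:
    """Enumerate fixed points state by state with the scalar evaluator."""
    free = free_view(network)
    out = []
    for state in range(2 ** free.n):
        asg = free.assignment(state)
        if all(
            evaluate(free.rule_of(n), asg) == asg[n] for n in free.nodes
        ):
            out.append(state)
    return out


def sync_step(network: BooleanNetwork, state: int) -> int:
    """Synchronous update of every free node at once."""
    free = free_view(network)
    asg = free.assignment(state)
    nxt = 0
    for i, name in enumerate(free.nodes):
        nxt |= evaluate(free.rule_of(name), asg) << i
    return nxt


def sync_fixed_points_bruteforce(network: BooleanNetwork) -> list[int]:
    free = free_view(network)
    return [s for s in range(2 ** free.n) if sync_step(network, s) == s]


def ga_successor_states_bruteforce(
    network: BooleanNetwork, state: int
) -> dict[str, int]:
    """One-node-at-a-time successors via the scalar evaluator."""
    free = free_view(network)
    asg = free.assignment(state)
    out = {}
    for i, name in enumerate(free.nodes):
        bit = evaluate(free.rule_of(name), asg)
        out[name] = (state & ~(1 << i)) | (bit << i)
    return out


def attractor_states_bruteforce(network: BooleanNetwork) -> list[frozenset[int]]:
    """Terminal SCCs by Tarjan-free repeated reachability (tiny n only)."""
    free = free_view(network)
    n_states = 2 ** free.n
    succ = {
        s: set(ga_successor_states_bruteforce(network, s).values())
        for s in range(n_states)
    }
    # reachability closure per state
    reach: dict[int, frozenset[int]] = {}
    for s in range(n_states):
        seen = {s}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in succ[u]:
                    if v not in seen:
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
        reach[s] = frozenset(seen)
    attractors = set()
    for s in range(n_states):
        # s is in an attractor iff everything reachable can reach back
        if all(s in reach[v] for v in reach[s]):
            attractors.add(reach[s])
    return sorted(attractors, key=min)


def count_simple_paths_bruteforce(graph, source, sink) -> int:
    """Exhaustive recursive enumeration over a networkx digraph."""
    if source not in graph or sink not in graph:
        return 0

    def walk(v, visited):
        if v == sink:
            return 1
        total = 0
        for w in graph.successors(v):
            if w not in visited:
                total += walk(w, visited | {w})
        return total

    return walk(source, {source})
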