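"""Expanded-network structural analysis: path-based node essentiality.

A signaling network with signed, conditionally combined interactions is
*expanded* into an unsigned graph that makes logic explicit:

* a **complementary vertex** ``~v`` represents the negation of ``v`` and is
  introduced wherever some rule uses ``NOT v`` (or where a complementary
  output is requested); its inputs encode the negated rule of ``v``;
* a **composite vertex** represents a multi-literal AND clause: it receives
  one edge from each literal's vertex and sends one edge to the clause's
  target; multiple edges converging directly on an original or
  complementary vertex are alternatives (OR).

On this representation the loss of a vertex *cascades*: a composite vertex
dies with any of its inputs, and an original/complementary vertex that had
regulators dies when it loses all of them.  The **simple path (SP)
measure** counts directed paths without repeated vertices from an input to
an output vertex, and the importance of a vertex ``v`` is

    I_v = 1 - N_SP(G_dv) / N_SP(G_exp),

the relative loss of input–output simple paths after its cascading
deletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .logic import Const, dnf_clauses, negate_rule, to_canonical
from .network import BooleanNetwork

__all__ = [
    "ExpandedNetwork",
    "ImportanceRecord",
    "expand",
    "cascading_delete",
    "count_simple_paths",
    "importance",
    "COMPLEMENT_PREFIX",
]

COMPLEMENT_PREFIX = "~"

ORIGINAL = "original"
COMPLEMENTARY = "complementary"
COMPOSITE = "composite"


@dataclass(frozen=True)
class ExpandedNetwork:
    """Expanded (unsigned) representation of a Boolean network.

    ``graph`` holds vertices with a ``kind`` attribute (``original``,
    ``complementary`` or ``composite``); every edge denotes activation.
    ``constant_vertices`` records nodes whose rule simplified to a constant
    and therefore became input-less stubs.
    """

    graph: nx.DiGraph
    constant_vertices: tuple[tuple[str, int], ...] = ()

    def kind(self, vertex: str) -> str:
        return self.graph.nodes[vertex]["kind"]

    def vertices(self, kind: str | None = None) -> tuple[str, ...]:
        if kind is None:
            return tuple(sorted(self.graph.nodes))
        return tuple(
            sorted(v for v, d in self.graph.nodes(data=True) if d["kind"] == kind)
        )

    def to_networkx(self) -> nx.DiGraph:
        return self.graph


def _composite_name(literals: Sequence[str], target: str) -> str:
    return "&".join(literals) + "=>" + target


def _literal_vertex(name: str, polarity: bool) -> str:
    return name if polarity else COMPLEMENT_PREFIX + name


def expand(
    network: BooleanNetwork,
    extra_outputs: Iterable[str] = (),
    substitute_frozen: bool = True,
    recursive_complements: bool = True,
) -> ExpandedNetwork:
    """Build the expanded network of ``network``.

    Complementary vertices are created lazily: one for each node that some
    canonical clause uses negated, plus any requested in ``extra_outputs``
    (names prefixed with ``~``).  With ``substitute_frozen`` the clamped
    source values are substituted into all rules first (clamped sources then
    do not appear as vertices); without it sources stay as input vertices
    and rules are expanded verbatim.

    With ``recursive_complements`` (the default) negated rules may demand
    further complementary vertices, which are created and wired in turn
    until closure.  Without it the complement layer is *first order*: only
    the complements demanded by the original rules (and ``extra_outputs``)
    exist, and clauses of a negated rule that would require any other
    complementary vertex are dropped.  The first-order graph keeps every
    inhibitory alternative that is structurally visible in the original
    network while avoiding the combinatorial blow-up of nested negations.
    """
    base = network.substituted(dict(network.frozen)) if (
        substitute_frozen and network.frozen
    ) else network

    g = nx.DiGraph()
    constants: list[tuple[str, int]] = []
    needed_complements: set[str] = set()

    def ensure_vertex(vertex: str) -> None:
        if vertex.startswith(COMPLEMENT_PREFIX):
            if not g.has_node(vertex):
                g.add_node(vertex, kind=COMPLEMENTARY)
            needed_complements.add(vertex[len(COMPLEMENT_PREFIX):])
        else:
            if not g.has_node(vertex):
                g.add_node(vertex, kind=ORIGINAL)

    def add_clauses(target_vertex: str, clause_sets) -> None:
        for clause in sorted(
            clause_sets, key=lambda c: sorted((n, not p) for n, p in c)
        ):
            lits = sorted(
                _literal_vertex(n, p) for n, p in clause
            )
            for lv in lits:
                ensure_vertex(lv)
            if len(lits) == 1:
                g.add_edge(lits[0], target_vertex)
            else:
                comp = _composite_name(lits, target_vertex)
                g.add_node(comp, kind=COMPOSITE, arity=len(lits))
                for lv in lits:
                    g.add_edge(lv, comp)
                g.add_edge(comp, target_vertex)

    # original vertices and their clauses
    for name in base.nodes:
        ensure_vertex(name)
    for name in base.nodes:
        if name not in base.rules:
            continue  # source: input vertex without regulators
        clauses = dnf_clauses(base.rules[name])
        if isinstance(clauses, Const):
            constants.append((name, clauses.value))
            continue
        add_clauses(name, clauses)

    for out in extra_outputs:
        ensure_vertex(out)
        # a requested complementary output also admits the complements its
        # own negated rule demands (one level), so the output is wired even
        # in first-order mode
        if out.startswith(COMPLEMENT_PREFIX):
            node = out[len(COMPLEMENT_PREFIX):]
            if node in base.rules and not isinstance(
                dnf_clauses(base.rules[node]), Const
            ):
                negated = negate_rule(to_canonical(base.rules[node], node))
                for clause in negated.clause_sets():
                    for n, pol in clause:
                        if not pol:
                            needed_complements.add(n)

    # complementary vertices, created lazily
    allowed: frozenset[str] | None = (
        None if recursive_complements else frozenset(needed_complements)
    )
    done: set[str] = set()
    while True:
        todo = sorted(needed_complements - done)
        if not todo:
            break
        for node in todo:
            done.add(node)
            vertex = COMPLEMENT_PREFIX + node
            ensure_vertex(vertex)
            if node not in base.rules:
                if node in base.nodes:
                    continue  # complement of a source: input vertex
                raise ValueError(f"negated literal references unknown node {node!r}")
            clauses = dnf_clauses(base.rules[node])
            if isinstance(clauses, Const):
                constants.append((vertex, 1 - clauses.value))
                continue
            negated = negate_rule(to_canonical(base.rules[node], node))
            clause_sets = negated.clause_sets()
            if allowed is not None:
                clause_sets = tuple(
                    c
                    for c in clause_sets
                    if all(
                        pol or n in allowed or n not in base.rules
                        for n, pol in c
                    )
                )
            add_clauses(vertex, clause_sets)

    # record original in-degrees for the cascading rule
    for v in g.nodes:
        g.nodes[v]["base_in_degree"] = g.in_degree(v)
    return ExpandedNetwork(graph=g, constant_vertices=tuple(sorted(constants)))


# ---------------------------------------------------------------------------
# Cascading deletion
# ---------------------------------------------------------------------------

def cascading_delete(
    expanded: ExpandedNetwork,
    seed: str,
    protect: Iterable[str] = (),
) -> ExpandedNetwork:
    """Delete ``seed`` and cascade the loss of indispensable regulators.

    After removing the seed, iteratively delete every composite vertex
    missing at least one of its inputs and every original/complementary
    vertex that had regulators in the intact network but has lost them all.
    The result is independent of processing order.  Vertices in ``protect``
    (typically the designated input and output) may not be the seed.
    """
    protect_set = set(protect)
    if seed in protect_set:
        raise ValueError(f"cannot delete protected vertex {seed!r}")
    g = expanded.graph
    if seed not in g:
        raise KeyError(f"no vertex named {seed!r}")

    removed = {seed}
    # process cascades with a worklist of vertices whose inputs shrank
    frontier = list(g.successors(seed))
    while frontier:
        nxt: list[str] = []
        for v in frontier:
            if v in removed:
                continue
            data = g.nodes[v]
            live_in = sum(
                1 for p in g.predecessors(v) if p not in removed
            )
            if data["kind"] == COMPOSITE:
                dead = live_in < data["arity"]
            else:
                dead = data["base_in_degree"] > 0 and live_in == 0
            if dead:
                removed.add(v)
                nxt.extend(g.successors(v))
        frontier = nxt

    sub = g.subgraph([v for v in g.nodes if v not in removed]).copy()
    return ExpandedNetwork(
        graph=sub,
        constant_vertices=tuple(
            (v, c) for v, c in expanded.constant_vertices if v not in removed
        ),
    )


# ---------------------------------------------------------------------------
# Simple-path counting
# ---------------------------------------------------------------------------

def count_simple_paths(
    expanded: ExpandedNetwork | nx.DiGraph, source: str, sink: str
) -> int:
    """Exact number of directed simple paths from ``source`` to ``sink``.

    Composite vertices count as path vertices.  Enumeration is a DFS with
    on-path marking; only the count is kept, so memory stays linear in the
    vertex count.  Vertices that cannot reach the sink are pruned first.
    """
    g = expanded.graph if isinstance(expanded, ExpandedNetwork) else expanded
    if source == sink:
        raise ValueError("source and sink must differ")
    if source not in g or sink not in g:
        return 0

    # prune to vertices that can reach the sink
    can_reach = set(nx.ancestors(g, sink))
    can_reach.add(sink)
    if source not in can_reach:
        return 0

    order = {v: i for i, v in enumerate(sorted(g.nodes))}
    adj: dict[int, list[int]] = {}
    for v in can_reach:
        adj[order[v]] = sorted(
            order[w] for w in g.successors(v) if w in can_reach
        )
    src, snk = order[source], order[sink]

    count = 0
    on_path = set([src])
    # stack of iterators for iterative DFS
    stack: list[list[int]] = [list(adj[src])]
    ptrs = [0]
    path = [src]
    while stack:
        children, i = stack[-1], ptrs[-1]
        if i >= len(children):
            stack.pop()
            ptrs.pop()
            on_path.discard(path.pop())
            continue
        ptrs[-1] += 1
        w = children[i]
        if w == snk:
            count += 1
            continue
        if w in on_path:
            continue
        on_path.add(w)
        path.append(w)
        stack.append(adj[w])
        ptrs.append(0)
    return count


# ---------------------------------------------------------------------------
# Importance values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImportanceRecord:
    vertex: str
    n_paths_intact: int
    n_paths_damaged: int
    importance: float
    cascade: bool = True


def importance(
    expanded: ExpandedNetwork,
    vertex: str,
    source: str,
    sink: str,
    cascade: bool = True,
    n_paths_intact: int | None = None,
) -> ImportanceRecord:
    """Importance of ``vertex`` for source→sink connectivity.

    With ``cascade`` the vertex is removed by :func:`cascading_delete`;
    without it only the vertex itself (a pure topological control).  A
    vertex absent from the expanded graph (e.g. a complementary vertex
    nothing refers to) scores 0: its deletion cannot remove any path.
    ``n_paths_intact`` may be supplied to avoid recounting the intact
    network across a candidate scan.
    """
    if vertex in (source, sink):
        raise ValueError("cannot score the designated input or output vertex")
    base = (
        n_paths_intact
        if n_paths_intact is not None
        else count_simple_paths(expanded, source, sink)
    )
    if base == 0:
        raise ValueError("intact network has no input–output path")
    if vertex not in expanded.graph:
        return ImportanceRecord(vertex, base, base, 0.0, cascade)
    if cascade:
        damaged = cascading_delete(expanded, vertex, protect=(source, sink))
    else:
        g = expanded.graph.copy()
        g.remove_node(vertex)
        damaged = ExpandedNetwork(graph=g)
    after = count_simple_paths(damaged, source, sink)
    return ImportanceRecord(
        vertex=vertex,
        n_paths_intact=base,
        n_paths_damaged=after,
        importance=1.0 - after / base,
        cascade=cascade,
    )
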