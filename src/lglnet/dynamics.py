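"""General-asynchronous Boolean dynamics on the full state space.

Under the general asynchronous (GA) update, a single randomly chosen node
is updated at each time step.  The induced nondeterministic dynamics is
captured by a *state transition graph* (STG) over all :math:`2^f` states of
the :math:`f` free (non-clamped) nodes, with one labeled edge per state and
node — including self-loop edges when an update leaves the state unchanged.

Attractors are the terminal strongly-connected components of the STG:
either fixed points or complex attractors among whose states the system
oscillates.  Basins are computed exactly by reachability on the condensed
STG, and absorption probabilities to fixed points by solving the linear
system of the associated Markov chain (uniform probability :math:`1/f` per
node update).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .logic import And, Const, Expr, Not, Or, Var, evaluate, substitute_simplify, variables
from .network import BooleanNetwork, state_to_string

__all__ = [
    "StateTransitionGraph",
    "Attractor",
    "BasinReport",
    "AbsorptionResult",
    "StateSpaceTooLarge",
    "ga_successors",
    "build_stg",
    "attractors_from_stg",
    "fixed_points_analytic",
    "basin_partition",
    "absorption_probabilities",
]

DEFAULT_STATE_CAP = 20  # build STGs up to 2**20 states


class StateSpaceTooLarge(ValueError):
    pass


# ---------------------------------------------------------------------------
# Successors and the state transition graph
# ---------------------------------------------------------------------------

def ga_successors(network: BooleanNetwork, state: int) -> dict[str, int]:
    """One labeled successor per free node (general-asynchronous step).

    ``state`` is encoded over the network's full node order and must agree
    with any clamped sources.  The returned mapping sends each free node to
    the state reached by updating that node alone; self-transitions are
    included.
    """
    asg = network.assignment(state)
    for name, value in network.frozen.items():
        if asg[name] != value:
            raise ValueError(
                f"state sets clamped source {name!r} to {asg[name]}, "
                f"expected {value}"
            )
    out: dict[str, int] = {}
    for name in network.free_nodes:
        i = network.index(name)
        bit = evaluate(network.rule_of(name), asg)
        out[name] = (state & ~(1 << i)) | (bit << i)
    return out


def _eval_vec(expr: Expr, bits: Mapping[str, np.ndarray], n_states: int) -> np.ndarray:
    if isinstance(expr, Const):
        return np.full(n_states, bool(expr.value))
    if isinstance(expr, Var):
        return bits[expr.name]
    if isinstance(expr, Not):
        return ~_eval_vec(expr.operand, bits, n_states)
    if isinstance(expr, And):
        acc = _eval_vec(expr.args[0], bits, n_states)
        for a in expr.args[1:]:
            acc = acc & _eval_vec(a, bits, n_states)
        return acc
    if isinstance(expr, Or):
        acc = _eval_vec(expr.args[0], bits, n_states)
        for a in expr.args[1:]:
            acc = acc | _eval_vec(a, bits, n_states)
        return acc
    raise TypeError(f"not an expression: {expr!r}")


@dataclass(frozen=True)
class StateTransitionGraph:
    """All :math:`2^f` states of the free nodes with GA transition edges.

    ``nodes`` is the free-node order defining the bit encoding of states;
    ``successors[s, i]`` is the state reached from ``s`` by updating node
    ``i`` (possibly ``s`` itself).
    """

    nodes: tuple[str, ...]
    successors: np.ndarray  # shape (2**f, f)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_states(self) -> int:
        return self.successors.shape[0]

    def state_string(self, state: int) -> str:
        return state_to_string(state, self.n_nodes)

    def distinct_successors(self, state: int) -> np.ndarray:
        return np.unique(self.successors[state])

    def edge_arrays(self, drop_self_loops: bool = False):
        src = np.repeat(
            np.arange(self.n_states, dtype=np.int64), self.n_nodes
        )
        dst = self.successors.astype(np.int64).ravel()
        if drop_self_loops:
            keep = src != dst
            return src[keep], dst[keep]
        return src, dst

    def adjacency(self, drop_self_loops: bool = False) -> sp.csr_matrix:
        src, dst = self.edge_arrays(drop_self_loops)
        data = np.ones(len(src), dtype=np.int8)
        mat = sp.coo_matrix(
            (data, (src, dst)), shape=(self.n_states, self.n_states)
        ).tocsr()
        mat.data[:] = 1
        return mat

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph()
        for s in range(self.n_states):
            g.add_node(self.state_string(s))
        for s in range(self.n_states):
            for i, name in enumerate(self.nodes):
                g.add_edge(
                    self.state_string(s),
                    self.state_string(int(self.successors[s, i])),
                    label=name,
                )
        return g


def _free_network(network: BooleanNetwork) -> BooleanNetwork:
    return network.substituted(dict(network.frozen)) if network.frozen else network


def build_stg(
    network: BooleanNetwork, cap: int = DEFAULT_STATE_CAP
) -> StateTransitionGraph:
    """Construct the full general-asynchronous state transition graph.

    Clamped sources are substituted away first; the state space covers the
    free nodes only.  Raises :class:`StateSpaceTooLarge` beyond ``2**cap``
    states — reduce the network first.
    """
    free = _free_network(network)
    f = free.n
    if f > cap:
        raise StateSpaceTooLarge(
            f"{f} free nodes exceed the cap of {cap} (2**{f} states); "
            "apply network reduction before building the STG"
        )
    n_states = 1 << f
    states = np.arange(n_states, dtype=np.int64)
    bits = {
        name: ((states >> i) & 1).astype(bool)
        for i, name in enumerate(free.nodes)
    }
    succ = np.empty((n_states, f), dtype=np.int64)
    for i, name in enumerate(free.nodes):
        new_bit = _eval_vec(free.rule_of(name), bits, n_states)
        succ[:, i] = (states & ~(1 << i)) | (new_bit.astype(np.int64) << i)
    return StateTransitionGraph(nodes=free.nodes, successors=succ)


# ---------------------------------------------------------------------------
# Attractors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Attractor:
    """A terminal strongly-connected set of states.

    ``states`` are encoded over the STG's free-node order.  A fixed point
    has a single member state mapped to itself by every update.  For complex
    attractors ``on_fractions`` gives each node's average ON fraction over
    the member states (uniform average).
    """

    states: tuple[int, ...]
    nodes: tuple[str, ...]
    is_fixed_point: bool

    @property
    def on_fractions(self) -> dict[str, float]:
        arr = np.asarray(self.states, dtype=np.int64)
        return {
            name: float(np.mean((arr >> i) & 1))
            for i, name in enumerate(self.nodes)
        }

    @property
    def oscillating_nodes(self) -> tuple[str, ...]:
        fr = self.on_fractions
        return tuple(n for n in self.nodes if 0.0 < fr[n] < 1.0)

    def state_strings(self) -> tuple[str, ...]:
        return tuple(state_to_string(s, len(self.nodes)) for s in self.states)


def attractors_from_stg(stg: StateTransitionGraph) -> list[Attractor]:
    """Terminal strongly-connected components of the STG."""
    adj = stg.adjacency(drop_self_loops=True)
    n_comp, labels = csgraph.connected_components(
        adj, directed=True, connection="strong"
    )
    src, dst = stg.edge_arrays(drop_self_loops=True)
    terminal = np.ones(n_comp, dtype=bool)
    cross = labels[src] != labels[dst]
    terminal[labels[src[cross]]] = False

    attractors: list[Attractor] = []
    for comp in np.flatnonzero(terminal):
        members = np.flatnonzero(labels == comp)
        states = tuple(int(s) for s in members)
        fixed = len(states) == 1 and bool(
            np.all(stg.successors[states[0]] == states[0])
        )
        attractors.append(
            Attractor(states=states, nodes=stg.nodes, is_fixed_point=fixed)
        )
    attractors.sort(key=lambda a: a.states[0])
    return attractors


# ---------------------------------------------------------------------------
# Analytic fixed points
# ---------------------------------------------------------------------------

def _fixed_points_exhaustive(free: BooleanNetwork) -> list[int]:
    n_states = 1 << free.n
    states = np.arange(n_states, dtype=np.int64)
    bits = {
        name: ((states >> i) & 1).astype(bool)
        for i, name in enumerate(free.nodes)
    }
    ok = np.ones(n_states, dtype=bool)
    for i, name in enumerate(free.nodes):
        ok &= _eval_vec(free.rule_of(name), bits, n_states) == bits[name]
    return [int(s) for s in np.flatnonzero(ok)]


def _fixed_points_backtrack(free: BooleanNetwork) -> list[int]:
    """Constraint solving: x_i == f_i(x) via backtracking with propagation.

    Each rule node carries the constraint ``x_t == f_t(x)``; whenever a
    constraint expression collapses to a constant it either pins its (still
    undecided) target or is checked against the decided value, and new pins
    are substituted into every remaining constraint until quiescence.
    """
    solutions: list[int] = []
    names = free.nodes
    index = {n: i for i, n in enumerate(names)}

    def propagate(cons: dict[str, Expr], asg: dict[str, int]):
        while True:
            newly: dict[str, int] = {}
            for tgt in list(cons):
                e = cons[tgt]
                if not isinstance(e, Const):
                    continue
                want = asg.get(tgt, newly.get(tgt))
                if want is not None:
                    if want != e.value:
                        return None
                else:
                    newly[tgt] = e.value
                del cons[tgt]
            if not newly:
                return cons, asg
            asg.update(newly)
            cons = {
                t: substitute_simplify(e, newly) for t, e in cons.items()
            }

    def solve(cons: dict[str, Expr], asg: dict[str, int]) -> None:
        res = propagate(dict(cons), dict(asg))
        if res is None:
            return
        cons, asg = res
        undecided = [n for n in names if n not in asg]
        if not undecided:
            assert not cons
            solutions.append(sum(asg[n] << index[n] for n in names))
            return
        # branch on the undecided variable appearing in the most constraints
        counts = {n: 0 for n in undecided}
        for e in cons.values():
            for v in variables(e):
                if v in counts:
                    counts[v] += 1
        pivot = max(undecided, key=lambda n: (counts[n], -index[n]))
        for value in (0, 1):
            nxt = {
                t: substitute_simplify(e, {pivot: value})
                for t, e in cons.items()
            }
            solve(nxt, {**asg, pivot: value})

    cons0 = {n: free.rule_of(n) for n in names if n in free.rules}
    # free sources satisfy x == x trivially and act as pure branch variables
    solve(cons0, {})
    return sorted(set(solutions))


def fixed_points_analytic(
    network: BooleanNetwork, cap: int = DEFAULT_STATE_CAP
) -> list[int]:
    """All fixed points, solved independent of time and update scheme.

    States are encoded over the free nodes (clamped sources substituted).
    Below ``2**cap`` states the check is exhaustive and vectorized; above,
    the Boolean equation system ``x_i = f_i(x)`` is solved by backtracking
    with constant propagation.
    """
    free = _free_network(network)
    if free.n <= cap:
        return _fixed_points_exhaustive(free)
    return _fixed_points_backtrack(free)


# ---------------------------------------------------------------------------
# Basins of attraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasinReport:
    """Exact basin partition of a state transition graph.

    ``reach_mask[s]`` is a bitmask of the attractors reachable from state
    ``s``.  A state belongs to attractor ``j``'s *exclusive* basin when only
    ``j`` is reachable from it (the attractor's own states therefore count
    toward its exclusive basin); states from which several attractors are
    reachable form the overlap region.
    """

    attractors: tuple[Attractor, ...]
    reach_mask: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.reach_mask)

    @property
    def exclusive_counts(self) -> tuple[int, ...]:
        return tuple(
            int(np.sum(self.reach_mask == (1 << j)))
            for j in range(len(self.attractors))
        )

    @property
    def overlap_count(self) -> int:
        mask = self.reach_mask
        return int(np.sum((mask & (mask - 1)) != 0))

    @property
    def exclusive_percentages(self) -> tuple[float, ...]:
        return tuple(100.0 * c / self.n_states for c in self.exclusive_counts)

    def exclusive_states(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.reach_mask == (1 << j))

    def overlap_states(self) -> np.ndarray:
        mask = self.reach_mask
        return np.flatnonzero((mask & (mask - 1)) != 0)


def basin_partition(
    stg: StateTransitionGraph, attractors: Sequence[Attractor]
) -> BasinReport:
    """Exact exclusive-basin/overlap partition by condensation reachability."""
    if len(attractors) > 63:
        raise ValueError("more than 63 attractors not supported")
    adj = stg.adjacency(drop_self_loops=True)
    n_comp, labels = csgraph.connected_components(
        adj, directed=True, connection="strong"
    )
    src, dst = stg.edge_arrays(drop_self_loops=True)
    cross = labels[src] != labels[dst]
    cs, cd = labels[src[cross]], labels[dst[cross]]
    # condensation edges, deduplicated
    cond = sp.coo_matrix(
        (np.ones(len(cs), dtype=np.int8), (cs, cd)), shape=(n_comp, n_comp)
    ).tocsr()

    comp_mask = np.zeros(n_comp, dtype=np.int64)
    for j, att in enumerate(attractors):
        comp_mask[labels[att.states[0]]] |= 1 << j

    # Propagate reachable-attractor masks backwards through the condensation
    # DAG in reverse topological (Kahn) order.
    coo = cond.tocoo()
    indptr, indices = cond.indptr, cond.indices
    indegree = np.bincount(coo.row, minlength=n_comp)  # in-deg of reversed DAG
    order: list[int] = list(np.flatnonzero(indegree == 0))
    rev = sp.coo_matrix(
        (np.ones(len(coo.row), dtype=np.int8), (coo.col, coo.row)),
        shape=(n_comp, n_comp),
    ).tocsr()
    head = 0
    while head < len(order):
        c = order[head]
        head += 1
        for p in rev.indices[rev.indptr[c]:rev.indptr[c + 1]]:
            indegree[p] -= 1
            if indegree[p] == 0:
                order.append(int(p))
    assert len(order) == n_comp, "condensation is not a DAG"
    for c in order:  # successors of c come earlier in `order`
        acc = comp_mask[c]
        for k in indices[indptr[c]:indptr[c + 1]]:
            acc |= comp_mask[k]
        comp_mask[c] = acc
    return BasinReport(
        attractors=tuple(attractors), reach_mask=comp_mask[labels]
    )


# ---------------------------------------------------------------------------
# Absorption probabilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbsorptionResult:
    """Markov-chain absorption probabilities into fixed-point attractors.

    ``transient_states`` indexes the rows of ``probabilities``; column ``j``
    is the probability of eventually reaching fixed point ``j`` under the
    uniform GA chain (probability :math:`1/f` per node update).  Rows sum
    to 1.
    """

    fixed_points: tuple[int, ...]
    transient_states: np.ndarray
    probabilities: np.ndarray  # shape (n_transient, n_fixed_points)

    def probability(self, state: int, j: int) -> float:
        if state == self.fixed_points[j]:
            return 1.0
        if state in self.fixed_points:
            return 0.0
        idx = int(np.searchsorted(self.transient_states, state))
        if (
            idx >= len(self.transient_states)
            or self.transient_states[idx] != state
        ):
            raise KeyError(f"state {state} not in the chain")
        return float(self.probabilities[idx, j])


def absorption_probabilities(
    stg: StateTransitionGraph,
    attractors: Sequence[Attractor],
    iterative_above: int = 100_000,
    tol: float = 1e-12,
) -> AbsorptionResult:
    """Absorption probabilities of the uniform GA Markov chain.

    All attractors must be fixed points (absorption into complex attractors
    is not supported).  The linear system is solved on the transient states
    with sparse LU below ``iterative_above`` states, and by (geometrically
    convergent) fixed-point iteration above.
    """
    for att in attractors:
        if not att.is_fixed_point:
            raise ValueError(
                "absorption probabilities require fixed-point attractors "
                "only; complex attractor present"
            )
    fps = tuple(att.states[0] for att in attractors)
    n_states, f = stg.n_states, stg.n_nodes

    absorbing = np.zeros(n_states, dtype=bool)
    absorbing[list(fps)] = True
    transient = np.flatnonzero(~absorbing)
    pos = -np.ones(n_states, dtype=np.int64)
    pos[transient] = np.arange(len(transient))

    src, dst = stg.edge_arrays(drop_self_loops=False)
    keep = ~absorbing[src]
    src, dst = src[keep], dst[keep]
    w = np.full(len(src), 1.0 / f)

    to_transient = ~absorbing[dst]
    Q = sp.coo_matrix(
        (w[to_transient], (pos[src[to_transient]], pos[dst[to_transient]])),
        shape=(len(transient), len(transient)),
    ).tocsr()
    fp_col = -np.ones(n_states, dtype=np.int64)
    for j, s in enumerate(fps):
        fp_col[s] = j
    to_abs = absorbing[dst]
    R = sp.coo_matrix(
        (w[to_abs], (pos[src[to_abs]], fp_col[dst[to_abs]])),
        shape=(len(transient), len(fps)),
    ).tocsr()

    if len(transient) == 0:
        B = np.zeros((0, len(fps)))
    elif len(transient) <= iterative_above:
        A = sp.eye(len(transient), format="csc") - Q.tocsc()
        B = spla.spsolve(A, R.tocsc())
        B = np.asarray(B.todense() if sp.issparse(B) else B).reshape(
            len(transient), len(fps)
        )
    else:
        B = np.asarray(R.todense())
        Rd = B.copy()
        for _ in range(1_000_000):
            nxt = Q @ B + Rd
            if np.max(np.abs(nxt - B)) < tol:
                B = nxt
                break
            B = nxt
    resid = np.max(np.abs(Q @ B + np.asarray(R.todense()) - B)) if len(transient) else 0.0
    if resid > 1e-10:
        raise RuntimeError(f"absorption solve residual {resid:.2e} exceeds 1e-10")
    return AbsorptionResult(
        fixed_points=fps,
        transient_states=transient,
        probabilities=B,
    )
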