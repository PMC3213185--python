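"""GA state transition graphs, attractors, basins and absorption."""

import numpy as np
import pytest

from lglnet.dynamics import (
    StateSpaceTooLarge,
    absorption_probabilities,
    attractors_from_stg,
    basin_partition,
    build_stg,
    fixed_points_analytic,
    ga_successors,
)
from lglnet.io import parse_network
from lglnet.network import state_from_string
from lglnet.synth import GeneratorConfig, motif_network, random_network

from conftest import (
    fixed_points_bruteforce,
    free_view,
    ga_successor_states_bruteforce,
    sync_fixed_points_bruteforce,
)


def _att_strings(network, attractors):
    free = free_view(network)
    return {
        tuple(free.state_string(s) for s in att.states) for att in attractors
    }


# ---------------------------------------------------------------------------
# Successors
# ---------------------------------------------------------------------------

def test_disease_state_is_invariant_under_every_update(tlgl6):
    state = state_from_string("110000")
    assert set(ga_successors(tlgl6, state).values()) == {state}


def test_all_off_state_successors(tlgl6):
    succ = ga_successors(tlgl6, 0)
    distinct = {v for v in succ.values() if v != 0}
    assert distinct == {
        state_from_string("100000"),
        state_from_string("010000"),
        state_from_string("001000"),
    }
    assert succ["Ceramide"] == 0 and succ["DISC"] == 0 and succ["Apoptosis"] == 0


def test_single_negation_node():
    net = parse_network("A* = NOT A\n")
    assert ga_successors(net, 0) == {"A": 1}


def test_successors_respect_clamped_sources():
    net = parse_network("#@ source S = 1\nA* = S\n")
    with pytest.raises(ValueError, match="clamped"):
        ga_successors(net, 0b00)  # S bit contradicts the clamp


# ---------------------------------------------------------------------------
# STG construction
# ---------------------------------------------------------------------------

def test_stg_sizes(tlgl6):
    stg = build_stg(tlgl6)
    assert stg.n_states == 64 and stg.successors.shape == (64, 6)


def test_stg_constant_single_node():
    net = parse_network("A* = 0\n")
    stg = build_stg(net)
    assert stg.n_states == 2
    assert list(stg.successors[:, 0]) == [0, 0]


def test_stg_cap():
    net = random_network(GeneratorConfig(n_nodes=10, seed=0))
    with pytest.raises(StateSpaceTooLarge, match="reduction"):
        build_stg(net, cap=8)


def test_stg_matches_scalar_successors(tlgl6):
    stg = build_stg(tlgl6)
    for state in (0, 7, 33, 63):
        expected = ga_successor_states_bruteforce(tlgl6, state)
        got = {n: int(stg.successors[state, i]) for i, n in enumerate(stg.nodes)}
        assert got == expected


# ---------------------------------------------------------------------------
# Attractors
# ---------------------------------------------------------------------------

def test_six_node_model_has_the_two_reported_fixed_points(tlgl6):
    stg = build_stg(tlgl6)
    atts = attractors_from_stg(stg)
    assert _att_strings(tlgl6, atts) == {("000001",), ("110000",)}
    assert all(a.is_fixed_point for a in atts)


def test_receptor_oscillator_complex_attractor():
    net = parse_network("TCR* = NOT CTLA4\nCTLA4* = TCR\n")
    atts = attractors_from_stg(build_stg(net))
    assert len(atts) == 1
    (att,) = atts
    assert not att.is_fixed_point and len(att.states) == 4
    assert att.on_fractions == {"TCR": 0.5, "CTLA4": 0.5}
    assert set(att.oscillating_nodes) == {"TCR", "CTLA4"}


def test_self_activation_bistability():
    atts = attractors_from_stg(build_stg(motif_network("self-activation")))
    assert _att_strings(motif_network("self-activation"), atts) == {("0",), ("1",)}


def test_analytic_fixed_points(tlgl6):
    fps = fixed_points_analytic(tlgl6)
    assert {tlgl6.state_string(s) for s in fps} == {"000001", "110000"}
    assert fixed_points_analytic(parse_network("A* = NOT A\n")) == []


def test_sixteen_node_solver_agrees_with_backtracking(tlgl18):
    bottom = tlgl18.restricted(
        [n for n in tlgl18.nodes if n not in ("TCR", "CTLA4")]
    )
    exhaustive = fixed_points_analytic(bottom)
    solved = fixed_points_analytic(bottom, cap=4)  # force the solver path
    assert sorted(exhaustive) == sorted(solved)
    assert len(exhaustive) == 3


def test_fixed_points_agree_across_methods_on_random_networks():
    # analytic enumeration == equation solving == synchronous oracle ==
    # fixed points of the asynchronous STG
    for seed in range(12):
        net = random_network(
            GeneratorConfig(n_nodes=7, n_sources=1, seed=40 + seed, self_loop_p=0.2)
        )
        brute = fixed_points_bruteforce(net)
        assert fixed_points_analytic(net) == brute
        assert fixed_points_analytic(net, cap=3) == brute
        assert sync_fixed_points_bruteforce(net) == brute
        stg_fps = [
            a.states[0]
            for a in attractors_from_stg(build_stg(net))
            if a.is_fixed_point
        ]
        assert sorted(stg_fps) == brute


# ---------------------------------------------------------------------------
# Basins
# ---------------------------------------------------------------------------

def test_six_node_exclusive_basins(tlgl6):
    stg = build_stg(tlgl6)
    atts = attractors_from_stg(stg)
    rep = basin_partition(stg, atts)
    by_state = {a.states[0]: j for j, a in enumerate(atts)}
    normal = by_state[state_from_string("000001")]
    disease = by_state[state_from_string("110000")]
    assert rep.exclusive_counts[normal] == 36
    assert rep.exclusive_counts[disease] == 3
    assert round(rep.exclusive_percentages[normal]) == 56
    assert round(rep.exclusive_percentages[disease]) == 5
    assert rep.overlap_count == 64 - 36 - 3

    # every state with Apoptosis ON is exclusively normal
    apop = stg.nodes.index("Apoptosis")
    for s in range(64):
        if (s >> apop) & 1:
            assert rep.reach_mask[s] == 1 << normal


def test_single_attractor_basin_covers_everything():
    net = parse_network("A* = B\nB* = 1 OR B\n")
    stg = build_stg(net)
    atts = attractors_from_stg(stg)
    assert len(atts) == 1
    rep = basin_partition(stg, atts)
    assert rep.exclusive_counts[0] == stg.n_states and rep.overlap_count == 0


# ---------------------------------------------------------------------------
# Absorption probabilities
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def six_node_chain(tlgl6):
    stg = build_stg(tlgl6)
    atts = attractors_from_stg(stg)
    rep = basin_partition(stg, atts)
    res = absorption_probabilities(stg, atts)
    return tlgl6, stg, atts, rep, res


def test_exclusive_basin_states_absorb_with_certainty(six_node_chain):
    _, stg, atts, rep, res = six_node_chain
    for j in range(len(atts)):
        for s in rep.exclusive_states(j):
            assert res.probability(int(s), j) == pytest.approx(1.0)


def test_rows_sum_to_one(six_node_chain):
    *_, res = six_node_chain
    assert np.allclose(res.probabilities.sum(axis=1), 1.0, atol=1e-10)


def test_three_states_reach_disease_at_printed_precision(six_node_chain):
    tlgl6, stg, atts, rep, res = six_node_chain
    disease = [
        j for j, a in enumerate(atts)
        if stg.state_string(a.states[0]) == "110000"
    ][0]
    high = {
        stg.state_string(int(s)): res.probability(int(s), disease)
        for s in rep.overlap_states()
        if round(res.probability(int(s), disease), 1) >= 0.7
    }
    assert set(high) == {"010000", "101000", "000000"}
    assert high["010000"] == pytest.approx(0.75)
    assert high["101000"] == pytest.approx(0.75)
    assert high["000000"] == pytest.approx(25 / 36)


def test_absorption_matches_dense_no_self_loop_chain(six_node_chain):
    # independent oracle: dense linear solve on the jump chain with
    # self-loops removed and rows renormalized; hitting probabilities are
    # invariant under that transformation
    tlgl6, stg, atts, _, res = six_node_chain
    n = stg.n_states
    fps = [a.states[0] for a in atts]
    P = np.zeros((n, n))
    for s in range(n):
        if s in fps:
            P[s, s] = 1.0
            continue
        targets = [t for t in stg.successors[s] if t != s]
        if not targets:
            P[s, s] = 1.0
            continue
        for t in targets:
            P[s, int(t)] += 1.0 / len(targets)
    # solve hitting probabilities for each fixed point by linear system
    for j, fp in enumerate(fps):
        A = np.eye(n) - P
        A[fp] = 0.0
        A[fp, fp] = 1.0
        b = np.zeros(n)
        b[fp] = 1.0
        for other in fps:
            if other != fp:
                A[other] = 0.0
                A[other, other] = 1.0
        h = np.linalg.solve(A, b)
        for s in res.transient_states:
            assert res.probability(int(s), j) == pytest.approx(h[s], abs=1e-9)


def test_absorption_agrees_with_monte_carlo(six_node_chain):
    tlgl6, stg, atts, rep, res = six_node_chain
    rng = np.random.default_rng(2024)
    fps = [a.states[0] for a in atts]
    n_runs = 4000
    for start in (0b000000, 0b000010, 0b000101):  # overlap states
        hits = np.zeros(len(fps))
        for _ in range(n_runs):
            s = start
            while s not in fps:
                s = int(stg.successors[s, rng.integers(stg.n_nodes)])
            hits[fps.index(s)] += 1
        for j in range(len(fps)):
            p = res.probability(start, j)
            se = max(np.sqrt(p * (1 - p) / n_runs), 1e-6)
            assert abs(hits[j] / n_runs - p) < 3.5 * se


def test_absorption_requires_fixed_points():
    net = parse_network("A* = NOT B\nB* = A\n")
    stg = build_stg(net)
    atts = attractors_from_stg(stg)
    with pytest.raises(ValueError, match="complex"):
        absorption_probabilities(stg, atts)
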