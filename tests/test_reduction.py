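"""Stabilization analysis, mediator elimination and back-substitution."""

import random

import pytest

from lglnet.dynamics import fixed_points_analytic
from lglnet.io import parse_network
from lglnet.logic import Const, parse_expression, truth_table_equal, write_expression
from lglnet.network import BooleanNetwork
from lglnet.reduction import (
    ReductionError,
    live_branch_steady_state,
    logical_steady_state,
    reconstruct_full_attractor,
    remove_mediators,
    remove_node_with_value,
    strip_apoptosis_clause,
)
from lglnet.synth import GeneratorConfig, random_network
from lglnet.tlgl import reduce_full_network, reduce_to_core

from conftest import attractor_states_bruteforce, fixed_points_bruteforce, free_view


# ---------------------------------------------------------------------------
# Death-clause stripping
# ---------------------------------------------------------------------------

def test_strip_death_clause(tlgl6):
    stripped = strip_apoptosis_clause(tlgl6)
    assert truth_table_equal(
        stripped.rules["DISC"],
        parse_expression("Ceramide OR (Fas AND NOT FLIP)", tlgl6.nodes),
    )
    # the output's own rule is untouched
    assert stripped.rules["Apoptosis"] == tlgl6.rules["Apoptosis"]


def test_strip_leaves_unrelated_rules_alone():
    net = parse_network("A* = B\nB* = A\nApoptosis* = A OR Apoptosis\n")
    stripped = strip_apoptosis_clause(net)
    assert stripped.rules["A"] == net.rules["A"]


def test_strip_requires_the_output_node():
    net = parse_network("A* = A\n")
    with pytest.raises(ReductionError, match="Apoptosis"):
        strip_apoptosis_clause(net)


# ---------------------------------------------------------------------------
# Logical steady state analysis
# ---------------------------------------------------------------------------

def test_lssa_chain_from_clamped_source():
    net = parse_network("#@ source Src = 1\nA* = Src\n")
    trace = logical_steady_state(net)
    assert trace.stabilized_values == {"A": 1}
    assert trace.residual.n == 0


def test_lssa_conflicting_clamp_errors():
    net = parse_network("#@ source Src = 1\nA* = Src\n")
    with pytest.raises(ReductionError, match="conflicting"):
        logical_steady_state(net, frozen={"Src": 0})


def test_lssa_full_network_stabilizes_36_nodes(tlgl60, tlgl18):
    trace = reduce_full_network(tlgl60)
    assert len(trace.stabilized) == 36
    assert trace.residual.n == 18
    values = trace.stabilized_values
    assert values["Proliferation"] == 0
    assert values["Cytoskeleton_signaling"] == 1
    # residual rules equal the bundled 18-node model
    assert set(trace.residual.nodes) == set(tlgl18.nodes)
    for name in tlgl18.rules:
        assert truth_table_equal(trace.residual.rules[name], tlgl18.rules[name]), name


def test_lssa_invariant_to_node_order(tlgl60):
    rng = random.Random(5)
    order = list(tlgl60.nodes)
    rng.shuffle(order)
    shuffled = BooleanNetwork(tuple(order), dict(tlgl60.rules), dict(tlgl60.frozen))
    a = live_branch_steady_state(tlgl60).stabilized_values
    b = live_branch_steady_state(shuffled).stabilized_values
    assert a == b


def test_stabilized_values_hold_in_every_attractor():
    # exhaustive check on small random networks with clamped sources
    for seed in range(12):
        net = random_network(
            GeneratorConfig(n_nodes=7, n_sources=2, seed=seed, self_loop_p=0.2)
        )
        trace = logical_steady_state(net)
        free = free_view(net)
        idx = {n: i for i, n in enumerate(free.nodes)}
        for att in attractor_states_bruteforce(net):
            for state in att:
                for name, value in trace.stabilized_values.items():
                    assert (state >> idx[name]) & 1 == value, (seed, name)


# ---------------------------------------------------------------------------
# Mediator elimination
# ---------------------------------------------------------------------------

def test_mediator_chain_collapses():
    net = parse_network("#@ source A\nB* = A\nC* = B\n")
    trace = remove_mediators(net, protected=("C",))
    assert [n for n, _, _ in trace.removed] == ["B"]
    assert write_expression(trace.residual.rules["C"]) == "A"


def test_self_loop_requests_are_skipped():
    net = parse_network("#@ source A\nB* = A OR B\nC* = B\n")
    trace = remove_mediators(net, protected=("C",), order=["B"], only_listed=True)
    assert trace.skipped == ("B",)
    assert trace.residual.n == 3


def test_constant_rules_are_rejected():
    net = parse_network("A* = 1\nB* = A\n")
    with pytest.raises(ReductionError, match="constant"):
        remove_mediators(net)


def test_published_reduction_reproduces_the_core(tlgl18, tlgl6):
    traces, core = reduce_to_core(tlgl18)
    assert set(core.nodes) == set(tlgl6.nodes)
    for name in tlgl6.nodes:
        assert truth_table_equal(core.rules[name], tlgl6.rules[name]), name
    removed = [n for t in traces for n, _, _ in t.removed]
    assert removed == [
        "sFas", "MCL1", "IAP", "GPCR", "SMAD", "CREB",
        "P2", "BID", "Caspase", "IFNG",
    ]


@pytest.mark.parametrize("criterion", ["and", "or"])
def test_fixed_points_preserved_under_reduction(criterion):
    # Naldi-style preservation: projections of full fixed points equal the
    # reduced model's fixed points — exhaustive oracle on random networks
    for seed in range(15):
        net = random_network(
            GeneratorConfig(n_nodes=8, n_sources=1, seed=100 + seed, self_loop_p=0.15)
        )
        free = free_view(net)
        lssa = logical_steady_state(free)
        trace = remove_mediators(lssa.residual, criterion=criterion)
        reduced = trace.residual
        keep = [free.nodes.index(n) for n in reduced.nodes]
        full_fps = [
            tuple((s >> i) & 1 for i in keep)
            for s in fixed_points_bruteforce(free)
        ]
        reduced_fps = [
            tuple((s >> i) & 1 for i in range(reduced.n))
            for s in fixed_points_bruteforce(reduced)
        ]
        assert sorted(full_fps) == sorted(reduced_fps), (seed, criterion)


# ---------------------------------------------------------------------------
# Reconstruction
# ---------------------------------------------------------------------------

def test_reconstruct_disease_and_normal_states(tlgl60):
    from lglnet.tlgl import full_fixed_points

    fps = full_fixed_points(tlgl60)
    normal, disease = fps["normal"], fps["disease"]
    assert tlgl60.is_fixed_point(normal)
    asg = tlgl60.assignment(disease)
    on = {n for n, v in asg.items() if v and n in tlgl60.rules}
    # mediator nodes recovered by back-substitution
    assert {"sFas", "GPCR", "S1P", "SMAD", "MCL1", "FLIP", "IAP"} <= on
    assert asg["Apoptosis"] == 0
    norm = tlgl60.assignment(normal)
    assert norm["Apoptosis"] == 1
    assert all(
        norm[n] == 0 for n in tlgl60.rules if n != "Apoptosis"
    )


def test_reconstruct_identity_for_empty_trace(tlgl6):
    from lglnet.reduction import ReductionTrace

    trace = ReductionTrace(inputs={}, stabilized={}, removed=(), residual=tlgl6)
    state = 0b100000  # 000001 rendering: Apoptosis ON
    assert reconstruct_full_attractor(trace, state, tlgl6) == state


def test_reconstruct_rejects_oscillatory_states():
    net = parse_network("A* = NOT B\nB* = A\n")
    from lglnet.reduction import ReductionTrace

    trace = ReductionTrace(inputs={}, stabilized={}, removed=(), residual=net)
    with pytest.raises(ReductionError):
        reconstruct_full_attractor(trace, 0b00, net)


def test_explicit_memory_node_removal():
    net = parse_network("#@ source S\nP* = P OR S\nQ* = NOT P\n")
    trace = remove_node_with_value(net, "P", 0)
    assert trace.removed[0][0] == "P"
    assert trace.removed[0][2] == "explicit"
    assert truth_table_equal(
        trace.residual.rules["Q"], parse_expression("NOT 0", ()),
    ) or write_expression(trace.residual.rules["Q"]) == "1"
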