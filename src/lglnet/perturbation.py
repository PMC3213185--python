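"""In-silico knockout / over-expression screening.

A *permanent* perturbation clamps one node to a fixed value (knockout = OFF,
over-expression = ON) and removes it from the update set, modeling a genetic
intervention; a *transient* perturbation flips a node's state once and lets
the dynamics continue, modeling a pharmacological pulse.

For each permanent perturbation of a survival network the screening
pipeline runs: live-branch logical steady state analysis → mediator
elimination → state-transition-graph attractor analysis of the residual,
then classifies the outcome by which attractors survive and whether the
apoptotic (output-ON) fixed point remains reachable from live-cell
(output-OFF) initial states:

``normal-only``
    every attractor has the output ON: the disease state is eliminated;
``disease-only``
    the output-ON fixed point is absent, or unreachable from any
    output-OFF state;
``both``
    otherwise; the exclusive basin of the normal fixed point (as a
    percentage of the reduced model's state space) quantifies the balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    Attractor,
    StateSpaceTooLarge,
    attractors_from_stg,
    basin_partition,
    build_stg,
)
from .logic import variables
from .network import BooleanNetwork, NetworkError
from .reduction import live_branch_steady_state, remove_mediators
from .structural import COMPLEMENT_PREFIX, ImportanceRecord

__all__ = [
    "Perturbation",
    "PerturbationOutcome",
    "apply_perturbation",
    "classify_outcome",
    "scan",
    "compare_structural_dynamic",
]

DEFAULT_OUTPUTS = ("Apoptosis", "Proliferation", "Cytoskeleton_signaling")


@dataclass(frozen=True)
class Perturbation:
    node: str
    value: int
    mode: str = "permanent-fix"  # or "transient-flip"

    def __post_init__(self) -> None:
        if self.mode not in ("permanent-fix", "transient-flip"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if self.value not in (0, 1):
            raise ValueError("perturbation value must be 0 or 1")


@dataclass(frozen=True)
class PerturbationOutcome:
    node: str
    value: int
    outcome: str  # normal-only | both | disease-only | incomplete
    normal_exclusive_pct: float
    n_free: int  # free nodes of the reduced perturbed model
    oscillating: tuple[str, ...] = ()
    n_attractors: int = 0


def apply_perturbation(
    network: BooleanNetwork, p: Perturbation, state: int | None = None
):
    """Apply a perturbation.

    Permanent fixes return a network with the node clamped (excluded from
    the update set).  Transient flips require an initial ``state`` and
    return ``(network, flipped_state)`` — the rules are unchanged, only the
    starting condition differs.
    """
    if p.node not in network.rules:
        raise NetworkError(
            f"cannot perturb {p.node!r}: not a regulated node (sources are "
            "clamped by the experimental condition, not perturbed)"
        )
    if p.mode == "permanent-fix":
        return network.with_frozen({p.node: p.value})
    if state is None:
        raise ValueError("transient-flip requires an initial state")
    return network, state ^ (1 << network.index(p.node))


def _oscillating_closure(
    residual_oscillating: set[str], removed: Sequence[tuple]
) -> set[str]:
    """Extend oscillation to eliminated mediators via their recorded rules."""
    osc = set(residual_oscillating)
    for name, rule, _kind in reversed(removed):
        if variables(rule) & osc:
            osc.add(name)
    return osc


def classify_outcome(
    network: BooleanNetwork,
    p: Perturbation,
    output: str = "Apoptosis",
    protected: Iterable[str] = DEFAULT_OUTPUTS,
    cap: int = 20,
    direct_limit: int = 16,
) -> PerturbationOutcome:
    """Classify a permanent perturbation by its surviving attractors.

    ``direct_limit`` is the free-node count up to which the residual's
    state transition graph is built without further reduction; larger
    residuals are shrunk by mediator elimination first (strict criterion,
    then the relaxed one) and flagged ``incomplete`` if they still exceed
    ``cap``.
    """
    if p.mode != "permanent-fix":
        raise ValueError("outcome classification applies to permanent fixes")
    perturbed = apply_perturbation(network, p)

    trace = live_branch_steady_state(perturbed, output=output)
    stabilized = trace.stabilized_values

    if output in stabilized:
        # the death clause propagation stabilizes everything once the
        # output commits, so a stabilized output means a single outcome
        if stabilized[output] == 1:
            return PerturbationOutcome(
                p.node, p.value, "normal-only", 100.0, 0, (), 1
            )
        return PerturbationOutcome(p.node, p.value, "disease-only", 0.0, 0, (), 1)

    residual = trace.residual
    protect = set(protected) | {output}
    # The state space of the stabilization residual is analysed directly
    # when it fits; mediator elimination (which preserves fixed points but
    # rescales basin percentages) is applied only as needed.
    reduced = residual
    removed: list[tuple] = []
    if reduced.n > direct_limit:
        for criterion in ("and", "or"):
            med = remove_mediators(
                reduced,
                protected=protect & set(reduced.nodes),
                criterion=criterion,
                ignore_regulators=(output,),
            )
            reduced = med.residual
            removed.extend(med.removed)
            if reduced.n <= direct_limit:
                break

    try:
        stg = build_stg(reduced, cap=cap)
    except StateSpaceTooLarge:
        return PerturbationOutcome(
            p.node, p.value, "incomplete", float("nan"), reduced.n, (), 0
        )
    attractors = attractors_from_stg(stg)
    out_idx = stg.nodes.index(output)

    def output_on(att: Attractor) -> bool:
        return all((s >> out_idx) & 1 for s in att.states)

    normal_ids = [j for j, a in enumerate(attractors) if output_on(a)]
    disease = [a for j, a in enumerate(attractors) if j not in normal_ids]

    osc_residual: set[str] = set()
    for att in disease:
        osc_residual.update(att.oscillating_nodes)
    oscillating = tuple(
        sorted(_oscillating_closure(osc_residual, removed))
    )

    if not disease:
        return PerturbationOutcome(
            p.node, p.value, "normal-only", 100.0, reduced.n,
            oscillating, len(attractors),
        )

    report = basin_partition(stg, attractors)
    normal_mask = sum(1 << j for j in normal_ids)
    states = np.arange(stg.n_states, dtype=np.int64)
    live = ((states >> out_idx) & 1) == 0
    if not normal_ids or not np.any(
        (report.reach_mask[live] & normal_mask) != 0
    ):
        return PerturbationOutcome(
            p.node, p.value, "disease-only", 0.0, reduced.n,
            oscillating, len(attractors),
        )

    mask = report.reach_mask
    exclusive_normal = int(
        np.sum(((mask & normal_mask) != 0) & ((mask & ~normal_mask) == 0))
    )
    pct = 100.0 * exclusive_normal / stg.n_states
    return PerturbationOutcome(
        p.node, p.value, "both", pct, reduced.n, oscillating, len(attractors)
    )


def scan(
    network: BooleanNetwork,
    disease_state: Mapping[str, int],
    output: str = "Apoptosis",
    outputs: Iterable[str] = DEFAULT_OUTPUTS,
    exclude: Iterable[str] = (),
    cap: int = 20,
) -> pd.DataFrame:
    """Systematic single-node perturbation scan.

    Every regulated, non-output node with a steady disease-state value is
    clamped to the opposite of that value (knockout for ON nodes,
    over-expression for OFF nodes) and classified.  ``disease_state`` maps
    node names to their value in the disease fixed point; nodes absent from
    it (oscillatory in the disease attractor) and nodes in ``exclude`` are
    skipped.  Returns one row per perturbed node, in network node order.
    """
    skip = set(outputs) | {output} | set(exclude)
    rows = []
    for name in network.nodes:
        if name not in network.rules or name in skip:
            continue
        if name not in disease_state:
            continue  # oscillates in the disease attractor
        value = 1 - int(disease_state[name])
        res = classify_outcome(
            network,
            Perturbation(name, value),
            output=output,
            protected=outputs,
            cap=cap,
        )
        rows.append(
            {
                "node": name,
                "disease_value": int(disease_state[name]),
                "perturbed_to": value,
                "outcome": res.outcome,
                "normal_exclusive_pct": res.normal_exclusive_pct,
                "n_free": res.n_free,
                "n_attractors": res.n_attractors,
                "oscillating": ",".join(res.oscillating),
            }
        )
    return pd.DataFrame(rows)


def compare_structural_dynamic(
    importances: Mapping[str, ImportanceRecord] | pd.DataFrame,
    outcomes: pd.DataFrame,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Sensitivity/specificity of the structural ranking vs the dynamic scan.

    The dynamic classification is the standard: a node is *important* when
    its perturbation leaves only the normal fixed point.  The structural
    classification calls a node important when the importance value of its
    candidate vertex (the original vertex for disease-ON nodes, the
    complementary vertex for disease-OFF nodes) exceeds the threshold.  The
    two analyses must cover the same candidate set.
    """
    if isinstance(importances, pd.DataFrame):
        imp_by_vertex = dict(
            zip(importances["vertex"], importances["importance"])
        )
    else:
        imp_by_vertex = {v: r.importance for v, r in importances.items()}

    nodes = list(outcomes["node"])
    wanted = {
        row["node"]: (
            row["node"]
            if row["disease_value"] == 1
            else COMPLEMENT_PREFIX + row["node"]
        )
        for _, row in outcomes.iterrows()
    }
    missing = sorted(set(wanted.values()) - set(imp_by_vertex))
    extra = sorted(set(imp_by_vertex) - set(wanted.values()))
    if missing or extra:
        raise ValueError(
            f"candidate sets differ; missing importance for {missing}, "
            f"unused importance for {extra}"
        )

    positive = {
        row["node"]: row["outcome"] == "normal-only"
        for _, row in outcomes.iterrows()
    }
    rows = []
    for thr in thresholds:
        tp = fn = tn = fp = 0
        for node in nodes:
            pred = imp_by_vertex[wanted[node]] > thr
            if positive[node]:
                tp += pred
                fn += not pred
            else:
                tn += not pred
                fp += pred
        rows.append(
            {
                "threshold": thr,
                "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
                "specificity": tn / (tn + fp) if tn + fp else float("nan"),
                "tp": tp,
                "fp": fp,
                "tn": tn,
                "fn": fn,
            }
        )
    return pd.DataFrame(rows)
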