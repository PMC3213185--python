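# Methods

## The model

The package centres on a 60-node Boolean model of T cell survival
signaling in T-LGL leukemia.  Six source nodes encode the experimental
condition and are clamped by default: antigen stimulation (`Stimuli`),
`IL15` and `PDGF` ON — the minimal dysregulation reproducing the disease —
and `Stimuli2`, `CD45` and the viral protein `TAX` OFF.  Every rule except
that of `Apoptosis` carries a trailing `AND NOT Apoptosis` *death clause*:
once programmed cell death commits, all signaling activity ceases.
`Apoptosis* = Caspase OR Apoptosis` makes death self-sustaining; this
self-loop is required for the apoptotic state to be a fixed point at all,
and it is what the reduced models inherit (`Apoptosis* = DISC OR
Apoptosis` in the 6-node core).

States are bit vectors over the declared node order, rendered leftmost =
first node, so the 6-node core's states read `S1P FLIP Fas Ceramide DISC
Apoptosis` (disease = `110000`).

The three fixtures are transcriptions of the published model at three
levels of reduction.  `tlgl18` and `tlgl6` are exactly what the package's
own reduction pipeline produces from `tlgl60`; the test suite asserts this
rule-by-rule (truth-table equality), which pins the transcription against
every quantitative checkpoint of the original analysis (node/edge counts,
stabilized set, fixed points, basin sizes, perturbation outcomes).

## Dynamics

**Update scheme.**  General asynchronous: each state has one labeled
successor per free node (clamped sources are substituted out of the
state space).  Self-transitions are retained as self-loop edges; they
carry no information for reachability and are dropped before computing
strongly-connected components.

**Attractors** are the terminal SCCs of the state transition graph,
computed with `scipy.sparse.csgraph`.  Fixed points are additionally
obtainable without the graph: below the state cap (default `2^20`) by a
vectorized check of `f_i(x) = x_i` over all states; above it by
backtracking over the Boolean equation system with constant propagation.
The suite cross-checks both routes against brute-force enumeration and
against a synchronous-update oracle (fixed points are update-scheme
independent).

**Basins.**  A state belongs to an attractor's *exclusive* basin when that
attractor is the only one reachable from it; attractor member states
therefore count toward their own exclusive basin (the published 56%/5%
figures for the 6-node core are 36/64 and 3/64 under exactly this
convention).  Reachability is computed exactly on the condensation DAG —
no trajectory sampling — so percentages are deterministic.

**Absorption probabilities** use the uniform chain (probability `1/f` per
node update, self-loops included) and solve `(I − Q)B = R` on the
transient states with sparse LU (a geometric fixed-point iteration takes
over above 10^5 states).  Hitting probabilities are invariant to removing
self-loops and renormalizing, which the tests exploit as an independent
dense oracle.  Of the 25 shared states of the 6-node core, exactly two
reach the disease state with probability 0.75 and one with 25/36 ≈ 0.694;
at the one-decimal precision of the published figure all three read 0.7,
and the acceptance test counts them at that printed precision.

## Reduction

**Logical steady state analysis** iterates constant substitution until no
rule collapses.  For the survival analysis it runs on the *live branch*:
the death clauses are stripped (`Apoptosis := 0` in every other rule)
before propagation, and the residual network is then rebuilt from the
original rules with the stabilized constants substituted, so the residual
keeps its death clauses.  Under the default inputs 36 of the 54 regulated
nodes stabilize, leaving the 18-node sub-network.

**Mediator elimination** removes nodes without self-loops that have at
most one regulator *and* at most one target (the strict reading of a
"simple mediator"; an OR variant — at most one of the two — is available
where a stronger, still fixed-point-preserving reduction is wanted).
In-degree counting can ignore designated regulators; the survival pipeline
ignores the ubiquitous `Apoptosis` clause, matching how the published
sub-network diagrams omit those edges.  Substitution can collapse a
downstream rule to a constant (a lagged pair such as `P27*=STAT3`,
`Proliferation*=STAT3 AND NOT P27` resolves to 0 at steady state); such
nodes join the stabilized set.  The node `P2` — a pure memory node whose
positive self-loop doubles the disease fixed point without biological
distinction — is never removed automatically; an explicit
`remove_node_with_value(net, "P2", 0)` eliminates it at its OFF
representative and records the choice in the trace.

**Reconstruction** extends a residual fixed point by the clamped inputs,
the stabilized values and the eliminated nodes' recorded rules in reverse
elimination order, then relaxes by synchronous sweeps until
self-consistent (needed because stabilized values are live-branch values,
while the apoptotic fixed point lies on the death branch).  The result
must verify as a fixed point and agree with the residual state; otherwise
the reduced state is oscillatory and the caller is directed to state
transition graph analysis.  The disease attractor of the full model is not
a fixed point — the TCR/CTLA4 receptor loop oscillates — so its
reconstruction clamps those two nodes and reports the steady projection.

## Perturbation screening

A permanent perturbation clamps one node to the opposite of its disease
value and removes it from the update set.  The pipeline per node:
live-branch stabilization → state transition graph of the residual →
attractor classification by the Apoptosis bit.  The residual is analysed
*directly* whenever it has ≤ 16 free nodes; mediator elimination is
applied only to squeeze larger residuals under the cap, because it
preserves fixed points but rescales basin percentages.  This reproduces
the published 72% normal basin for Fas-ON on the 6-node core (23/32
states); percentages for large-residual cases are reported on the
residual's own state space and can differ in scale from figures computed
on other reduced models, while the outcome *classes* (normal-only / both /
disease-only) are reduction-invariant.  "Disease-only" means the apoptotic
attractor is absent or unreachable from every biologically relevant
(Apoptosis-OFF) initial state.  Oscillating nodes are read off the complex
attractors and propagated to eliminated mediators through their recorded
rules.  The transient-flip mode (a one-step state flip) is provided for
completeness; on the core model only the trivial Apoptosis flip escapes
the disease state, and it is excluded from outcome classification.

## Expanded network and the SP measure

Expansion canonicalizes each rule to OR-of-ANDs, adds a composite vertex
per multi-literal clause and a complementary vertex `~v` per negated
literal; `~v`'s inputs encode the negated rule.  Two wiring depths are
provided.  *Recursive* closure is the literal reading of the construction
but nests negations of negations; on the 60-node model it inflates
input–output simple paths into the tens of millions, far beyond anything
a path-level essentiality ranking can use.  The shipped default is
therefore *first-order*: only complements demanded by the original rules
(plus requested outputs such as `~Apoptosis`, which also admits the
complements its own negated rule needs — here `~Caspase`) exist, and
negated-rule clauses that would require any other complement are dropped.

For the survival analysis the death clauses are stripped, the OFF-clamped
sources are substituted away, and the ON-clamped sources are kept as
vertices: they are constitutively available signals, and substituting them
would erase structurally real alternatives (e.g. it would collapse the GAP
and SOCS rules to constants and remove their complements from the
candidate set entirely).  Paths are counted from the single free input
PDGF to `~Apoptosis` by DFS with on-path marking (exact, memory linear in
the vertex count).  Under this convention the fourteen top-ranked
candidate vertices — ~DISC, ~Ceramide, ~Caspase, SPHK1, S1P, PDGFR, PI3K,
~SOCS, JAK, ~GAP, RAS, NFKB, MEK, ERK — all score importance ≥ 0.95,
matching the published ranking's head.

**Known limitation.**  Absolute path totals are extremely sensitive to the
wiring convention and to the exact clause structure of the source rules;
the published totals (78,827 and 346,974) are not reproduced by any
convention expressible from the rule semantics alone — the conventions
explored here bracket them from both sides — and the downstream
sensitivity/specificity point (1.00/0.76 at threshold 0.9) inherits that
dependence.  The corresponding acceptance tests assert the published
numbers and fail under this implementation; the relative ranking, the
≥ 0.95 head of the candidate list, and every dynamic quantity are
reproduced exactly.

## Synthetic data

The generator draws rules directly in canonical OR-of-ANDs form over
bounded regulator sets (default max in-degree 3, ≤ 2 clauses), with
per-literal inhibition probability 0.3, optional self-loops (probability
0.1) and clamped random sources — the structural features the reduction
and dynamics machinery assumes, at property-test scale (n ≤ 12, where
exhaustive oracles are feasible).  Identical seeds give byte-identical
networks.  It emulates curated models' sparse logic, not their degree
distributions or motif enrichment, so passing property tests certify the
algorithms' correctness contracts (fixed-point preservation, oracle
equality, confluence), not biological realism.  Canned motifs (toggle
switch, two-node negative feedback, self-activation, chains) pin the
qualitative attractor classes: positive feedback for multistability,
negative feedback for sustained oscillation.

## Numerical choices

Canonical forms sort literals and clauses lexicographically; only constant
propagation, idempotence, complement laws and absorption are applied (no
full minimization), keeping forms deterministic and the Table-level rule
reproductions exact.  State caps default to `2^20` states for graph
construction; the direct-analysis threshold for perturbation residuals is
`2^16`.  Absorption solves are validated to a residual of `1e-10`.
Percentages are compared at the precision the published analysis prints:
integers for basin percentages, two decimals for the sub-percent disease
basins, one decimal for absorption probabilities.
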