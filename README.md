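# lglnet

Boolean dynamic and structural analysis of the T-cell large granular
lymphocyte (T-LGL) leukemia survival signaling network — and of logical
models of signal transduction in general.

T-LGL leukemia is a clonal disease of cytotoxic T lymphocytes (CTLs) that
fail to undergo activation-induced cell death after an immune response.
The survival signaling circuitry behind this failure has been assembled as
a 60-node Boolean network: each component `v_i` (protein, mRNA or small
molecule) is ON or OFF, and its next state is given by a logical rule
`v_i* = f_i(u_{i1}, …, u_{ik})` over its regulators, e.g.

```
S1P*  = NOT (Ceramide OR Apoptosis)
DISC* = (Ceramide OR (Fas AND NOT FLIP)) AND NOT Apoptosis
```

Under general-asynchronous (GA) updating — one randomly chosen node
updated per step — the model's long-term behaviours are the attractors of
a nondeterministic state transition graph over the `2^n` states: a
*normal* fixed point in which Apoptosis is ON, and a *disease* (T-LGL)
state in which survival signaling locks itself on.  This package
implements the full analysis tool-chain around that model:

* **logic_core / netio** — rule parsing (`NOT > AND > OR`), canonical
  OR-of-ANDs forms, rule files, and the three bundled T-LGL fixtures
  (`tlgl60`, `tlgl18`, `tlgl6`);
* **reduction** — logical steady state analysis (constant propagation from
  clamped inputs) and simple-mediator elimination, which together shrink
  the 60-node model to an exactly analysable 6-node apoptotic core while
  preserving fixed points, plus back-substitution to recover full states;
* **dynamics** — exact GA state transition graphs, attractor detection via
  terminal strongly-connected components, exclusive-basin partitions by
  graph reachability, and Markov-chain absorption probabilities
  (probability `1/f` per node update);
* **structural** — the expanded network (complementary `~v` vertices for
  negative regulation, composite vertices for AND clauses), cascading
  deletion, simple-path (SP) counting, and importance values
  `I_v = 1 − N_SP(G_Δv) / N_SP(G_exp)`;
* **perturbation** — systematic knockout / over-expression screening with
  outcome classification (normal-only / both / disease-only) and the
  structural-vs-dynamic sensitivity/specificity comparison;
* **synthetic_data** — a seeded random Boolean network generator and
  canned motifs used by the property-based test suite.

## Worked example

```python
from lglnet import (load_fixture, build_stg, attractors_from_stg,
                    basin_partition, absorption_probabilities)

core = load_fixture("tlgl6")            # S1P, FLIP, Fas, Ceramide, DISC, Apoptosis
stg = build_stg(core)                   # 64 states, 6 labeled edges each
atts = attractors_from_stg(stg)
for a in atts:
    print(a.state_strings()[0], "fixed point" if a.is_fixed_point else "complex")

rep = basin_partition(stg, atts)
print([round(p) for p in rep.exclusive_percentages], rep.overlap_count)
```

prints

```
110000 fixed point
000001 fixed point
[5, 56] 25
```

i.e. the apoptotic core has exactly two fixed points — `000001` (normal:
only Apoptosis ON) and `110000` (disease: S1P and FLIP ON, death pathway
silent) — whose exclusive basins cover 5% and 56% of the 64-state space,
with 25 states from which both outcomes remain reachable.  Absorption
analysis of those 25 shared states shows the normal fate is the more
probable one from all but three of them.

The same pipeline from the shell:

```bash
lglnet attractors -n tlgl6
lglnet basins -n tlgl6
lglnet perturb -n tlgl6 --node Fas --value 1
#  Fas=1   both    normal exclusive basin 71.9%   oscillating: -
lglnet perturb-scan --out scan.tsv        # all 49 eligible nodes of tlgl60
```

The full-network scan classifies exactly 15 interventions (e.g. STAT3 or
SPHK1 knockout, Ceramide or DISC over-expression) as *normal-only*: they
abolish the disease state entirely and are the model's candidate
therapeutic targets.

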