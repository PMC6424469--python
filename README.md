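# multimotif

Tools for finding and analyzing the transcriptional network motifs that
generate **four-attractor ("stepwise") cell-fate transition systems**, and
for characterizing a four-factor model of early T-cell commitment through
bifurcation analysis, quasi-potential landscapes and minimum action paths.

## The scientific problem

Many differentiation programs pass through a series of discrete,
*individually stable* intermediate states: in early T-cell development the
progression ETP/DN1 → DN2a → DN2b → DN3 is driven by Notch signaling and
accompanied by stepwise changes of the core factors PU.1 (down) and TCF-1,
GATA3, BCL11B (up). A dynamical system reproducing this needs **four
coexisting stable steady states whose TF levels are monotonically coupled**
("ordered" attractors). This package asks, and answers computationally,
which small gene regulatory networks can do that and why the transitions
between the states are irreversible.

Gene dynamics are modeled with Hill-function ODEs. Each TF follows

    dX_i/dt = k0_i + k_i * R_i(X) - rd_i * X_i

where `R_i` combines the regulators' Hill factors additively (weighted by
`beta_ij`) or multiplicatively; an activator contributes
`(X_j/K_ij)^n_ij / (1 + (X_j/K_ij)^n_ij)` and an inhibitor
`1 / (1 + (X_j/K_ij)^n_ij)`.

The main components:

* **Enumeration and screening** (`enumeration`): exhaustive generation of
  all 3-node topologies with up to 6 regulations (465 templates, 12,258
  signed networks, 2,114 relabeling classes), random parameter screening
  with Latin-hypercube initial conditions, and classification of
  four-attractor hits as ordered/unordered.
* **Motif analysis** (`motifs`): positive feedback loop (PFL) enumeration;
  Type I motifs (three PFLs sharing a TF), Type II motifs (two disjoint
  PFLs bridged by a third), complexity atlases and minimum topologies.
* **Enrichment** (`enrichment`): empirical motif-enrichment p-values
  against two randomization schemes (regulation permutation, independent
  random pairs).
* **T-cell model** (`tcell`): a packaged synthetic four-TF model (PU.1,
  TCF-1, GATA3, BCL11B + a Notch drive) that is quadristable at zero
  Notch, loses its states through three saddle-node bifurcations as Notch
  rises, and collapses to an ETP/DN2a bistable switch under *Bcl11b*
  knockout; pulse-response grids and fluctuating-signal simulations.
* **Landscapes and paths** (`landscape`): self-consistent mean-field
  quasi-potential `U = -ln Pss` from diagonal moment equations
  (`sigma_i* = -D / A_ii` per attractor), Freidlin–Wentzell minimum action
  paths `S_T = 1/2 ∫ |dphi/dt - F(phi)|^2 dt`, path discretization and
  transition-action sensitivity.
* **Performance comparison** (`compare`): quasi-steady-state reduction to
  an effective PU.1 production curve and differential-evolution fitting to
  a seven-crossing surrogate target.

## Worked example

```python
>>> import numpy as np
>>> from multimotif.tcell import tcell_model, stage_attractors, scan_bifurcation
>>> tm = tcell_model()                      # packaged synthetic fixture
>>> aset, labels = stage_attractors(tm, N=0.0, seed=2)
>>> for lab, s in sorted(zip(labels, aset.stable_states), key=lambda z: -z[1][0]):
...     print(f"{lab:5s} PU1={s[0]:.2f} TCF1={s[1]:.2f} GATA3={s[2]:.2f} BCL11B={s[3]:.2f}")
ETP   PU1=2.49 TCF1=0.17 GATA3=0.06 BCL11B=0.06
DN2a  PU1=2.49 TCF1=1.51 GATA3=0.53 BCL11B=0.06
DN2b  PU1=0.90 TCF1=2.00 GATA3=1.98 BCL11B=1.53
DN3   PU1=0.35 TCF1=2.00 GATA3=2.02 BCL11B=1.53
>>> br = scan_bifurcation(tm, "N", np.linspace(0, 1.2, 25), seed=4)
>>> [round(v, 3) for v in br.saddle_nodes]
[0.131, 0.18, 0.24]
```

The four rows are the stable states at zero Notch: PU.1 falls strictly and
the three T-lineage factors rise monotonically along the stage sequence —
the stepwise ("ordered") pattern. The three saddle-node values are the
Notch levels at which ETP, DN2a and DN2b successively lose stability; past
the last one only DN3 remains, which is why commitment is irreversible.

A command-line interface mirrors the library:

```bash
multimotif enumerate --n-nodes 3 --max-regulations 6
multimotif tcell attractors -N 0
multimotif tcell bifurcation --control N --hi 1.2
multimotif map --from ETP --to DN3
multimotif enrich net.json --scheme random_pairs --n-networks 1000 --seed 1
```

## Fixtures are synthetic

The packaged T-cell model and the minimum-motif parameter sets were
constructed by this package's own searches (random sampling plus annealed
refinement under the four-ordered-attractor, bifurcation and knockout
selection criteria). They are labelled synthetic in their filenames and
are not transcriptions of any published parameter table. See
`docs/methods.md` for the construction procedure and its limitations.
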