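# Methods

## Model form and conventions

TF dynamics follow Hill-function ODEs,
`dX_i/dt = k0_i + k_i R_i(X) - rd_i X_i`, with `R_i` either the
`beta`-weighted sum or the product of the regulators' Hill factors
(activator `u/(1+u)`, inhibitor `1/(1+u)`, `u = (X_j/K_ij)^n_ij`).
A node with no regulators has `R_i = 0` in both forms, so an isolated
gene relaxes linearly to `k0/rd`. External signals (Notch) enter as an
*additive* production drive `k_s u_s/(1+u_s)` on their target; a
multiplicative activator gate would zero its target's regulated
production at zero signal and destroy the signal-free attractor
structure, so the additive form is the only self-consistent choice for
an input that must vanish at baseline.

Units: all parameters are dimensionless; one time unit corresponds to
roughly six hours of real time, so a TF half-life of about four hours
gives the default degradation rate `rd = ln 2/(4/6) ≈ 1.04` used in the
packaged fixtures.

Concentrations are non-negative; the right-hand side raises on negative
inputs and integrator callbacks clip at zero (production terms are
bounded, so trajectories started in the positive orthant stay there up
to integrator round-off).

## Attractor search and classification

`find_attractors` integrates from 125 Latin-hypercube initial
conditions in `(0, 3.3)^d` (scipy LSODA with the analytic Jacobian) to
`t = 500`, treats endpoints with `||RHS||_inf < 1e-3` as stabilized,
polishes them by Newton iteration to `||RHS||_inf < 1e-6`, merges
duplicates within a relative Euclidean tolerance of `1e-2`, and decides
stability from the Jacobian eigenvalues (strictly negative real parts;
a zero real part is reported unstable with a marginality flag).
Endpoints that fail to stabilize are screened for sustained
oscillations: the peak-to-peak amplitude over the final 10% of the
time span must exceed `1e-2`.

Four stable states are *ordered* when some arrangement makes every TF
non-strictly monotone with at least one strictly monotone TF — the
stepwise pattern in which any two TFs are monotonically coupled across
the states. The decision scans all 24 arrangements.

`find_fixed_points` complements this with multi-start Newton root
finding, which also recovers saddles; it is the workhorse for
phase-plane structure (the minimum motifs have seven steady states,
four of them stable) and for bifurcation branches.

## Enumeration, screening and motifs

Topology spaces are enumerated exactly: unsigned templates (subsets of
the `n^2` ordered pairs), signed networks (`2^r` per template), and one
canonical representative per node-relabeling class. The canonical key
is the lexicographic minimum over node permutations of the flattened
signed adjacency string; signs are never permuted. For 3 nodes and up
to 6 regulations this gives 465 / 12,258 / 2,114; the 11-regulation
T-cell network has 2,047 subnetworks in 1,553 classes.

Screening draws uniform parameter sets from configurable ranges
(defaults: `k0 ∈ [0, 0.3]`, `k ∈ [0.3, 3]`, `rd ∈ [0.3, 1.5]`,
`K ∈ [0.1, 3]`, `n ∈ [1, 6]`, `beta ∈ [0.5, 2]`; chosen to span the
unit-scale state box — the published sampling ranges for this problem
class live in supplementary material we do not redistribute, so exact
reproduction of published screening counts would require substituting
those ranges in a range config). A hit requires exactly four stable
states and no oscillation flag; sets with five or more stable states
are logged separately. All randomness derives from one master seed
through named substreams (topology key, purpose), which makes
screening results independent of worker count and resumable from
JSON-lines checkpoints.

A positive feedback loop is a simple directed cycle with an even
number of inhibitions; self-activations count as length-1 PFLs. Motif
predicates act on node sets of PFL triples: Type I — non-empty triple
intersection; Type II — two disjoint loops that both intersect the
third. Instances are counted as unordered tuples of distinct PFLs.
Complexity-atlas edges connect topologies whose signed regulation sets
differ by exactly one regulation (a sign flip is distance two);
minimal topologies are capable topologies none of whose
single-regulation-removal children is capable, with unknown children
reported as undecided rather than silently non-minimal.

## The synthetic T-cell fixture

The packaged model (`data/tcell_model_synthetic.json`) is a
reconstruction, not a transcription. The 11-edge topology was selected
by requiring (a) every regulation to be individually documented in the
early T-cell literature — PU.1 auto-activation, PU.1 ⊣ TCF-1,
PU.1 ⊣ GATA3, GATA3 ⊣ PU.1, BCL11B ⊣ PU.1, TCF-1 auto-activation,
TCF-1 → GATA3, GATA3 auto-activation, TCF-1 → BCL11B, GATA3 → BCL11B,
BCL11B auto-activation — and (b) the 2,047 regulation subsets to fall
into exactly 1,553 relabeling classes, which pins the edge multiset.
Notch enters solely as an additive drive on TCF-1 (37 free parameters
in total), so every downstream response saturates with the TCF-1
level; this is what keeps the knockout model monostable at strong
signal.

Parameters were found by the package's own machinery: random sampling
seeded a simulated-annealing refinement whose score demanded, at zero
Notch, exactly four stable states among seven steady states with the
stepwise ordering (TCF-1 crossing its min–max midpoint at the first
stage step and GATA3 at the second); a monotone 4→3→2→1 stable-count
profile along Notch; and, under BCL11B knockout (`k = k0 = 0`),
exactly two states at zero Notch with a single saddle-node in Notch.
Three hand-derived constraints were imposed after the search exposed
the corresponding failure modes: the BCL11B self-activation threshold
sits near its basal level (`K_BB = 0.13`) so the off-branch can be
forced through a fold by the opening GATA3 gate (otherwise a
BCL11B-low state persists at every Notch level); GATA3's repression of
PU.1 is weak (`K = 4.5`) so GATA3 alone can never silence PU.1
(otherwise knockout models develop spurious committed states); and
PU.1's basal level sits at the knee of its self-activation
(`k0/rd ≈ 0.32` vs `K_PP ≈ 0.6`), so PU.1 silencing is reversible
exactly when BCL11B is absent. The mechanism of quadristability is a
TCF-1 bistable switch (ETP → DN2a), a joint GATA3/BCL11B/PU.1 cascade
flip (DN2a → DN2b) and a PU.1 on/off switch under combined
GATA3+BCL11B repression (DN2b → DN3).

Stage labels: with four stable states, rank along the monotone
ordering (PU.1 descending); with fewer, nearest reference attractor in
log-concentration space (floor `1e-3`), the reference set being the
four zero-Notch states. Knockout semantics zero both the regulated and
the basal production (switchable).

Bifurcation scans are brute-force continuations: at each control value
all fixed points are recomputed by multi-start Newton seeded with the
previous grid point's branch points; saddle-node events are localized
by bisection on the stable-state count to `1e-4` in the control.

## Landscapes and minimum action paths

Around each attractor the diagonal moment equations
`dsigma_i/dt = 2 A_ii sigma_i + 2D` give the stationary variance
`sigma_i* = -D/A_ii` (exact for linear drift). The steady-state
density is the weighted mixture of the per-attractor axis-aligned
Gaussians and `U = -ln Pss`. Mixture weights default to the empirical
basin counts of the 125-start attractor search; equal weights are an
option. The default diffusion is `D = 0.01`; grids span
`[min(0, mean - 8 sd), 1.2 x max coordinate]` with 100 points per axis
(the sub-zero extension keeps the full Gaussian mass of components
near the axes on the grid — it is the approximation's support, not a
physical concentration). Because the mixture is separable, dense
arrays are only materialized for 1D/2D views and projections
marginalize by per-axis trapezoid integration.

The Freidlin–Wentzell action is discretized with segment midpoints:
`S = sum 1/2 |Δphi/Δt - F(midpoint)|^2 Δt`. Minimum action paths fix
both endpoints, start from the straight line, and are optimized with
L-BFGS-B using the analytic action gradient (Jacobian-vector products)
under non-negativity bounds, over a ladder of horizons (default
T ∈ {20, 50, 100}; T ∈ {40, 80} in the T-cell tests, where the
minimizing horizon is the largest offered). For a 1D gradient flow the
uphill action converges to twice the barrier height, which the tests
verify to 2% on a double well; on-flow paths cost below `1e-6` at fine
discretization.

Path discretization min–max normalizes each TF along the path and bins
into equal-width levels; the switching order is the sequence of first
midpoint crossings. Transition-action sensitivity multiplies one
parameter at a time by `1 ± delta` (default 1%), re-finds the
attractors (perturbations that break quadristability are excluded, not
plotted) and reports the percent change of the requested transition
actions.

## Enrichment and performance comparison

Null ensembles: *permute_regulations* reassigns each regulation to a
uniformly random unoccupied ordered pair (self-pairs included,
rejection on collisions), preserving the count and sign multiset;
*random_pairs* assigns +/−/none with probability 1/3 to every ordered
pair. Empirical p-values are right-tail counts `P(null >= observed)`,
reported as `< 1/N` when no null network reaches the observed count;
no smoothing is applied.

The performance comparison reduces a PU.1-centred circuit to one
effective ODE by fixing PU.1, relaxing the other TFs to their (lowest)
steady state along a continuation in PU.1, and reading off the
production term. The surrogate target is a basal rate plus three sharp
Hill steps that crosses the linear degradation line seven times with
alternating stability (four attractors). Circuits are fitted by
scipy's differential evolution over the regulation shapes; the
comparison of interest is the ordering of best-SSD distributions
between a circuit embedding several shared-node motif copies and its
single-motif counterpart, not absolute SSD values.

## The minimum-motif fixture

The 3-node minimum-motif models (`data/minimum_motifs_synthetic.json`)
were generated in two stages. Structural stage: among the 2,114
canonical topologies, keep those containing a Type I or Type II motif
whose every single-regulation-removal child contains neither — 32
candidates (18 Type I, 14 Type II; the motif is necessary for
four-attractor capability, so structural minimality is necessary for
dynamical minimality). Parameter stage: for each candidate, random
sampling from the default ranges seeds an annealed search scored
toward exactly seven steady states with four stable, ordered
attractors; accepted parameter sets must additionally verify robustly
— the same seven-state structure recovered from a dense deterministic
lattice of Newton starts over the full steady-state range at several
multistart seeds, and an ordered four-attractor outcome of the
125-start search at two seeds. 26 of the 32 candidates (13 Type I, 13
Type II) yielded such a parameter set within the search budget;
structural motif presence does not guarantee a realizable
four-attractor regime, and notably all three 6-regulation Type I
candidates resisted, consistent with part of the Type I structural
surplus over the dynamically capable set being incapable.

## What the synthetic fixtures do and do not show

Passing tests on these fixtures demonstrate that the package's
*methods* — screening, classification, bifurcation analysis,
landscapes, action minimization, enrichment — behave correctly on
systems engineered to have the qualitative structure the biology
demands. They do not reproduce any published parameter values, and
quantitative outputs tied to parameters (fold positions, action
values, sensitivity magnitudes) are properties of the synthetic models
only. One known quantitative compromise: in the packaged T-cell model
the ETP → DN2a transition barely engages the PU.1 → GATA3 threshold,
so that parameter's transition-action sensitivity has the expected
sign but near-zero magnitude; and ETP/DN2a share nearly identical
PU.1/BCL11B levels, so the BCL11B × PU.1 landscape projection shows
three separated basins rather than four (TCF-1 × PU.1 and
GATA3 × PU.1 show all four).

## Problem sizes

The default test and acceptance runs use desk-scale sizes chosen as
the package's own defaults: 125 Latin-hypercube starts, 25-point
bifurcation grids, 100-point paths, 8 x 8 signal grids, 20
fluctuating-signal replicates, 10^3-network enrichment ensembles and
single-digit optimization runs. Full-scale screening (10^6 parameter
sets per topology across thousands of topologies) is cluster work and
is exposed through `run_screen`'s worker/checkpoint machinery rather
than exercised in the test suite.
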