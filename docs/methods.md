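# Methods

This note documents the models, conventions and numerical choices behind
`rsnet`, and what its synthetic-data tests do and do not establish.

## Synthetic cohort model

Each subject-phase series is drawn from a zero-mean multivariate normal
whose correlation matrix is block-constant over a planted partition of
the N parcels: `rho_within` (default 0.4) inside a module, `rho_between`
(default 0.1) across modules. Positive definiteness is verified by
Cholesky factorization at configuration time; violating combinations are
rejected naming the offending values. Temporal dependence comes from a
shared AR(1) filter (coefficient 0.3) applied identically to every
column, which leaves cross-column correlations untouched while giving
columns the slow, autocorrelated character of BOLD. Defaults mirror the
reference design: 57 + 62 subjects, two phases each, 200 samples at
TR = 2.5 s, 90 parcels, 5 near-equal modules (about the scale of
canonical resting-state communities).

Nuisance realism: six smoothed random-walk "motion" traces and two slow
sinusoid-plus-noise "WM/CSF" signals are mixed into the series with
per-parcel Gaussian loadings of scale 0.2, so the cleaning stage has
genuine structure to remove. Covariates (estradiol, progesterone,
testosterone, state/trait anxiety, Beck anxiety/depression) are drawn
per group × phase from normal distributions with the published means and
SDs, hard-clipped to instrument ranges (hormones ≥ 0, STAI 20–80, Beck
scales 0–63). Clipping, not resampling, is used: the one-sided truncation
shifts means by well under the reporting precision at these parameter
values.

What the generator does **not** emulate: volumetric imaging and its
artifacts, physiological (cardiac/respiratory) noise, motion spikes
requiring scrubbing, spatial autocorrelation between parcels, and any
empirically realistic effect size for group differences in connectivity
(no such estimate exists to copy; injected effects via `EffectSpec` are
user choices). Passing recovery tests therefore shows the pipeline is
correct and well-calibrated under its stated model — not that real PDM
cohorts would behave this way.

All randomness flows from a single seed through named
`numpy.random.SeedSequence` derivations (per subject-phase stream, per
stage in the pipeline); identical configs give bit-identical outputs.

## Cleaning

Order: detrend → nuisance regression → band-pass, each per parcel.
Detrending removes the least-squares line; the nuisance regression is
OLS with an intercept always included (mean removal is implied by the
later correlation step) and rejects rank-deficient regressor sets naming
the collinear columns. The band-pass is a zero-phase forward–backward
Butterworth, order 2 per pass, 0.01–0.08 Hz; zero phase matters because
phase shifts would distort interregional correlations. Even-reflection
edge padding is used: with records as short as T = 200, the default
odd-reflection padding leaks filter transients that swamp the stopband
attenuation. Detrending is linear only — a deliberate, flagged choice
rather than a guess at higher polynomial orders. Global-signal
regression is intentionally not implemented.

## Network construction

Edge weights are |atanh(r)|; the sign of r is retained in the
`ConnectivityMatrix` for audit but never used downstream. Perfect
correlations (|r| = 1) are rejected rather than clipped, naming the
parcel pair. Thresholding is backbone-first: the maximum-total-weight
spanning tree (Kruskal over descending weights) guarantees a connected,
acyclic skeleton, then non-tree edges join in descending weight order
until the edge count reaches `round_half_up(cost · N(N−1)/2)`. The
half-up rounding rule and the tie-break among equal weights —
lexicographic by (smaller index, larger index) — are conventions chosen
for determinism and stated here because no standard fixes them. Because
every cost level shares one backbone and one ranking, networks over a
grid are nested, which in turn makes global efficiency monotone in cost.

## Graph metrics

Binary clustering is Watts–Strogatz; weighted clustering is the Onnela
geometric-mean triangle formula with weights normalized by the network
maximum (the convention of the standard brain-connectivity toolchain).
Weighted shortest paths use edge length 1/weight (Dijkstra). Local
efficiency of a node is the global efficiency of its neighbor-induced
subgraph, using the same mode's distances; degree counts links in both
modes. Small-world σ uses degree-preserving double-edge-swap nulls
(default 100 nulls, 10·|E| swap attempts each) with windowed
connectivity checking: swaps are applied in windows of |E|/10 and a
window is rolled back if it disconnected the graph, so nulls keep both
the degree sequence and connectedness. Graphs with no admissible swap
(complete graphs) are returned unchanged with a warning, making σ = 1
exactly in that degenerate case.

## Modular structure and similarity

Partitions come from Louvain (networkx implementation) with resolution 1
and 20 seeded restarts, keeping the best Newman–Girvan Q (weighted
generalization in weighted mode); module ids are canonicalized to
first-appearance order so partitions compare stably. NMI uses the
average-entropy normalization 2I/(H1+H2); two trivial one-module
partitions are defined as identical (NMI 1). Phi similarity for a node
of interest correlates the two subjects' binary "shares the NOI's
module" vectors; pairs where either vector is constant are undefined and
are excluded from averages (counted and warned, never imputed).

The permutation test statistic is the pooled mean of within-group
pairwise similarities (both groups pooled, weighted by pair counts).
Each of the default 10,000 permutations shuffles group labels;
p = #{permuted > observed}/n_perm with strict exceedance, exactly as
defined — a consequence is that fully tied similarity structures give
p = 0, an edge case documented in the tests. An optional add-one
correction exists but is off by default.

## Mixed models

With exactly two occasions per subject, the "unstructured" covariance is
the saturated 2×2: occasion-specific variances plus a free covariance,
parametrized as (log σ₁, log σ₂, atanh ρ) and fitted by REML
(Nelder–Mead on the profiled restricted likelihood; fixed effects then
come from GLS at the optimum). Subjects missing a phase are dropped.
Covariates enter phase-specific (they are measured per phase) and
mean-centered. Wald t tests use model-based standard errors with
df = n_subjects − n_fixed_effects — a deliberately simple rule, logged
on every result; null simulations in the test suite confirm type-I
control near the nominal 5% at the cohort sizes used. On non-convergence
the result is flagged and the starting-value covariance (equal
variances, zero correlation) is reported rather than silently trusted.

BH-FDR is applied across nodes within each cost level only; cost levels
are left uncorrected, matching the analysis design this package
implements. The minimal-detectable-effect solvers invert the noncentral-t
power function by bisection (Brent) and round half-up to two decimals for
reporting; full precision is available with `decimals=None`.

## Problem sizes in tests

The test suite exercises scaled-down configurations chosen to probe each
property at the smallest size where it is informative: oracle
equivalence enumerates all 112 connected graphs on ≤ 6 nodes (up to
isomorphism) and exhaustive spanning-tree search up to N = 7;
connectedness runs 100 subjects over the full 38-level grid;
small-worldness samples 6 cost levels with 10 nulls each; calibration
uses 500 permutation-test runs (200 permutations, 10+10 subjects) and
1,000 mixed-model null fits (20+20 subjects). The demo pipeline config
(4+4 subjects, 30 parcels, 3 costs) is a smoke-scale illustration, not a
powered analysis.

## Known limitations

- The spanning-tree backbone is the maximum-weight spanning tree; the
  iterative per-node strongest-edge "local thresholding" description it
  formalizes could differ on adversarial inputs, though both guarantee
  connectedness.
- Degrees of freedom for Wald tests are not Satterthwaite/Kenward–Roger;
  at very small cohort sizes the simple rule may run conservative.
- The weighted local-efficiency variant evaluates plain efficiency on
  the neighbor subgraph; other toolboxes use triangle-weighted variants.
- Louvain is a heuristic: Q is a lower bound on the optimum (verified
  exact on small graphs by exhaustive partition search in tests).
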