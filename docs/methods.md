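# Methods

`tautraj` analyses a proteins × samples table of log2 MS intensities from
AT8-stratified neurons (single cells or pools) and orders the molecular
response to tau accumulation. This note records the models, the defaults
and why, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate.

## Data model

A `ProteomeMatrix` couples the value table with an explicit detection mask
(what was measured before imputation) and sample metadata (donor, pTau
status, capture type). Observed values are never altered by any
preprocessing step; imputation only fills gaps and flags them in a separate
mask, so "detected" always means measured. Plain TSV is the interchange
format; orientation on read is resolved by matching one axis against the
metadata sample ids and an ambiguous file is an error rather than a guess.

## Preprocessing

Steps run in a fixed order: contaminant removal (id prefix `Cont_`) →
detection filter → cell filter → imputation.

- **Detection filter.** A protein is kept when detected in at least
  `min_frac` of samples in *either* pTau group (inclusive ≥). Defaults:
  0.30 for single cells, 0.70 for mini-pools. Filtering before imputation
  is deliberate — imputation must not rescue proteins.
- **Cell filter.** Samples with fewer than 1,000 detected proteins are
  dropped (strict <), then samples whose observed tau lies below the 5th
  percentile of observed tau across the *remaining* samples. The
  protein-count filter runs first; both the order and the percentile
  definition (linear interpolation between order statistics) are
  configurable. Samples whose tau row itself is undetected are dropped at
  the second step, since they cannot be placed on the axis. Because the
  percentile is recomputed from survivors, this one step is deliberately
  not idempotent; the other filters are.
- **Imputation.** Per sample, missing entries are drawn from
  N(μ − 1.8σ, (0.3σ)²) where μ and σ (ddof = 1) come from that sample's
  observed values only — the standard low-abundance ("downshifted normal")
  treatment of MNAR missingness. A sample needs at least two observed
  values; all draws flow from one seeded generator.

## Trajectory

Two orderings, matching the two capture modes:

- **Tau proxy** (single cells): the value is log2 MAPT intensity; ties in
  ranking break by sample id. A constant tau vector is flagged degenerate.
- **Diffusion pseudotime** (mini-pools): PCA reduction (≤ 20 components),
  kNN graph with `k_graph = 10`, adaptive Gaussian kernel with per-sample
  bandwidth equal to the distance to the `knn_dm = 5`-th neighbour,
  symmetrised affinity, Markov normalisation, eigendecomposition, and a
  multiscale space from the top `n_components = 5` non-trivial components
  scaled by λ/(1−λ). Pseudotime is Euclidean distance from the root in that
  space, min–max scaled to [0, 1] (root = 0). Waypoint refinement, terminal
  states and branch probabilities are intentionally not implemented: only
  the 1-D ordering is consumed downstream. Determinism is enforced by a
  fixed eigenvector sign convention (largest-magnitude entry positive), and
  connectivity is judged on the kNN graph itself, not on kernel weights,
  which can underflow between far-apart groups. The root is an explicit
  caller choice (typically the most tau-negative sample); no automatic rule
  is imposed.
- **Binning:** `bin_by_tau` divides [min, max] of the axis into `n_bins = 5`
  equal-width bins, internal bins left-closed/right-open, the last right
  edge inclusive.

## Association screen

Pearson r per protein against the axis; two-sided p from the t distribution
with n − 2 df; Benjamini–Hochberg adjustment (via statsmodels); significant
at q < 0.05. Zero-variance proteins are flagged untested and excluded from
the adjustment rather than assigned p = 1, so they do not deflate the BH
denominator. Clustering of significant proteins: per-protein z-scores, Ward
linkage on Euclidean distances, cut to exactly k clusters (k = 6
single-cell, k = 4 mini-pool). Panel screening restricts the same screen to
a curated id list with BH within the panel (stated in the report header).
Over-representation uses the one-sided hypergeometric tail with the
user-supplied background as population; sets disjoint from the background
are skipped with a warning.

## Proteostasis scores

A score is the mean of per-protein z-scores (computed across all cells,
population sd) over the pathway's detected members; absent members are
dropped and logged. Built-ins: 20S core (PSMA1–7, PSMB1–8; 15 members),
full proteasome (those + PSME1, PSMF1; 17), 19S regulatory particle
(resolved at runtime as detected PSMC*/PSMD* ids), and the lysosomal
acidification machinery (11 named ATP6V0/V1 subunits). Z-scoring after
imputation matches the pipeline order; an observed-only variant is a
configuration switch. Binned trends report mean, SEM (sample sd, n − 1
denominator; configurable) and n per tau bin; single-sample bins report SEM
as absent, empty bins are omitted.

## Phospho-site occupancy excess

The baseline model is a Gaussian LMM with a single donor random intercept,
fitted by REML on pTau-negative samples only: given the variance ratio
λ = σ²_donor/σ²_resid the GLS solution is closed-form per donor block
(Woodbury identity), and the restricted likelihood is profiled over log λ
with a bounded 1-D search; λ = 0 is evaluated explicitly so the boundary
solution — which equals OLS exactly — is attainable. Donor intercepts are
empirical best predictions; donors unseen in the baseline fit get the fixed
part only, since their intercepts are not estimable. Residuals for all
cells quantify excess phosphorylation; the headline excess β is
re-estimated as a pTau-status fixed effect in a refit on all cells, which
is the same contrast as the residual framing but carries a standard error.
Fold change is 2^β.

PTM report filtering applies the full threshold stack with the exact stated
strictness (`Lib.Q.Value < 0.5`, `Global.Q.Value < 0.5`,
`Lib.Peptidoform.Q.Value < 0.5`, `Global.Peptidoform.Q.Value < 0.5`,
`Q.Value < 0.01`, `PEP <= 0.05`, `Peptidoform.Q.Value < 0.01`,
`PTM.Site.Confidence > 0.9`), with site localization probability ≥ 0.99
additionally required in phospho mode. Column names match
case-insensitively with dots and underscores interchangeable. The K-GG
maximum-intensity outlier removal is off by default and errors on ties
rather than guessing. Sites are keyed residue + 1-based position on the
441-aa 2N4R tau sequence (pT231 style).

## Breakpoint analysis

Per protein, along the tau axis: outlier removal (|y − median| > 3 × 1.4826
MAD; called winsorisation in the field's usage but implemented as trimming,
with clipping behind a flag — if the MAD is zero the rule degenerates to
removing any value off the median, with a warning), z-scoring, then
continuous piecewise-linear least squares with B ∈ {0, 1, 2} breakpoints.

- **Optimisation.** Muggeo-style iterative linearization: the design
  augments the hinge covariates (x − ψ)₊ with gap covariates −1[x > ψ]; the
  breakpoint update is the ratio of their coefficients, iterated to
  convergence with projection into the admissible (strictly interior,
  strictly ascending) region. One-breakpoint fits are additionally seeded
  from the grid of midpoints between consecutive distinct x values (capped
  at 200), which makes the global optimum reliably reachable; two-breakpoint
  fits start from the best quantile pairs. Bootstrap restarting then runs
  `n_boot` rounds of residual resampling, refitting on the perturbed data
  and keeping any breakpoint vector that improves the RSS on the original
  data — the standard escape from local optima in segmented regression. The
  default `n_boot` is 1,000; the benchmarks use 50, which the recovery
  results show is sufficient at these sample sizes.
- **Selection.** BIC = n·ln(RSS/n) + k·ln(n) with k = 2 + 2B (intercept,
  base slope, one slope change and one position per breakpoint; the k
  convention is recorded in the report so alternatives can be compared).
  Ties favour fewer breakpoints; RSS = 0 maps to −∞ with a warning.
- **Stratification.** One-breakpoint fits with the breakpoint inside the
  central [0.20, 0.80] fraction of the axis (inclusive) are retained
  against edge effects. The early/late cut is the density minimum between
  the two largest modes of a Gaussian KDE (Silverman bandwidth) of retained
  breakpoint positions; a unimodal density falls back to the median and is
  flagged. Modules: early + rising first slope → early up/plateau; early +
  falling → early down/plateau; late + falling second slope → late decline;
  late + rising → late recover. A zero primary slope defers to the other
  segment's sign (logged). The timing label (early/late vs the cut) is also
  reported for one-breakpoint fits outside the retention band, whose module
  is undefined; timing should not depend on the edge filter.

## Synthetic cohorts

The generator emulates what the analysis assumes: a latent tau continuum
drawn uniformly over `tau_range` (default 12–18 log2 units, giving uniform
coverage so breakpoint positions are identifiable), donors assigned in
shuffled balance with N(0, donor_sd²) random intercepts (default 0.5 log2),
protein responses that are null, linear (±slope_scale, jittered ±25%), or
continuous hinges with an early (default tau = 14) or late (default
tau = 17) breakpoint, Gaussian measurement noise (default 0.3 log2), and
one row that is the tau protein itself (latent tau + noise, no donor
offset). pTau labels are a hard threshold on latent tau (default 15, the
range midpoint) with optional label noise (default 0). Missingness is
injected per entry with retention probability
logistic((value − midpoint) × steepness), the MNAR pattern the imputation
targets. Mini-pool mode averages `pool_size` (default 20) member responses
around a pool centre before adding noise. The phospho layer is
a₀ + a₁·tau + donor intercept + β·1[pTau⁺] + noise with a₁ = 0.8 by
default and β injected by the caller. Class counts follow
largest-remainder apportionment, so stated fractions are hit exactly when
they divide evenly.

What the generator does *not* emulate: peptide-level rollup, shared-peptide
ambiguity, batch/run effects, correlated protein modules beyond the shared
tau response, or non-Gaussian heavy-tailed noise. Passing benchmarks
therefore demonstrate correctness of the estimators under the assumed
model, not robustness to those real-data features.

## Benchmark conditions and problem sizes

The benchmark routines fix cohort sizes that resolve each question at
desk scale: breakpoint recovery uses 20 cohorts of 200 cells × 100 proteins
(20 early breaks at tau 14, 20 late at tau 17, noise 0.3, no donor offsets
so the benchmark isolates measurement noise from the recovery question;
donor heterogeneity is exercised separately by the mixed-model benchmark);
specificity uses an all-null cohort of the same size; FDR control uses 20
null cohorts of 100 cells × 300 proteins; the mixed-model benchmark uses
200 cells from 8 donors with donor sd 0.5 and noise 0.3 and injects
β = 1.16 log2 units. Under those conditions the excess estimator is
unbiased with a sampling sd of ≈ 0.09 — matching its own reported standard
error — so recovery is assessed by the mean signed bias and the mean
absolute per-seed error, the quantities that converge with the number of
seeds. The degenerate no-donor-variance check verifies the REML boundary
solution coincides with OLS.

## Known limitations

- The diffusion pseudotime is a plain multiscale diffusion distance; on
  data with genuine branching it will interleave branches rather than
  resolve them.
- Two-breakpoint fits use quantile-pair starts plus bootstrap restarts and
  are not guaranteed globally optimal (the one-breakpoint grid guarantee
  does not extend to B = 2); the nesting property RSS(B=2) ≤ RSS(B=1) is
  enforced only up to the optimiser's reach and is verified empirically.
- The early/late KDE cut assumes at most two dominant modes; more complex
  breakpoint distributions fall back to the median split.
- The LMM assumes a single random intercept and homoscedastic residuals; no
  random slopes.
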