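# tautraj

**Single-neuron proteomics trajectory analysis along the tau-accumulation axis.**

In Alzheimer's disease, neurons within one cortical region span a continuum
of tau burden: from tangle-free cells to AT8-positive, tangle-bearing ones.
`tautraj` implements the analysis stack for laser-microdissected
single-neuron (and mini-pool) proteomes ordered along that continuum:

- **Preprocessing** — contaminant removal, group-wise detection filters
  (≥ 30% of either pTau group for single cells, ≥ 70% for mini-pools),
  cell-quality filters, and per-sample downshifted-normal imputation of
  missing-not-at-random values: missing entries in sample *j* are drawn from
  N(μ_j − 1.8 σ_j, (0.3 σ_j)²).
- **Trajectory** — log2 tau (MAPT) intensity as a pseudotime proxy for
  single cells, or diffusion-map pseudotime from a root cell (kNN graph,
  adaptive Gaussian kernel, multiscale diffusion distance) for mini-pools;
  plus 5 equal-width tau bins.
- **Association screen** — per-protein Pearson *r* against the axis with
  Benjamini–Hochberg FDR (significant at *q* < 0.05), Ward/Euclidean
  clustering of significant proteins, curated-panel screening (e.g.
  cell-death proteins), and a hypergeometric over-representation test
  against GMT gene sets.
- **Proteostasis scores** — mean per-protein z-score over pathway members
  (proteasome, 20S core, 19S regulatory particle, lysosomal V-ATPase
  acidification machinery), with mean ± SEM per tau bin.
- **Phospho occupancy excess** — a Gaussian mixed model with a donor random
  intercept, y = β₀ + β₁·tau + u_donor + ε, fitted by profile REML on
  pTau-negative cells only; residuals in pTau-positive cells quantify
  phosphorylation beyond tau abundance, and a refit with a status term
  yields the excess β with a standard error (fold change = 2^β; β = 1.16
  log2 units ⇒ 2.2-fold).
- **Breakpoint analysis** — per protein, continuous piecewise-linear fits
  with 0/1/2 breakpoints (Muggeo iterative linearization with bootstrap
  restarting), model selection by BIC = n·ln(RSS/n) + (2+2B)·ln(n),
  retention of one-breakpoint fits in the central 0.20–0.80 of the tau
  range, and stratification into four temporal modules (early up/plateau,
  early down/plateau, late decline, late recover) at the valley of the
  breakpoint-position density.
- **Synthetic cohorts** — a first-class generator producing matrices with a
  latent tau continuum, donor intercepts, linear/hinged protein responses,
  logistic MNAR missingness and a phosphopeptide layer with a controllable
  occupancy excess, together with ground-truth tables for benchmarking.

## Worked example

```python
import tautraj as tt

cfg = tt.CohortConfig(n_cells=120, n_proteins=400, seed=42)
matrix, truth = tt.generate_cohort(cfg)

traj = tt.tau_proxy_ordering(matrix)          # order cells by log2 MAPT
records = tt.correlate_with_axis(matrix, traj)
print(int(records["significant"].sum()), "of", len(records))

report = tt.run_breakpoint_analysis(matrix, traj, n_boot=50, seed=42)
print(report.summary["early_late_cut"])
```

prints

```
197 of 400
14.22
```

197 of the 400 proteins pass the *q* < 0.05 correlation screen (the cohort
simulates 200 responding proteins plus the tau row), and the early/late
timing cut lands at tau ≈ 14.2 log2 units, separating the injected early
(tau = 14) breakpoint cluster from the late one (tau = 17). The `examples/` directory holds
one short narrative script per capability (simulation, preprocessing,
trajectories, pathway scores, phospho excess, breakpoint timing); each
prints the numbers it computes and what they mean. A thin CLI mirrors the
stages (`tautraj simulate|preprocess|trajectory|correlate|scores|phospho|breakpoints|run-all`).

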