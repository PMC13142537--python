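"""Perseus-style preprocessing: filters plus downshifted-normal imputation.

Proteins must be detected in at least 30% of either pTau group (single-cell
convention); cells need enough detected proteins and non-trivial tau; the
remaining gaps are filled from a per-sample Normal(mu - 1.8 sigma,
(0.3 sigma)^2), the standard low-abundance imputation for MNAR proteomics.
"""

import tautraj as tt

cfg = tt.CohortConfig(n_cells=120, n_donors=6, n_proteins=400, seed=42)
matrix, _ = tt.generate_cohort(cfg)
matrix = tt.inject_missingness(matrix, cfg)

m = tt.remove_contaminants(matrix)
m = tt.filter_proteins_by_detection(m, min_frac=0.3)
m = tt.filter_cells(m, min_proteins=100, tau_low_percentile=5)
m = tt.impute_downshifted_normal(m, width=0.3, downshift=1.8, seed=42)

for line in m.log:
    print(line)
print(f"\nafter preprocessing: {m.n_proteins} proteins x {m.n_samples} cells,"
      f" complete: {m.is_complete}")
# The log records every removal count; imputed positions stay flagged in
# m.imputed so downstream steps can distinguish measured from filled values.
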