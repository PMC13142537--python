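"""Quantify phospho-site occupancy beyond tau abundance.

A donor random-intercept mixed model of phospho intensity on tau is fitted
in pTau-negative cells only; residuals for pTau-positive cells then measure
phosphorylation exceeding abundance-based expectation, and a refit with a
status term gives the excess beta with a standard error. A beta of 1.16
log2 units corresponds to a 2.2-fold excess.
"""

import tautraj as tt

cfg = tt.CohortConfig(n_cells=200, n_donors=8, n_proteins=50, seed=11)
matrix, truth = tt.generate_cohort(cfg)
ph = tt.generate_phospho_layer(matrix, truth, beta_true=1.16,
                               occupancy_noise_sd=0.3, seed=11)

neg = (ph["ptau_status"] == "negative").to_numpy()
fit = tt.fit_random_intercept_lmm(ph["phospho"], ph["tau"], ph["donor_id"],
                                  subset=neg)
print(f"baseline fit (negatives): slope {fit.beta:.3f}, "
      f"donor var {fit.sigma_donor2:.3f}, residual var {fit.sigma_resid2:.3f}")

rep = tt.phospho_excess(fit, ph["phospho"], ph["tau"], ph["donor_id"],
                        ph["ptau_status"])
print(f"mean residual, positives: {rep.mean_residual['positive']:+.3f} log2")
print(f"excess beta: {rep.beta_excess:.3f} +/- {rep.se_excess:.3f} log2 "
      f"(injected 1.16)")
print(f"fold change: {rep.fold_change:.2f}x "
      f"(2^1.16 = {tt.fold_change_from_log2(1.16):.2f})")
# The recovered beta should sit within a couple of standard errors of the
# injected 1.16; its 2^beta fold change is the quantity reported to readers.
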