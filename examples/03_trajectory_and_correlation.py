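"""Order cells along the tau axis and screen proteins for association.

Single-cell cohorts use log2 tau (MAPT) intensity as the ordering; mini-pool
cohorts use diffusion-map pseudotime from a root cell. Each protein is then
correlated with the axis (Pearson) with Benjamini-Hochberg FDR control.
"""

from scipy.stats import spearmanr

import tautraj as tt

cfg = tt.CohortConfig(n_cells=120, n_proteins=400, seed=42)
matrix, truth = tt.generate_cohort(cfg)

proxy = tt.tau_proxy_ordering(matrix)
root = proxy.values.idxmin()  # most tau-negative cell as the root
dpt = tt.diffusion_pseudotime(matrix, root_sample=root, k_graph=10,
                              knn_dm=5, n_components=5)
rho = spearmanr(dpt.values, truth.cells["latent_tau"]).statistic
print(f"pseudotime vs latent tau: Spearman = {rho:.3f}")

records = tt.correlate_with_axis(matrix, proxy)
n_sig = int(records["significant"].sum())
print(f"significant proteins (q < 0.05): {n_sig} of {len(records)}")
top = records[records["significant"]].nsmallest(5, "rank", keep="all")
print("\nstrongest associations:")
print(top[["r", "q", "rank"]].to_string())
# MAPT itself correlates perfectly with the tau-proxy axis (r = 1); the
# responding proteins follow, while null proteins stay below the FDR cut.
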