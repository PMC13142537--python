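"""Temporal ordering of protein responses via breakpoint analysis.

Each protein is winsorized, z-scored, and fitted with 0/1/2-breakpoint
continuous piecewise-linear models; BIC picks the breakpoint count; the
one-breakpoint proteins inside the central 0.20-0.80 tau band are split
into early/late timing at the valley of the breakpoint-position density and
classified into four modules by slope direction.
"""

import tautraj as tt
from tautraj.benchmarks import breakpoint_recovery_config

cfg = breakpoint_recovery_config(seed=0)  # breaks injected at tau 14 and 17
matrix, truth = tt.generate_cohort(cfg)
traj = tt.tau_proxy_ordering(matrix)
report = tt.run_breakpoint_analysis(matrix, traj, n_boot=50, seed=0)

s = report.summary
print(f"proteins analysed: {s['n_proteins']}")
print(f"linear (B=0): {s['n_linear']}   non-linear (B>=1): {s['n_nonlinear']}")
print(f"early/late cut at tau = {s['early_late_cut']:.2f} "
      f"(true breakpoints at 14 and 17)")
print("module counts:", s["module_counts"])
tab = report.table.set_index("protein_id")
b1 = tab[tab["n_breakpoints"] == 1]
print(f"\nmedian |breakpoint - truth| = "
      f"{(b1['bp1'] - truth.proteins.loc[b1.index, 'breakpoint']).abs().median():.2f}"
      f" log2 units")
# With 20 early- and 20 late-break proteins injected, the cut lands between
# the two clusters and most break proteins recover the correct timing.
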