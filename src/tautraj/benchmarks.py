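"""Self-contained benchmark routines on synthetic cohorts.

Each function generates its own cohort(s) under the stated study conditions,
runs the corresponding analysis end to end and returns summary metrics.
They back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import assoc, phospho, proteostasis, trajectory
from .breakpoints import _rss_at, fit_piecewise, run_breakpoint_analysis
from .preprocess import impute_downshifted_normal
from .simulate import (CohortConfig, generate_cohort, generate_phospho_layer,
                       relabel_proteins)
from .matrix import from_values, make_sample_table


def breakpoint_recovery_config(seed: int) -> CohortConfig:
    """200 cells; 100 proteins: 20 early-break at tau=14, 20 late-break at
    tau=17, 30 linear, 30 null; measurement noise 0.3 (no donor offsets, so
    the benchmark isolates measurement noise)."""
    return CohortConfig(
        n_cells=200, n_proteins=100, frac_linear_up=0.15,
        frac_linear_down=0.15, frac_early_break=0.2, frac_late_break=0.2,
        noise_sd=0.3, donor_sd=0.0, seed=seed,
    )


def breakpoint_recovery(seeds, n_boot: int = 50) -> dict:
    """Fraction of break proteins selected as one-breakpoint with correct
    early/late timing, plus the median breakpoint position error as a
    fraction of the tau range."""
    correct = []
    err_frac = []
    b1 = []
    for seed in seeds:
        cfg = breakpoint_recovery_config(seed)
        m, truth = generate_cohort(cfg)
        traj = trajectory.tau_proxy_ordering(m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = run_breakpoint_analysis(m, traj, n_boot=n_boot, seed=seed)
        tab = rep.table.set_index("protein_id")
        tr = truth.proteins
        brk = tr.index[tr["response_class"].isin(["early_break", "late_break"])]
        sel = tab.loc[brk]
        true_t = tr.loc[brk, "response_class"].map(
            {"early_break": "early", "late_break": "late"})
        is_b1 = sel["n_breakpoints"] == 1
        correct.extend((is_b1 & (sel["timing"] == true_t)).tolist())
        b1.extend(is_b1.tolist())
        span = traj.values.max() - traj.values.min()
        err_frac.extend(
            ((sel.loc[is_b1, "bp1"]
              - tr.loc[sel.index[is_b1], "breakpoint"]).abs() / span).tolist())
    return {
        "frac_b1_correct_timing": float(np.mean(correct)),
        "frac_b1": float(np.mean(b1)),
        "median_bp_error_frac": float(np.median(err_frac)),
        "n_break_proteins": len(correct),
    }


def null_specificity(seed: int, n_boot: int = 50) -> dict:
    """Fraction of proteins assigned >= 1 breakpoint on an all-null cohort."""
    cfg = CohortConfig(n_cells=200, n_proteins=100, frac_linear_up=0,
                       frac_linear_down=0, frac_early_break=0,
                       frac_late_break=0, noise_sd=0.3, donor_sd=0.0,
                       seed=seed)
    m, truth = generate_cohort(cfg)
    traj = trajectory.tau_proxy_ordering(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = run_breakpoint_analysis(m, traj, n_boot=n_boot, seed=seed)
    tab = rep.table
    frac = float((tab["n_breakpoints"] >= 1).mean())
    return {"frac_nonlinear_on_null": frac, "n": len(tab)}


def grid_oracle_excess(seed: int, n_instances: int = 50, n_points: int = 30,
                       n_boot: int = 20) -> dict:
    """Worst relative RSS excess of the one-breakpoint fit over an
    exhaustive midpoint grid search, across random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        x = np.sort(rng.uniform(0, 10, n_points))
        y = rng.normal(0, 1, n_points)
        f = fit_piecewise(x, y, 1, n_boot=n_boot, seed=int(rng.integers(2**31)))
        ux = np.unique(x)
        grid = min(_rss_at(x, y, np.array([mid]))[0]
                   for mid in (ux[:-1] + ux[1:]) / 2)
        worst = max(worst, f.rss / grid - 1.0)
    return {"max_rel_rss_excess": float(worst), "n": n_instances}


def fdr_null(base_seed: int, n_reps: int = 20) -> dict:
    """Mean fraction of q < 0.05 calls on fully null cohorts."""
    fracs = []
    for k in range(n_reps):
        cfg = CohortConfig(n_cells=100, n_proteins=300, frac_linear_up=0,
                           frac_linear_down=0, frac_early_break=0,
                           frac_late_break=0, donor_sd=0.0,
                           seed=base_seed + k)
        m, _ = generate_cohort(cfg)
        rec = assoc.correlate_with_axis(m, trajectory.tau_proxy_ordering(m))
        fracs.append(float(rec.drop(index="MAPT")["significant"].mean()))
    fracs = np.asarray(fracs)
    return {
        "mean_significant_fraction": float(fracs.mean()),
        "mc_error": float(fracs.std(ddof=1) / np.sqrt(n_reps)),
        "n_reps": n_reps,
    }


def lmm_recovery(seeds, beta_true: float = 1.16) -> dict:
    """Recovery of an injected phospho occupancy excess (log2 units)."""
    errs = []
    for seed in seeds:
        cfg = CohortConfig(n_cells=200, n_donors=8, n_proteins=20,
                           donor_sd=0.5, noise_sd=0.3, seed=seed)
        m, truth = generate_cohort(cfg)
        ph = generate_phospho_layer(m, truth, beta_true=beta_true,
                                    occupancy_noise_sd=0.3, donor_sd=0.5,
                                    seed=seed)
        neg = (ph["ptau_status"] == "negative").to_numpy()
        fit = phospho.fit_random_intercept_lmm(
            ph["phospho"], ph["tau"], ph["donor_id"], subset=neg)
        rep = phospho.phospho_excess(fit, ph["phospho"], ph["tau"],
                                     ph["donor_id"], ph["ptau_status"])
        errs.append(rep.beta_excess - beta_true)
    errs = np.asarray(errs)
    return {
        "mean_bias": float(errs.mean()),
        "mean_abs_error": float(np.abs(errs).mean()),
        "mean_recovered_beta": float(errs.mean() + beta_true),
        "n_seeds": len(errs),
    }


def lmm_ols_degenerate(seed: int) -> dict:
    """With zero true donor variance the REML fit collapses onto OLS."""
    cfg = CohortConfig(n_cells=200, n_donors=8, n_proteins=20, donor_sd=0.0,
                       noise_sd=0.3, seed=seed)
    m, truth = generate_cohort(cfg)
    ph = generate_phospho_layer(m, truth, beta_true=0.0, donor_sd=0.0,
                                seed=seed)
    fit = phospho.fit_random_intercept_lmm(ph["phospho"], ph["tau"],
                                           ph["donor_id"])
    slope = float(np.polyfit(ph["tau"], ph["phospho"], 1)[0])
    return {"abs_beta_minus_ols": abs(fit.beta - slope),
            "sigma_donor2": fit.sigma_donor2}


def imputation_moments(seed: int, n_obs: int = 10000,
                       n_missing: int = 10000) -> dict:
    """Moments of downshifted-normal draws in a sample with observed
    mean 20 and sd 1 (expected: mean 18.2, sd 0.3)."""
    rng = np.random.default_rng(seed)
    obs = rng.normal(0, 1, n_obs)
    obs = (obs - obs.mean()) / obs.std(ddof=1) + 20.0
    vals = pd.DataFrame(
        {"S1": np.concatenate([obs, np.full(n_missing, np.nan)])},
        index=[f"P{i}" for i in range(n_obs + n_missing)])
    m = from_values(vals, make_sample_table(["S1"], ["D1"], ["negative"]))
    out = impute_downshifted_normal(m, seed=seed)
    imp = out.values.loc[out.imputed["S1"], "S1"]
    unchanged = bool(np.array_equal(
        out.values.loc[~out.imputed["S1"], "S1"].to_numpy(), obs))
    return {
        "imputed_mean": float(imp.mean()),
        "imputed_sd": float(imp.std(ddof=1)),
        "n_draws": int(len(imp)),
        "observed_unchanged": unchanged,
    }


def pathway_trend_contrast(seed: int) -> dict:
    """Binned trends when acidification members respond linear-up and 20S
    members linear-down: per-bin mean differences of each trend."""
    cfg = CohortConfig(n_cells=200, n_proteins=120, frac_linear_up=0.3,
                       frac_linear_down=0.3, frac_early_break=0,
                       frac_late_break=0, noise_sd=0.3, seed=seed)
    m, truth = generate_cohort(cfg)
    up = truth.proteins.index[truth.proteins["response_class"] == "linear_up"]
    dn = truth.proteins.index[truth.proteins["response_class"] == "linear_down"]
    mapping = dict(zip(up, proteostasis._ACIDIFICATION)) | \
        dict(zip(dn, proteostasis._20S))
    m, _ = relabel_proteins(m, truth, mapping)
    bins = trajectory.bin_by_tau(trajectory.tau_proxy_ordering(m), 5)
    defs = {d.name: d for d in proteostasis.builtin_definitions()}
    acid = proteostasis.binned_trend(
        proteostasis.pathway_score(m, defs["acidification"]), bins)
    s20 = proteostasis.binned_trend(
        proteostasis.pathway_score(m, defs["proteasome_20S"]), bins)
    return {
        "acidification_monotone_up": bool(np.all(np.diff(acid["mean"]) > 0)),
        "proteasome_20S_monotone_down": bool(np.all(np.diff(s20["mean"]) < 0)),
        "acidification_means": acid["mean"].tolist(),
        "proteasome_20S_means": s20["mean"].tolist(),
        "n_bins": int(len(acid)),
    }


def trajectory_fidelity(seed: int) -> dict:
    """Spearman agreement of both orderings with the latent tau axis on a
    100-cell continuum (noise 0.3)."""
    cfg = CohortConfig(n_cells=100, n_proteins=300, noise_sd=0.3, seed=seed)
    m, truth = generate_cohort(cfg)
    proxy = trajectory.tau_proxy_ordering(m)
    rho_proxy = float(spearmanr(proxy.values,
                                truth.cells["latent_tau"]).statistic)
    dpt = trajectory.diffusion_pseudotime(m, proxy.values.idxmin())
    rho_dpt = float(spearmanr(dpt.values, truth.cells["latent_tau"]).statistic)
    return {"spearman_tau_proxy": rho_proxy,
            "spearman_pseudotime_abs": abs(rho_dpt),
            "n_cells": cfg.n_cells}


def ptm_filter_toy() -> dict:
    """The 7-record boundary-semantics table: 1 clean record (PEP exactly
    0.05, inclusive) + 6 single-rule violators (Q.Value exactly 0.01 among
    them, strict)."""
    clean = dict(
        lib_q_value=0.1, global_q_value=0.1, lib_peptidoform_q_value=0.1,
        global_peptidoform_q_value=0.1, q_value=0.005, pep=0.05,
        peptidoform_q_value=0.005, ptm_site_confidence=0.95,
        site_localization_probability=0.995,
    )
    rows = [dict(clean)]
    for col, bad in [("lib_q_value", 0.6),
                     ("global_peptidoform_q_value", 0.5),
                     ("q_value", 0.01), ("pep", 0.0501),
                     ("peptidoform_q_value", 0.02),
                     ("ptm_site_confidence", 0.9)]:
        r = dict(clean)
        r[col] = bad
        rows.append(r)
    df = pd.DataFrame(rows)
    kept = phospho.apply_ptm_filters(df, "phospho")
    return {"n_input": len(df), "n_retained": int(len(kept)),
            "pep_boundary_kept": bool((kept["pep"] == 0.05).all()
                                      and len(kept) > 0)}
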