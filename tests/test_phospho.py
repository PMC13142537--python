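"""PTM filtering rules and the random-intercept mixed model."""

import numpy as np
import pandas as pd
import pytest

import tautraj as tt
from tautraj.phospho import KGG_RULES, PHOSPHO_RULES, _fit_lmm


def _clean_record():
    return dict(
        lib_q_value=0.1, global_q_value=0.1, lib_peptidoform_q_value=0.1,
        global_peptidoform_q_value=0.1, q_value=0.005, pep=0.05,
        peptidoform_q_value=0.005, ptm_site_confidence=0.95,
        site_localization_probability=0.995,
    )


def _toy_report():
    """One clean record plus six, each violating exactly one threshold."""
    rows = [_clean_record()]
    violations = [
        ("lib_q_value", 0.6),
        ("global_peptidoform_q_value", 0.5),  # boundary: < is strict
        ("q_value", 0.01),  # boundary: strict < drops it
        ("pep", 0.0501),
        ("peptidoform_q_value", 0.02),
        ("ptm_site_confidence", 0.9),  # boundary: > is strict
    ]
    for col, bad in violations:
        r = _clean_record()
        r[col] = bad
        rows.append(r)
    return pd.DataFrame(rows)


def test_ptm_filter_retains_only_clean_record():
    df = _toy_report()
    kept = tt.apply_ptm_filters(df, "phospho")
    assert len(kept) == 1
    # the retained record carries PEP exactly at the inclusive 0.05 boundary
    assert kept.iloc[0]["pep"] == 0.05


def test_ptm_filter_boundary_semantics():
    r_pep = _clean_record(); r_pep["pep"] = 0.05
    r_q = _clean_record(); r_q["q_value"] = 0.01
    df = pd.DataFrame([r_pep, r_q])
    kept = tt.apply_ptm_filters(df, "phospho")
    assert len(kept) == 1 and kept.iloc[0]["q_value"] == 0.005


def test_ptm_filter_modes_and_columns():
    df = _toy_report()
    # kgg mode ignores site localization
    low_loc = _clean_record(); low_loc["site_localization_probability"] = 0.5
    df2 = pd.DataFrame([low_loc])
    assert len(tt.apply_ptm_filters(df2, "kgg")) == 1
    assert len(tt.apply_ptm_filters(df2, "phospho")) == 0
    # dotted/case-variant column names are accepted
    df3 = df2.rename(columns={"q_value": "Q.Value", "pep": "PEP"})
    assert len(tt.apply_ptm_filters(df3, "kgg")) == 1
    with pytest.raises(KeyError, match="pep"):
        tt.apply_ptm_filters(df2.drop(columns=["pep"]), "kgg")


def test_ptm_filter_monotone_in_thresholds():
    """Relaxing any single threshold never shrinks the retained set."""
    rng = np.random.default_rng(0)
    cols = [c for c, _, _ in PHOSPHO_RULES]
    df = pd.DataFrame({c: rng.uniform(0, 1, 300) for c in cols})
    base = tt.apply_ptm_filters(df, "phospho")
    import tautraj.phospho as ph

    for i, (col, op, thr) in enumerate(PHOSPHO_RULES):
        relaxed = list(PHOSPHO_RULES)
        widen = thr + 0.2 if op in ("<", "<=") else thr - 0.2
        relaxed[i] = (col, op, widen)
        orig = ph.PHOSPHO_RULES
        ph.PHOSPHO_RULES = tuple(relaxed)
        try:
            out = tt.apply_ptm_filters(df, "phospho")
        finally:
            ph.PHOSPHO_RULES = orig
        assert set(base.index) <= set(out.index)


def test_kgg_outlier_policy():
    s = pd.Series([1.0, 5.0, 9.0])
    out = tt.kgg_outlier_policy(s, remove_max=True)
    assert np.isnan(out.iloc[2]) and out.iloc[:2].tolist() == [1.0, 5.0]
    pd.testing.assert_series_equal(tt.kgg_outlier_policy(s), s)
    with pytest.raises(ValueError, match="tie"):
        tt.kgg_outlier_policy(pd.Series([1.0, 9.0, 9.0]), remove_max=True)


# ---------------------------------------------------------------------------
# Mixed model
# ---------------------------------------------------------------------------

def _phospho_cohort(seed, beta=1.16, donor_sd=0.5, noise=0.3, n_cells=200):
    cfg = tt.CohortConfig(n_cells=n_cells, n_donors=8, n_proteins=20,
                          donor_sd=donor_sd, noise_sd=noise, seed=seed)
    m, truth = tt.generate_cohort(cfg)
    return tt.generate_phospho_layer(m, truth, beta_true=beta,
                                     occupancy_noise_sd=noise,
                                     donor_sd=donor_sd, seed=seed)


def test_lmm_matches_statsmodels_reml():
    """Profile-REML fit agrees with the statsmodels MixedLM oracle."""
    import statsmodels.formula.api as smf

    ph = _phospho_cohort(0)
    neg = ph[ph["ptau_status"] == "negative"]
    fit = tt.fit_random_intercept_lmm(
        ph["phospho"], ph["tau"], ph["donor_id"],
        subset=(ph["ptau_status"] == "negative").to_numpy())
    sm_fit = smf.mixedlm("phospho ~ tau", neg, groups=neg["donor_id"]).fit(
        reml=True)
    assert fit.beta == pytest.approx(sm_fit.params["tau"], abs=1e-5)
    assert fit.intercept == pytest.approx(sm_fit.params["Intercept"], abs=1e-4)
    assert fit.sigma_resid2 == pytest.approx(sm_fit.scale, rel=1e-3)
    assert fit.sigma_donor2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]),
                                             rel=1e-2, abs=1e-4)


def test_lmm_matches_reml_grid_search():
    """1-D brute-force REML grid over the variance ratio agrees in beta."""
    from tautraj.phospho import _reml_neg2loglik

    rng = np.random.default_rng(7)
    donors = np.repeat(["a", "b", "c"], 4)
    x = rng.normal(16, 1.5, 12)
    eff = {"a": 0.5, "b": -0.3, "c": 0.1}
    y = 1.0 + 0.8 * x + np.array([eff[d] for d in donors]) + rng.normal(0, 0.2, 12)
    fit = tt.fit_random_intercept_lmm(y, x, donors)
    X = np.column_stack([np.ones(12), x])
    _, gidx = np.unique(donors, return_inverse=True)
    lams = np.concatenate([[0.0], np.exp(np.linspace(-12, 8, 40001))])
    crits = [_reml_neg2loglik(l, X, y, gidx, 3)[0] for l in lams]
    best = lams[int(np.argmin(crits))]
    beta_grid = _reml_neg2loglik(best, X, y, gidx, 3)[1][1]
    assert fit.beta == pytest.approx(beta_grid, abs=1e-4)


def test_lmm_zero_donor_variance_equals_ols():
    ph = _phospho_cohort(3, beta=0.0, donor_sd=0.0)
    fit = tt.fit_random_intercept_lmm(ph["phospho"], ph["tau"], ph["donor_id"])
    slope, intercept = np.polyfit(ph["tau"], ph["phospho"], 1)
    assert fit.beta == pytest.approx(slope, abs=1e-6)
    assert fit.sigma_donor2 == 0.0


def test_lmm_invariant_to_x_shift():
    ph = _phospho_cohort(4)
    f1 = tt.fit_random_intercept_lmm(ph["phospho"], ph["tau"], ph["donor_id"])
    f2 = tt.fit_random_intercept_lmm(ph["phospho"], ph["tau"] + 100.0,
                                     ph["donor_id"])
    assert f1.beta == pytest.approx(f2.beta, abs=1e-8)


def test_lmm_preconditions():
    with pytest.raises(ValueError, match="4 samples"):
        tt.fit_random_intercept_lmm([1, 2], [1, 2], ["a", "b"])
    with pytest.raises(ValueError, match="2 donors"):
        tt.fit_random_intercept_lmm([1, 2, 3, 4], [1, 2, 3, 4], ["a"] * 4)
    with pytest.raises(ValueError, match="constant"):
        tt.fit_random_intercept_lmm([1, 2, 3, 4], [2, 2, 2, 2],
                                    ["a", "a", "b", "b"])


def test_phospho_excess_slope_and_recovery():
    """Slope a1=0.8 and the injected excess are recovered over 20 seeds."""
    slopes, errs = [], []
    for seed in range(20):
        ph = _phospho_cohort(seed)
        neg = (ph["ptau_status"] == "negative").to_numpy()
        fit = tt.fit_random_intercept_lmm(ph["phospho"], ph["tau"],
                                          ph["donor_id"], subset=neg)
        rep = tt.phospho_excess(fit, ph["phospho"], ph["tau"],
                                ph["donor_id"], ph["ptau_status"])
        slopes.append(fit.beta)
        errs.append(rep.beta_excess - 1.16)
    assert np.mean(slopes) == pytest.approx(0.8, abs=0.1)
    assert abs(np.mean(errs)) < 0.05  # bias
    assert np.mean(np.abs(errs)) < 0.15


def test_phospho_excess_null_injection():
    ph = _phospho_cohort(1, beta=0.0)
    neg = (ph["ptau_status"] == "negative").to_numpy()
    fit = tt.fit_random_intercept_lmm(ph["phospho"], ph["tau"],
                                      ph["donor_id"], subset=neg)
    rep = tt.phospho_excess(fit, ph["phospho"], ph["tau"], ph["donor_id"],
                            ph["ptau_status"])
    n_pos = (~neg).sum()
    sem = rep.residuals[~neg].std(ddof=1) / np.sqrt(n_pos)
    assert abs(rep.mean_residual["positive"]) < 3 * max(sem, rep.se_excess)
    # negative-cell residuals about their own fit average ~0 (BLUP shrinkage
    # leaves only a tiny remainder)
    assert abs(rep.mean_residual["negative"]) < 0.05


@pytest.mark.parametrize("beta,fold", [(1.16, 2.2), (0.0, 1.0), (1.0, 2.0)])
def test_fold_change_conversion(beta, fold):
    assert round(tt.fold_change_from_log2(beta), 1) == fold


def test_detection_fraction_by_group():
    groups = pd.Series(
        ["positive"] * 10 + ["negative"] * 10,
        index=[f"S{i}" for i in range(20)],
    )
    rows = []
    for i in range(8):  # site detected in 8/10 positives only
        rows.append({"site": "pT217", "sample_id": f"S{i}", "intensity": 1.0})
    rows.append({"site": "pS999", "sample_id": "S0", "intensity": np.nan})
    rec = pd.DataFrame(rows)
    frac = tt.detection_fraction_by_group(rec, groups)
    assert frac.loc["pT217", "positive"] == pytest.approx(0.8)
    assert frac.loc["pT217", "negative"] == 0.0
    assert (frac.loc["pS999"] == 0.0).all()
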