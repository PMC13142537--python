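"""Piecewise fitting, BIC selection, range filtering, module stratification."""

import numpy as np
import pandas as pd
import pytest

import tautraj as tt
from tautraj.breakpoints import (FitError, PiecewiseFit, _rss_at, bic,
                                 filter_breakpoint_range, select_model,
                                 stratify_modules)


def test_winsorize_mad_rule():
    y = np.array([0.0, 0.0, 0.0, 0.0, 100.0])
    with pytest.warns(UserWarning, match="MAD"):  # majority ties -> MAD 0
        cleaned, keep = tt.winsorize_mad(y)
    assert not keep[-1] and keep[:4].all()
    y2 = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 1.0])
    _, keep2 = tt.winsorize_mad(y2)
    assert keep2.all()
    # brute-force rule agreement on a random vector
    rng = np.random.default_rng(0)
    y3 = rng.normal(0, 1, 10)
    _, keep3 = tt.winsorize_mad(y3)
    med = np.median(y3)
    mad = 1.4826 * np.median(np.abs(y3 - med))
    np.testing.assert_array_equal(keep3, np.abs(y3 - med) <= 3 * mad)


def test_winsorize_zero_mad_degenerate_rule():
    """With a zero MAD the literal rule removes any value off the median;
    an all-constant vector passes through unchanged."""
    with pytest.warns(UserWarning, match="MAD"):
        _, keep = tt.winsorize_mad(np.array([1.0, 1.0, 1.0, 1.0, 1.0, 9.0]))
    assert keep.tolist() == [True] * 5 + [False]
    with pytest.warns(UserWarning, match="MAD"):
        _, keep2 = tt.winsorize_mad(np.ones(6))
    assert keep2.all()


def test_noiseless_hinge_recovered_exactly():
    x = np.arange(0.0, 11.0)
    y = np.maximum(0.0, x - 5.0)
    f = tt.fit_piecewise(x, y, 1, n_boot=10, seed=0)
    assert f.breakpoints[0] == pytest.approx(5.0, abs=1e-6)
    assert f.slopes[0] == pytest.approx(0.0, abs=1e-6)
    assert f.slopes[1] == pytest.approx(1.0, abs=1e-6)
    assert f.converged


def test_b0_equals_closed_form_ols():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 10, 40)
    y = 2.0 - 0.5 * x + rng.normal(0, 0.3, 40)
    f = tt.fit_piecewise(x, y, 0)
    slope, intercept = np.polyfit(x, y, 1)
    assert f.slopes[0] == pytest.approx(slope, abs=1e-10)
    assert f.intercept == pytest.approx(intercept, abs=1e-10)


def test_one_breakpoint_matches_grid_oracle():
    """Returned RSS never exceeds the exhaustive midpoint-grid optimum."""
    rng = np.random.default_rng(5)
    for i in range(50):
        x = np.sort(rng.uniform(0, 10, 30))
        y = rng.normal(0, 1, 30)
        f = tt.fit_piecewise(x, y, 1, n_boot=20, seed=i)
        ux = np.unique(x)
        grid = min(_rss_at(x, y, np.array([m]))[0]
                   for m in (ux[:-1] + ux[1:]) / 2)
        assert f.rss <= grid * (1 + 1e-8)


def test_rss_nesting_across_model_orders():
    rng = np.random.default_rng(9)
    for seed in range(5):
        x = np.sort(rng.uniform(0, 10, 60))
        y = np.where(x > 4, x - 4, 0.0) + rng.normal(0, 0.3, 60)
        f0 = tt.fit_piecewise(x, y, 0)
        f1 = tt.fit_piecewise(x, y, 1, n_boot=20, seed=seed)
        f2 = tt.fit_piecewise(x, y, 2, n_boot=20, seed=seed)
        assert f2.rss <= f1.rss * (1 + 1e-9)
        assert f1.rss <= f0.rss * (1 + 1e-9)


def test_fit_determinism_and_continuity():
    rng = np.random.default_rng(2)
    x = np.sort(rng.uniform(0, 10, 80))
    y = np.where(x > 6, 6 - x, 0.0) + rng.normal(0, 0.2, 80)
    f1 = tt.fit_piecewise(x, y, 2, n_boot=30, seed=42)
    f2 = tt.fit_piecewise(x, y, 2, n_boot=30, seed=42)
    assert f1.breakpoints == f2.breakpoints and f1.rss == f2.rss
    # continuity: prediction approached from both sides agrees at each break
    for psi in f1.breakpoints:
        eps = 1e-9
        left = f1.predict(np.array([psi - eps]))[0]
        right = f1.predict(np.array([psi + eps]))[0]
        assert left == pytest.approx(right, abs=1e-6)
    assert all(np.diff(f1.breakpoints) > 0)
    assert all(x.min() < p < x.max() for p in f1.breakpoints)


def test_fit_preconditions():
    with pytest.raises(FitError, match="0, 1 or 2"):
        tt.fit_piecewise(np.arange(10.0), np.arange(10.0), 3)
    with pytest.raises(FitError, match="distinct"):
        tt.fit_piecewise(np.array([1.0, 1, 1, 2, 2, 2]), np.zeros(6), 1)


@pytest.mark.parametrize(
    "n,rss,B,expected",
    [(100, 100.0, 0, 2 * np.log(100)),  # n*ln(1) + 2 ln(100) = 9.2103...
     (10, 10.0, 2, 6 * np.log(10))],  # 13.8155...
)
def test_bic_arithmetic(n, rss, B, expected):
    f = PiecewiseFit(None, B, (1.0,) * B if B else (), 0.0, (0.0,) * (B + 1),
                     rss, n)
    assert bic(f) == pytest.approx(expected, abs=1e-10)


def test_bic_same_rss_penalty_gap_and_zero_rss():
    f0 = PiecewiseFit(None, 0, (), 0.0, (0.0,), 50.0, 200)
    f1 = PiecewiseFit(None, 1, (1.0,), 0.0, (0.0, 0.0), 50.0, 200)
    assert bic(f1) - bic(f0) == pytest.approx(2 * np.log(200), abs=1e-10)
    perfect = PiecewiseFit(None, 0, (), 0.0, (1.0,), 0.0, 10)
    with pytest.warns(UserWarning, match="zero"):
        assert bic(perfect) == float("-inf")


def test_select_model_tie_prefers_fewer_breakpoints():
    f0 = PiecewiseFit(None, 0, (), 0.0, (0.0,), 1.0, 50, bic=10.0)
    f1 = PiecewiseFit(None, 1, (1.0,), 0.0, (0.0, 0.0), 1.0, 50, bic=10.0)
    assert select_model([f1, f0]).n_breakpoints == 0
    f1.bic = 9.0
    assert select_model([f1, f0, None]).n_breakpoints == 1
    with pytest.raises(FitError):
        select_model([None, None])


def test_select_model_linear_data_prefers_b0():
    """On noisy straight lines, BIC selects the 0-breakpoint model nearly
    always (spurious hinges do not beat the 2 ln n penalty)."""
    rng = np.random.default_rng(3)
    chosen = []
    for _ in range(40):
        x = np.sort(rng.uniform(0, 10, 100))
        y = 0.5 * x + rng.normal(0, 0.3, 100)
        fits = []
        for B in (0, 1, 2):
            f = tt.fit_piecewise(x, y, B, n_boot=10, seed=rng)
            f.bic = bic(f)
            fits.append(f)
        chosen.append(select_model(fits).n_breakpoints)
    assert np.mean(np.array(chosen) == 0) >= 0.95


def test_strong_hinge_selects_b1():
    x = np.linspace(0, 10, 60)
    y = np.where(x > 5, x - 5, 0.0)
    fits = []
    for B in (0, 1, 2):
        f = tt.fit_piecewise(x, y, B, n_boot=10, seed=0)
        f.bic = bic(f)
        fits.append(f)
    # the B=1 fit is exact (RSS ~ 0 -> BIC -inf); B=2 cannot beat the tie rule
    assert select_model(fits).n_breakpoints in (1, 2)
    assert select_model(fits).rss < 1e-12


def _mkfit(pid, bp, a1=1.0, a2=0.0, B=1):
    return PiecewiseFit(pid, B, (bp,) if B == 1 else (bp, bp + 1),
                        0.0, (a1, a2) + ((0.0,) if B == 2 else ()), 1.0, 50)


@pytest.mark.parametrize("bp,kept", [(12.0, True), (11.0, False),
                                     (18.0, True), (19.0, False),
                                     (15.0, True)])
def test_range_filter_inclusive_bounds(bp, kept):
    # range [10, 20]: central band = [12, 18] inclusive
    out = filter_breakpoint_range([_mkfit("p", bp)], (10.0, 20.0))
    assert (len(out) == 1) is kept


def test_range_filter_only_b1():
    fits = [_mkfit("a", 15.0), _mkfit("b", 15.0, B=2),
            PiecewiseFit("c", 0, (), 0.0, (1.0,), 1.0, 50)]
    out = filter_breakpoint_range(fits, (10.0, 20.0))
    assert [f.protein_id for f in out] == ["a"]


def test_stratify_two_clusters_and_module_labels():
    """Well-separated breakpoint clusters split at the density valley and
    slope signs map onto the four modules."""
    rng = np.random.default_rng(0)
    fits = (
        [_mkfit(f"e{i}", 14.0 + rng.normal(0, 0.1), a1=1.0, a2=0.0)
         for i in range(10)]
        + [_mkfit(f"l{i}", 17.0 + rng.normal(0, 0.1), a1=0.2, a2=-1.0)
           for i in range(10)]
    )
    assignments, cut, fallback = stratify_modules(fits)
    assert not fallback
    assert 14.5 < cut < 16.5
    amap = {a.protein_id: a for a in assignments}
    assert all(amap[f"e{i}"].module == "early_up_plateau" for i in range(10))
    assert all(amap[f"l{i}"].module == "late_decline" for i in range(10))
    # order invariance
    assignments2, cut2, _ = stratify_modules(fits[::-1])
    assert cut2 == cut
    assert {a.protein_id: a.module for a in assignments2} == \
        {a.protein_id: a.module for a in assignments}


def test_stratify_definitions_on_canonical_shapes():
    # early hinge rising then flat; late hinge slowly rising then declining
    fits = [_mkfit(f"e{i}", 14.0, a1=1.0, a2=0.0) for i in range(5)]
    fits += [_mkfit(f"l{i}", 17.0, a1=0.2, a2=-1.0) for i in range(5)]
    assignments, _, _ = stratify_modules(fits)
    modules = {a.protein_id: a.module for a in assignments}
    assert modules["e0"] == "early_up_plateau"
    assert modules["l0"] == "late_decline"
    # down-then-stabilize and suppress-then-recover
    fits2 = [_mkfit(f"e{i}", 14.0, a1=-1.0, a2=0.0) for i in range(5)]
    fits2 += [_mkfit(f"l{i}", 17.0, a1=0.0, a2=1.0) for i in range(5)]
    assignments2, _, _ = stratify_modules(fits2)
    modules2 = {a.protein_id: a.module for a in assignments2}
    assert modules2["e0"] == "early_down_plateau"
    assert modules2["l0"] == "late_recover"
    # a zero primary slope defers to the other segment's sign
    fits3 = [_mkfit(f"e{i}", 14.0, a1=1.0, a2=0.0) for i in range(9)]
    fits3 += [_mkfit("lz", 17.0, a1=0.5, a2=0.0)]
    with pytest.warns(UserWarning, match="zero slope"):
        assignments3, _, _ = stratify_modules(fits3)
    assert {a.protein_id: a.module for a in assignments3}["lz"] == "late_recover"


def test_stratify_needs_ten_fits():
    with pytest.raises(ValueError, match="10"):
        stratify_modules([_mkfit("a", 14.0)])


def test_breakpoint_recovery_noiseless_and_noisy():
    """Noiseless hinges are recovered with zero error; at noise sd 0.3 the
    median position error stays below 5% of the x-range (20 seeds)."""
    x = np.linspace(12, 18, 150)
    y = np.where(x > 14.5, x - 14.5, 0.0)
    f = tt.fit_piecewise(x, y, 1, n_boot=10, seed=0)
    assert f.breakpoints[0] == pytest.approx(14.5, abs=1e-8)
    errs = []
    rng = np.random.default_rng(4)
    for seed in range(20):
        yn = y + rng.normal(0, 0.3, len(x))
        fn = tt.fit_piecewise(x, yn, 1, n_boot=20, seed=seed)
        errs.append(abs(fn.breakpoints[0] - 14.5))
    assert np.median(errs) < 0.05 * (18 - 12)


def test_run_breakpoint_analysis_report(imputed_cohort):
    _, m, truth = imputed_cohort
    traj = tt.tau_proxy_ordering(m)
    rep1 = tt.run_breakpoint_analysis(m, traj, n_boot=10, seed=3)
    rep2 = tt.run_breakpoint_analysis(m, traj, n_boot=10, seed=3)
    pd.testing.assert_frame_equal(rep1.table, rep2.table)  # determinism
    tab = rep1.table.set_index("protein_id")
    assert "MAPT" not in tab.index
    assert set(tab.columns) >= {"bp1", "alpha1", "alpha2", "bic", "module"}
    # every selected one-breakpoint fit respects the range-filter flag
    b1 = tab[tab["n_breakpoints"] == 1]
    lo, hi = traj.values.min(), traj.values.max()
    frac = (b1["bp1"] - lo) / (hi - lo)
    assert ((frac >= 0.2) & (frac <= 0.8)).equals(b1["retained"])
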