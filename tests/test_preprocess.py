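"""Preprocessing: contaminants, detection/cell filters, imputation."""

import numpy as np
import pandas as pd
import pytest

import tautraj as tt
from tautraj.matrix import MatrixError


def test_remove_contaminants_by_prefix(toy_matrix):
    out = tt.remove_contaminants(toy_matrix)
    assert list(out.protein_ids) == ["MAPT", "SQSTM1", "PSMA1"]
    # no matching prefix -> identity
    again = tt.remove_contaminants(out)
    assert list(again.protein_ids) == list(out.protein_ids)


def test_remove_all_contaminants_warns():
    vals = pd.DataFrame({"S1": [1.0, 2.0], "S2": [1.0, 2.0]},
                        index=["Cont_A", "Cont_B"])
    m = tt.from_values(vals, tt.make_sample_table(
        ["S1", "S2"], ["D1", "D1"], ["negative", "positive"]))
    with pytest.warns(UserWarning, match="contaminants"):
        out = tt.remove_contaminants(m)
    assert out.n_proteins == 0


@pytest.mark.parametrize(
    "det_pos,det_neg,min_frac,kept",
    # enumerate detection counts out of 10 per group against the threshold
    [(7, 0, 0.7, True), (6, 6, 0.7, False), (3, 0, 0.3, True),
     (2, 2, 0.3, False), (0, 10, 0.7, True), (7, 7, 0.7, True)],
)
def test_detection_filter_either_group_inclusive(det_pos, det_neg, min_frac, kept):
    """A protein survives iff detected in >= min_frac of either pTau group."""
    n = 10
    sids = [f"P{i}" for i in range(n)] + [f"N{i}" for i in range(n)]
    vals = pd.Series(
        [15.0 if i < det_pos else np.nan for i in range(n)]
        + [15.0 if i < det_neg else np.nan for i in range(n)],
        index=sids,
    ).to_frame().T
    vals.index = ["PROT1"]
    m = tt.from_values(vals, tt.make_sample_table(
        sids, ["D1"] * 2 * n, ["positive"] * n + ["negative"] * n))
    out = tt.filter_proteins_by_detection(m, min_frac)
    assert ("PROT1" in out.protein_ids) is kept


def test_detection_filter_empty_group_errors():
    vals = pd.DataFrame({"S1": [1.0], "S2": [1.0]}, index=["P"])
    m = tt.from_values(vals, tt.make_sample_table(
        ["S1", "S2"], ["D1", "D1"], ["negative", "negative"]))
    with pytest.raises(MatrixError, match="positive"):
        tt.filter_proteins_by_detection(m, 0.7)


def test_cell_filter_count_then_percentile():
    """999-protein sample dropped (strict <); then the lowest-tau sample of
    20 distinct tau values falls below the 5th percentile (linear
    interpolation) and is dropped."""
    rng = np.random.default_rng(0)
    n_prot, n_cells = 1200, 21
    sids = [f"S{i:02d}" for i in range(n_cells)]
    vals = pd.DataFrame(rng.normal(16, 1, (n_prot, n_cells)),
                        index=["MAPT"] + [f"P{i}" for i in range(n_prot - 1)],
                        columns=sids)
    taus = np.linspace(12, 18, n_cells)
    vals.loc["MAPT"] = taus
    # S00 keeps only 999 detected proteins
    vals.iloc[999:, 0] = np.nan
    m = tt.from_values(vals, tt.make_sample_table(
        sids, ["D1"] * n_cells, ["negative"] * n_cells))
    out = tt.filter_cells(m, min_proteins=1000, tau_low_percentile=5)
    assert "S00" not in out.sample_ids
    # of the 20 remaining distinct taus, only the lowest falls below the cut
    remaining_taus = np.sort(taus[1:])
    cut = np.percentile(remaining_taus, 5)
    expect_dropped = {sids[i] for i in range(1, n_cells) if taus[i] < cut}
    assert set(m.sample_ids) - set(out.sample_ids) - {"S00"} == expect_dropped
    assert len(expect_dropped) == 1


def test_cell_filter_identity_when_all_pass():
    vals = pd.DataFrame(np.full((5, 4), 15.0),
                        index=["MAPT", "A", "B", "C", "D"],
                        columns=["S1", "S2", "S3", "S4"])
    m = tt.from_values(vals, tt.make_sample_table(
        ["S1", "S2", "S3", "S4"], ["D1"] * 4, ["negative"] * 4))
    out = tt.filter_cells(m, min_proteins=2, tau_low_percentile=0)
    assert list(out.sample_ids) == ["S1", "S2", "S3", "S4"]


def test_filters_idempotent_and_preserve_observed(small_cohort):
    cfg, matrix, _ = small_cohort
    mm = tt.inject_missingness(matrix, cfg)
    once = tt.filter_proteins_by_detection(
        tt.remove_contaminants(mm), 0.3)
    twice = tt.filter_proteins_by_detection(
        tt.remove_contaminants(once), 0.3)
    pd.testing.assert_frame_equal(once.values, twice.values)
    # observed entries unchanged by the filters
    common = once.protein_ids
    pd.testing.assert_frame_equal(once.values.loc[common],
                                  mm.values.loc[common])


def test_imputation_moments_and_mask():
    """Imputed draws land at mu - 1.8 sigma with spread 0.3 sigma; the
    observed half of the column is untouched and no NaN remains."""
    rng = np.random.default_rng(1)
    obs = rng.normal(0, 1, 5000)
    obs = (obs - obs.mean()) / obs.std(ddof=1) + 20.0  # exact mu=20, sd=1
    vals = pd.DataFrame(
        {"S1": np.concatenate([obs, np.full(5000, np.nan)])},
        index=[f"P{i}" for i in range(10000)],
    )
    m = tt.from_values(vals, tt.make_sample_table(["S1"], ["D1"], ["negative"]))
    out = tt.impute_downshifted_normal(m, seed=7)
    assert out.is_complete
    imp = out.values.loc[out.imputed["S1"], "S1"]
    assert len(imp) == 5000
    assert imp.mean() == pytest.approx(18.2, abs=3 * 0.3 / np.sqrt(5000))
    assert imp.std(ddof=1) == pytest.approx(0.3, rel=0.05)
    np.testing.assert_array_equal(
        out.values.loc[~out.imputed["S1"], "S1"].to_numpy(), obs)


def test_imputation_identity_and_determinism(toy_matrix):
    out1 = tt.impute_downshifted_normal(toy_matrix, seed=3)
    out2 = tt.impute_downshifted_normal(toy_matrix, seed=3)
    pd.testing.assert_frame_equal(out1.values, out2.values)
    # a complete matrix passes through unchanged
    again = tt.impute_downshifted_normal(out1, seed=99)
    pd.testing.assert_frame_equal(again.values, out1.values)


def test_imputation_needs_two_observed():
    vals = pd.DataFrame({"S1": [15.0, np.nan, np.nan]}, index=["A", "B", "C"])
    m = tt.from_values(vals, tt.make_sample_table(["S1"], ["D1"], ["negative"]))
    with pytest.raises(MatrixError, match="S1"):
        tt.impute_downshifted_normal(m, seed=0)
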