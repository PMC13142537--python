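"""PTM report filtering and quantification of phosphorylation excess.

Two concerns live here:

* filtering long-format PTM peptide reports by the stack of q-value /
  confidence thresholds used for the K-GG (ubiquitin remnant) search, with
  an extra site-localization cut (>= 0.99) for the phospho search;
* quantifying phospho-site occupancy beyond what tau abundance predicts: a
  Gaussian linear mixed model with a donor random intercept is fitted on
  pTau-negative samples only (phospho ~ tau), residuals are computed for all
  cells, and the positive-group excess is estimated as a pTau-status fixed
  effect in a refit on all cells. A log2 excess beta converts to fold change
  as 2**beta (beta = 1.16 -> 2.2-fold).

The mixed model is fitted by restricted maximum likelihood, profiling the
variance ratio lambda = sigma_donor^2 / sigma_resid^2: given lambda the GLS
solution is closed-form (Woodbury identity per donor block), and a 1-D
bounded search over log(lambda) — with lambda = 0 evaluated explicitly so the
no-donor-variance boundary solution, which equals OLS, is attainable exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

# (canonical column, operator, threshold) — strictness exactly as stated
KGG_RULES = (
    ("lib_q_value", "<", 0.5),
    ("global_q_value", "<", 0.5),
    ("lib_peptidoform_q_value", "<", 0.5),
    ("global_peptidoform_q_value", "<", 0.5),
    ("q_value", "<", 0.01),
    ("pep", "<=", 0.05),
    ("peptidoform_q_value", "<", 0.01),
    ("ptm_site_confidence", ">", 0.9),
)
PHOSPHO_RULES = KGG_RULES + (("site_localization_probability", ">=", 0.99),)

_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


def canonical_column(name: str) -> str:
    """Normalize a report column name: case-insensitive, '.' == '_'."""
    return str(name).strip().lower().replace(".", "_").replace(" ", "_")


def normalize_report_columns(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out.columns = [canonical_column(c) for c in out.columns]
    return out


def apply_ptm_filters(records: pd.DataFrame, mode: str = "phospho") -> pd.DataFrame:
    """Retain records satisfying every threshold of the chosen rule set.

    ``mode`` is ``"phospho"`` (adds the site-localization >= 0.99 rule) or
    ``"kgg"`` (the 8 base thresholds). Column names are matched
    case-insensitively with dots and underscores interchangeable.
    """
    if mode not in ("phospho", "kgg"):
        raise ValueError("mode must be 'phospho' or 'kgg'")
    rules = PHOSPHO_RULES if mode == "phospho" else KGG_RULES
    rec = normalize_report_columns(records)
    keep = np.ones(len(rec), dtype=bool)
    for col, op, thr in rules:
        if col not in rec.columns:
            raise KeyError(f"PTM report is missing required column {col!r}")
        keep &= _OPS[op](rec[col].to_numpy(dtype=float), thr)
    return records.iloc[np.flatnonzero(keep)]


def kgg_outlier_policy(intensities: pd.Series, remove_max: bool = False) -> pd.Series:
    """Optionally blank the single maximum intensity (K48 outlier handling).

    Off by default. A tie at the maximum raises: the caller must decide
    explicitly which observation to discard.
    """
    if len(intensities) < 2:
        raise ValueError("need at least 2 intensity values")
    if not remove_max:
        return intensities.copy()
    vals = intensities.to_numpy(dtype=float)
    mx = np.nanmax(vals)
    at_max = np.flatnonzero(vals == mx)
    if len(at_max) > 1:
        raise ValueError(
            f"{len(at_max)} values tie at the maximum {mx}; "
            "resolve the tie explicitly before removal"
        )
    out = intensities.copy()
    out.iloc[at_max[0]] = np.nan
    return out


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model (profile REML)
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    """A fitted Gaussian LMM with one random intercept per donor."""

    beta: float  # slope of phospho on tau (log2 per log2)
    intercept: float
    sigma_donor2: float
    sigma_resid2: float
    donor_intercepts: dict
    n: int
    coefficients: np.ndarray = field(default=None, repr=False)
    se: np.ndarray = field(default=None, repr=False)
    feature_names: tuple = ("intercept", "tau")

    @property
    def variance_ratio(self) -> float:
        return self.sigma_donor2 / self.sigma_resid2 if self.sigma_resid2 else np.inf


def _reml_neg2loglik(lam: float, X, y, group_idx, n_groups):
    n, p = X.shape
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    for g in range(n_groups):
        m = group_idx == g
        Xg, yg = X[m], y[m]
        ng = int(m.sum())
        c = lam / (1.0 + lam * ng)
        sX = Xg.sum(axis=0)
        sy = yg.sum()
        XtViX += Xg.T @ Xg - c * np.outer(sX, sX)
        XtViy += Xg.T @ yg - c * sX * sy
    beta = np.linalg.solve(XtViX, XtViy)
    quad = 0.0
    logdetV = 0.0
    resid = y - X @ beta
    for g in range(n_groups):
        m = group_idx == g
        rg = resid[m]
        ng = int(m.sum())
        c = lam / (1.0 + lam * ng)
        quad += rg @ rg - c * rg.sum() ** 2
        logdetV += np.log1p(lam * ng)
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    crit = (n - p) * np.log(quad) + logdetV + logdetXtViX
    return crit, beta, quad, XtViX, resid


def _fit_lmm(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Profile-REML fit; returns (beta_vec, sigma_u2, sigma_e2, blups, cov)."""
    uniq, group_idx = np.unique(groups, return_inverse=True)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular design (e.g. constant predictor)")

    def crit_of(theta):
        return _reml_neg2loglik(np.exp(theta), X, y, group_idx, len(uniq))[0]

    res = minimize_scalar(crit_of, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-10})
    crit0 = _reml_neg2loglik(0.0, X, y, group_idx, len(uniq))[0]
    lam = float(np.exp(res.x)) if res.fun < crit0 else 0.0
    crit, beta, quad, XtViX, resid = _reml_neg2loglik(
        lam, X, y, group_idx, len(uniq)
    )
    sigma_e2 = quad / (n - p)
    sigma_u2 = lam * sigma_e2
    blups = {}
    for g, name in enumerate(uniq):
        m = group_idx == g
        ng = int(m.sum())
        blups[name] = float(lam * resid[m].sum() / (1.0 + lam * ng))
    cov = np.linalg.inv(XtViX) * sigma_e2
    return beta, float(sigma_u2), float(sigma_e2), blups, cov


def fit_random_intercept_lmm(
    y, x, donor, subset=None
) -> LmmFit:
    """Fit phospho ~ tau with a donor random intercept, by profile REML.

    ``subset`` optionally restricts the fit (boolean mask aligned with the
    inputs), e.g. to pTau-negative samples, which is the baseline model the
    excess analysis builds on.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    donor = np.asarray(donor)
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        y, x, donor = y[subset], x[subset], donor[subset]
    n = len(y)
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    if len(np.unique(donor)) < 2:
        raise ValueError("need at least 2 donors")
    if np.ptp(x) == 0:
        raise ValueError("singular design: tau predictor is constant")
    X = np.column_stack([np.ones(n), x])
    beta, s_u2, s_e2, blups, cov = _fit_lmm(X, y, donor)
    return LmmFit(
        beta=float(beta[1]),
        intercept=float(beta[0]),
        sigma_donor2=s_u2,
        sigma_resid2=s_e2,
        donor_intercepts=blups,
        n=n,
        coefficients=beta,
        se=np.sqrt(np.diag(cov)),
    )


@dataclass
class ExcessReport:
    """Phosphorylation excess beyond tau abundance."""

    residuals: pd.Series  # per-sample residual about the negative-cell fit
    mean_residual: dict  # per pTau group
    beta_excess: float  # fixed pTau-status offset from the all-cells refit
    se_excess: float
    fold_change: float  # 2 ** beta_excess


def fold_change_from_log2(beta: float) -> float:
    """Convert a log2 offset to a fold change: 2**beta."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return float(2.0 ** beta)


def phospho_excess(
    fit: LmmFit, y, x, donor, ptau_status
) -> ExcessReport:
    """Residual excess of phospho intensity in pTau-positive cells.

    Residuals use the negative-cell fit (donor intercept included for donors
    seen in that fit, fixed part only otherwise). The excess ``beta_excess``
    is re-estimated as a pTau-status fixed effect in an LMM over all cells,
    which is the same contrast as the residual framing but comes with a
    standard error.
    """
    y_arr = np.asarray(y, dtype=float)
    x_arr = np.asarray(x, dtype=float)
    donor_arr = np.asarray(donor)
    status = np.asarray(ptau_status)
    pred = fit.intercept + fit.beta * x_arr
    pred = pred + np.array([fit.donor_intercepts.get(d, 0.0) for d in donor_arr])
    resid = y_arr - pred
    index = y.index if isinstance(y, pd.Series) else pd.RangeIndex(len(y_arr))
    residuals = pd.Series(resid, index=index, name="residual")
    means = {
        g: float(resid[status == g].mean())
        for g in ("negative", "positive")
        if (status == g).any()
    }
    is_pos = (status == "positive").astype(float)
    X = np.column_stack([np.ones(len(y_arr)), x_arr, is_pos])
    beta, _, _, _, cov = _fit_lmm(X, y_arr, donor_arr)
    b_exc = float(beta[2])
    return ExcessReport(
        residuals=residuals,
        mean_residual=means,
        beta_excess=b_exc,
        se_excess=float(np.sqrt(cov[2, 2])),
        fold_change=fold_change_from_log2(b_exc),
    )


def detection_fraction_by_group(
    records: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Per-site, per-group fraction of samples with a detected intensity.

    ``records`` is long format with columns ``site``, ``sample_id`` and
    ``intensity`` (NaN = not detected); ``groups`` maps sample_id -> group
    label. Samples absent from ``records`` for a site count as not detected.
    """
    for col in ("site", "sample_id", "intensity"):
        if col not in records.columns:
            raise KeyError(f"records is missing column {col!r}")
    out = {}
    n_by_group = groups.value_counts()
    for site, sub in records.groupby("site"):
        det = sub.loc[sub["intensity"].notna(), "sample_id"]
        det_groups = groups.reindex(det).value_counts()
        out[site] = (det_groups / n_by_group).reindex(n_by_group.index).fillna(0.0)
    return pd.DataFrame(out).T.rename_axis("site")
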