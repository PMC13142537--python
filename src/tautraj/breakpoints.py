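"""Temporal ordering of molecular responses via piecewise-linear breakpoints.

Each protein's z-scored intensity profile along the tau axis is modelled as
a continuous piecewise-linear function with 0, 1 or 2 breakpoints. Fitting
uses Muggeo-style iterative linearization (the breakpoint update comes from
the ratio of the gap-covariate and hinge-covariate coefficients) with
bootstrap restarting to escape local optima; one-breakpoint fits are also
seeded from the grid of midpoints between consecutive sorted x values, which
makes the global optimum reliably reachable. The breakpoint count is chosen
per protein by minimizing BIC = n*ln(RSS/n) + k*ln(n) with k = 2 + 2B
(intercept, base slope, plus one slope change and one position per
breakpoint). One-breakpoint proteins with a breakpoint in the central
0.20–0.80 fraction of the tau range are stratified into four modules by
breakpoint timing (early vs late, split at the valley of the breakpoint
position density) and slope direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MODULES = ("early_up_plateau", "early_down_plateau", "late_decline", "late_recover")


class FitError(RuntimeError):
    """Raised when a piecewise fit cannot be attempted on the given data."""


# ---------------------------------------------------------------------------
# Outlier handling
# ---------------------------------------------------------------------------

def winsorize_mad(y, threshold: float = 3.0, clip: bool = False):
    """Remove (or, with ``clip=True``, clip) values beyond ±threshold MAD.

    The MAD is scaled by 1.4826 for consistency with a normal sigma. Returns
    ``(cleaned_values, keep_mask)``; with ``clip=True`` the mask is all-True
    and out-of-range values are clipped to the fence instead. A zero MAD
    (a majority of identical values) degenerates the rule to "remove any
    value different from the median" and triggers a warning.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 values")
    med = np.median(y)
    mad = 1.4826 * np.median(np.abs(y - med))
    if mad == 0:
        warnings.warn(
            "MAD is zero; the ±3 MAD rule degenerates to removing every "
            "value different from the median"
        )
    dev = np.abs(y - med)
    keep = dev <= threshold * mad
    if clip:
        return np.clip(y, med - threshold * mad, med + threshold * mad), \
            np.ones(len(y), dtype=bool)
    return y[keep], keep


# ---------------------------------------------------------------------------
# Piecewise fitting
# ---------------------------------------------------------------------------

@dataclass
class PiecewiseFit:
    """A continuous piecewise-linear least-squares fit for one protein."""

    protein_id: str | None
    n_breakpoints: int
    breakpoints: tuple  # ascending, strictly inside the x-range
    intercept: float
    slopes: tuple  # alpha1 .. alpha(B+1)
    rss: float
    n: int
    bic: float = np.nan
    converged: bool = True

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = self.intercept + self.slopes[0] * x
        for b, psi in enumerate(self.breakpoints):
            gamma = self.slopes[b + 1] - self.slopes[b]
            out = out + gamma * np.maximum(0.0, x - psi)
        return out


def _hinge_design(x: np.ndarray, psis: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for psi in psis:
        cols.append(np.maximum(0.0, x - psi))
    return np.column_stack(cols)


def _rss_at(x: np.ndarray, y: np.ndarray, psis: np.ndarray):
    """Least-squares coefficients and RSS for fixed breakpoints."""
    A = _hinge_design(x, psis)
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), coef

def _valid(psis: np.ndarray, lo: float, hi: float, min_gap: float) -> bool:
    if np.any(psis <= lo) or np.any(psis >= hi):
        return False
    return bool(np.all(np.diff(psis) >= min_gap)) if len(psis) > 1 else True


def _muggeo(x, y, psis0, lo, hi, min_gap, max_iter=30, tol=None):
    """Iterative-linearization polish from a starting breakpoint vector.

    Returns (psis, rss, converged); falls back to the best iterate seen.
    """
    span = hi - lo
    tol = tol if tol is not None else 1e-10 * span
    psis = np.sort(np.asarray(psis0, dtype=float))
    if not _valid(psis, lo, hi, min_gap):
        return psis, np.inf, False
    best_rss, _ = _rss_at(x, y, psis)
    best_psis = psis.copy()
    converged = False
    for _ in range(max_iter):
        U = [np.maximum(0.0, x - p) for p in psis]
        V = [-(x > p).astype(float) for p in psis]
        A = np.column_stack([np.ones_like(x), x] + U + V)
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        B = len(psis)
        gam = coef[2:2 + B]
        delta = coef[2 + B:2 + 2 * B]
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(np.abs(gam) > 1e-12, delta / gam, 0.0)
        if not np.all(np.isfinite(step)):
            break
        new = np.sort(psis + step)
        # project into the admissible region
        new = np.clip(new, lo + 1e-9 * span, hi - 1e-9 * span)
        for b in range(1, len(new)):
            new[b] = max(new[b], new[b - 1] + min_gap)
        if np.any(new >= hi):
            break
        rss_new, _ = _rss_at(x, y, new)
        if rss_new < best_rss - 1e-15:
            best_rss, best_psis = rss_new, new.copy()
        if np.max(np.abs(new - psis)) < tol:
            psis = new
            converged = True
            break
        psis = new
    return best_psis, best_rss, converged


def fit_piecewise(
    x,
    y,
    n_breakpoints: int,
    n_boot: int = 1000,
    seed=None,
    protein_id: str | None = None,
    grid_cap: int = 200,
) -> PiecewiseFit:
    """Fit a continuous piecewise-linear model with B breakpoints.

    B = 0 is ordinary least squares. For B >= 1 the fit is Muggeo iterative
    linearization started from deterministic candidates (for B = 1, the
    midpoints between consecutive distinct sorted x values; for B = 2,
    quantile pairs), followed by ``n_boot`` bootstrap restarts: residuals are
    resampled onto the fitted values, the perturbed data are refitted, and
    the resulting breakpoints are kept if they improve the RSS on the
    original data. Deterministic for a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    B = int(n_breakpoints)
    if B not in (0, 1, 2):
        raise FitError("n_breakpoints must be 0, 1 or 2")
    ux = np.unique(x)
    need = 2 * (B + 1) + B
    if len(ux) < need:
        raise FitError(
            f"need at least {need} distinct x values for B={B}, got {len(ux)}"
        )
    n = len(x)

    if B == 0:
        rss, coef = _rss_at(x, y, np.empty(0))
        return PiecewiseFit(protein_id, 0, (), float(coef[0]), (float(coef[1]),),
                            rss, n, converged=True)

    rng = np.random.default_rng(seed)
    lo, hi = float(ux[0]), float(ux[-1])
    span = hi - lo
    min_gap = max(span * 1e-6, np.min(np.diff(ux)) * 0.5)

    # deterministic candidate starts
    if B == 1:
        mids = (ux[:-1] + ux[1:]) / 2.0
        if len(mids) > grid_cap:
            take = np.linspace(0, len(mids) - 1, grid_cap).round().astype(int)
            mids = mids[np.unique(take)]
        cand_rss = np.array([_rss_at(x, y, np.array([m]))[0] for m in mids])
        starts = [np.array([m]) for m in mids[np.argsort(cand_rss)[:3]]]
        best_psis = np.array([mids[int(np.argmin(cand_rss))]])
        best_rss = float(cand_rss.min())
    else:
        qs = np.quantile(x, np.linspace(0.1, 0.9, 9))
        qs = np.unique(qs)
        pairs = [
            np.array([a, b])
            for i, a in enumerate(qs)
            for b in qs[i + 1:]
            if b - a >= min_gap
        ]
        if not pairs:
            raise FitError("x values too degenerate for a 2-breakpoint fit")
        pair_rss = [_rss_at(x, y, p)[0] for p in pairs]
        order = np.argsort(pair_rss)
        starts = [pairs[i] for i in order[:3]]
        best_psis = pairs[int(order[0])].copy()
        best_rss = float(pair_rss[int(order[0])])

    converged = False
    for s in starts:
        psis, rss, conv = _muggeo(x, y, s, lo, hi, min_gap)
        if rss < best_rss - 1e-15:
            best_rss, best_psis = rss, psis
            converged = conv
        elif np.allclose(psis, best_psis) and conv:
            converged = True

    # bootstrap restarting: perturb, refit, keep the best on the original data
    _, coef0 = _rss_at(x, y, best_psis)
    fitted = _hinge_design(x, best_psis) @ coef0
    resid = y - fitted
    for _ in range(int(n_boot)):
        yb = fitted + rng.choice(resid, size=n, replace=True)
        jitter = best_psis + rng.normal(0.0, 0.05 * span, size=B)
        psis_b, _, _ = _muggeo(x, yb, jitter, lo, hi, min_gap, max_iter=10)
        if not _valid(psis_b, lo, hi, min_gap):
            continue
        rss_b, _ = _rss_at(x, y, psis_b)
        if rss_b < best_rss - 1e-12:
            psis, rss, conv = _muggeo(x, y, psis_b, lo, hi, min_gap)
            if rss < best_rss:
                best_rss, best_psis, converged = rss, psis, conv
                _, coef0 = _rss_at(x, y, best_psis)
                fitted = _hinge_design(x, best_psis) @ coef0
                resid = y - fitted

    rss, coef = _rss_at(x, y, best_psis)
    slopes = [float(coef[1])]
    for b in range(B):
        slopes.append(slopes[-1] + float(coef[2 + b]))
    return PiecewiseFit(
        protein_id,
        B,
        tuple(float(p) for p in best_psis),
        float(coef[0]),
        tuple(slopes),
        float(rss),
        n,
        converged=converged,
    )


def bic(fit: PiecewiseFit) -> float:
    """BIC = n*ln(RSS/n) + k*ln(n), k = 2 + 2B; RSS = 0 maps to -inf."""
    if fit.rss <= 0:
        warnings.warn("RSS is zero; BIC taken as -inf (perfect fit)")
        return float("-inf")
    k = 2 + 2 * fit.n_breakpoints
    return float(fit.n * np.log(fit.rss / fit.n) + k * np.log(fit.n))


def select_model(fits) -> PiecewiseFit:
    """Minimal-BIC fit among the attempted models; ties favour fewer breaks."""
    fits = [f for f in fits if f is not None]
    if not fits:
        raise FitError("all candidate fits failed")
    for f in fits:
        if not np.isfinite(f.bic) and f.bic != float("-inf"):
            f.bic = bic(f)
    best = None
    for f in sorted(fits, key=lambda f: f.n_breakpoints):
        if best is None or f.bic < best.bic:
            best = f
    return best


def filter_breakpoint_range(
    fits, x_range: tuple[float, float], lo: float = 0.20, hi: float = 0.80
):
    """Keep one-breakpoint fits whose breakpoint lies in the central
    [lo, hi] fraction (inclusive) of the tau range, avoiding edge effects."""
    xmin, xmax = x_range
    span = xmax - xmin
    if span <= 0:
        raise ValueError("x_range must have positive width")
    out = []
    for f in fits:
        if f.n_breakpoints != 1:
            continue
        frac = (f.breakpoints[0] - xmin) / span
        if lo <= frac <= hi:
            out.append(f)
    return out


@dataclass
class ModuleAssignment:
    protein_id: str
    timing: str  # early | late
    module: str
    breakpoint: float


def stratify_modules(retained_fits, grid_size: int = 512):
    """Split one-breakpoint proteins into the four trajectory modules.

    The early/late cut is the density minimum between the two largest modes
    of a Gaussian KDE (Silverman bandwidth) of breakpoint positions; if the
    distribution is unimodal the median is used and flagged. Modules:
    early + rising first segment -> early_up_plateau; early + falling ->
    early_down_plateau; late + falling second segment -> late_decline;
    late + rising -> late_recover. A zero slope defers to the other segment.

    Returns ``(assignments, cut, used_fallback)``.
    """
    fits = list(retained_fits)
    if len(fits) < 10:
        raise ValueError(f"need at least 10 retained fits, got {len(fits)}")
    pos = np.array([f.breakpoints[0] for f in fits])
    used_fallback = False
    if np.ptp(pos) == 0:
        cut = float(pos[0])
        used_fallback = True
    else:
        kde = stats.gaussian_kde(pos, bw_method="silverman")
        grid = np.linspace(pos.min(), pos.max(), grid_size)
        dens = kde(grid)
        interior = np.flatnonzero(
            (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
        ) + 1
        maxima = list(interior)
        if dens[0] > dens[1]:
            maxima.insert(0, 0)
        if dens[-1] > dens[-2]:
            maxima.append(grid_size - 1)
        if len(maxima) >= 2:
            top2 = sorted(sorted(maxima, key=lambda i: dens[i])[-2:])
            i0, i1 = top2
            cut = float(grid[i0 + int(np.argmin(dens[i0:i1 + 1]))])
        else:
            cut = float(np.median(pos))
            used_fallback = True
            warnings.warn(
                "breakpoint distribution is unimodal; early/late cut "
                "falls back to the median"
            )
    assignments = []
    for f in fits:
        early = f.breakpoints[0] <= cut
        a1, a2 = f.slopes[0], f.slopes[1]
        primary = a1 if early else a2
        if primary == 0:
            other = a2 if early else a1
            primary = other if other != 0 else 1.0
            warnings.warn(
                f"protein {f.protein_id!r}: zero slope; direction taken from "
                "the other segment"
            )
        if early:
            module = "early_up_plateau" if primary > 0 else "early_down_plateau"
        else:
            module = "late_decline" if primary < 0 else "late_recover"
        assignments.append(
            ModuleAssignment(f.protein_id, "early" if early else "late",
                             module, f.breakpoints[0])
        )
    return assignments, cut, used_fallback


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class BreakpointReport:
    """Per-protein piecewise-fit table plus module stratification."""

    table: pd.DataFrame
    cut: float | None
    used_fallback: bool
    summary: dict = field(default_factory=dict)


_REPORT_COLUMNS = [
    "protein_id", "n_breakpoints", "bp1", "bp2", "intercept",
    "alpha1", "alpha2", "alpha3", "rss", "bic", "converged",
    "retained", "timing", "module",
]


def run_breakpoint_analysis(
    matrix,
    trajectory,
    n_boot: int = 1000,
    seed: int = 0,
    mad_threshold: float = 3.0,
    range_lo: float = 0.20,
    range_hi: float = 0.80,
    exclude=("MAPT",),
) -> BreakpointReport:
    """Full breakpoint pipeline over a matrix and a tau-proxy trajectory.

    Per protein: winsorize (±mad_threshold MAD removal) -> z-score -> fit
    B in {0, 1, 2} -> BIC selection; then range-filter the one-breakpoint
    fits and stratify them into the four modules. Deterministic for a fixed
    seed.
    """
    matrix.require_complete("run_breakpoint_analysis")
    axis = trajectory.values.reindex(matrix.sample_ids)
    if axis.isna().any():
        raise ValueError("trajectory does not cover all samples")
    x_all = axis.to_numpy(dtype=float)
    x_range = (float(x_all.min()), float(x_all.max()))

    proteins = [p for p in matrix.protein_ids if p not in set(exclude)]
    children = np.random.SeedSequence(seed).spawn(len(proteins))
    rows = []
    selected = []
    for pid, ss in zip(proteins, children):
        y_raw = matrix.values.loc[pid].to_numpy(dtype=float)
        _, keep = winsorize_mad(y_raw, mad_threshold)
        y = y_raw[keep]
        x = x_all[keep]
        sd = y.std(ddof=0)
        if sd == 0:
            rows.append({"protein_id": pid, "n_breakpoints": -1,
                         "converged": False})
            continue
        yz = (y - y.mean()) / sd
        fits = []
        rng = np.random.default_rng(ss)
        for B in (0, 1, 2):
            try:
                f = fit_piecewise(x, yz, B, n_boot=n_boot, seed=rng,
                                  protein_id=pid)
                f.bic = bic(f)
                fits.append(f)
            except FitError:
                fits.append(None)
        try:
            best = select_model(fits)
        except FitError:
            rows.append({"protein_id": pid, "n_breakpoints": -1,
                         "converged": False})
            continue
        selected.append(best)
        bps = list(best.breakpoints) + [np.nan, np.nan]
        slopes = list(best.slopes) + [np.nan, np.nan]
        rows.append(
            {
                "protein_id": pid,
                "n_breakpoints": best.n_breakpoints,
                "bp1": bps[0],
                "bp2": bps[1],
                "intercept": best.intercept,
                "alpha1": slopes[0],
                "alpha2": slopes[1],
                "alpha3": slopes[2],
                "rss": best.rss,
                "bic": best.bic,
                "converged": best.converged,
            }
        )
    table = pd.DataFrame(rows)
    retained = filter_breakpoint_range(selected, x_range, range_lo, range_hi)
    retained_ids = {f.protein_id for f in retained}
    table["retained"] = table["protein_id"].isin(retained_ids)
    table["timing"] = pd.NA
    table["module"] = pd.NA
    cut = None
    used_fallback = False
    if len(retained) >= 10:
        assignments, cut, used_fallback = stratify_modules(retained)
        amap = {a.protein_id: a for a in assignments}
        # timing is meaningful for every one-breakpoint fit relative to the
        # cut; the module label is defined only for range-retained fits
        is_b1 = table["n_breakpoints"] == 1
        table.loc[is_b1, "timing"] = np.where(
            table.loc[is_b1, "bp1"] <= cut, "early", "late"
        )
        table["module"] = table["protein_id"].map(
            lambda p: amap[p].module if p in amap else pd.NA
        )
    table = table.reindex(columns=_REPORT_COLUMNS)
    counts = table["n_breakpoints"].value_counts().to_dict()
    summary = {
        "n_proteins": len(proteins),
        "n_linear": int(counts.get(0, 0)),
        "n_nonlinear": int(counts.get(1, 0) + counts.get(2, 0)),
        "n_failed": int(counts.get(-1, 0)),
        "n_retained": len(retained),
        "module_counts": table["module"].value_counts(dropna=True).to_dict(),
        "early_late_cut": cut,
        "bic_k": "2 + 2B",
    }
    return BreakpointReport(table, cut, used_fallback, summary)
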