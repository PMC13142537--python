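"""Protein-by-protein association with the trajectory axis.

Pearson correlation screen with Benjamini–Hochberg FDR control (q < 0.05
marks significance), Ward hierarchical clustering of significant proteins,
curated-panel screening (e.g. cell-death proteins), and a self-contained
hypergeometric over-representation test against GMT gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .matrix import ProteomeMatrix
from .trajectory import TrajectoryResult

SIG_THRESHOLD = 0.05


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate_with_axis(
    matrix: ProteomeMatrix,
    trajectory: TrajectoryResult,
    sig_threshold: float = SIG_THRESHOLD,
) -> pd.DataFrame:
    """Pearson r of every protein against the axis, with BH q-values.

    Returns a DataFrame indexed by protein_id with columns
    ``r, p, q, significant, rank, tested``. Zero-variance proteins are
    flagged ``tested=False`` and excluded from the FDR adjustment; ``rank``
    orders significant proteins by |r| (1 = strongest).
    """
    matrix.require_complete("correlate_with_axis")
    axis = trajectory.values.reindex(matrix.sample_ids)
    if axis.isna().any():
        raise ValueError("trajectory does not cover all samples in the matrix")
    x = axis.to_numpy(dtype=float)
    Y = matrix.values.to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples for the correlation screen")

    xc = x - x.mean()
    sx = np.sqrt((xc ** 2).sum())
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sy = np.sqrt((Yc ** 2).sum(axis=1))
    tested = (sy > 0) & (sx > 0)
    r = np.full(Y.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r[tested] = (Yc[tested] @ xc) / (sy[tested] * sx)
    r = np.clip(r, -1.0, 1.0)

    p = np.full_like(r, np.nan)
    df = n - 2
    rt = r[tested]
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = rt * np.sqrt(df / np.maximum(1.0 - rt ** 2, np.finfo(float).tiny))
    p[tested] = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)

    q = np.full_like(r, np.nan)
    q[tested] = bh_adjust(p[tested])

    out = pd.DataFrame(
        {"r": r, "p": p, "q": q, "tested": tested}, index=matrix.protein_ids
    )
    out["significant"] = (out["q"] < sig_threshold).fillna(False)
    out["rank"] = np.nan
    sig = out.index[out["significant"]]
    if len(sig):
        order = out.loc[sig, "r"].abs().sort_values(ascending=False).index
        out.loc[order, "rank"] = np.arange(1, len(order) + 1)
    return out[["r", "p", "q", "significant", "rank", "tested"]]


def cluster_significant(
    matrix: ProteomeMatrix,
    records: pd.DataFrame,
    k: int,
    trajectory: TrajectoryResult | None = None,
) -> pd.Series:
    """Ward/Euclidean hierarchical clustering of significant proteins.

    Proteins are z-scored across samples before clustering; the tree is cut
    into exactly ``k`` clusters (labels 1..k). Mirrors the k=4 (mini-pool)
    and k=6 (single-cell) analyses.
    """
    sig = records.index[records["significant"].astype(bool)]
    if len(sig) < k:
        raise ValueError(
            f"need at least k={k} significant proteins, have {len(sig)}"
        )
    Z = matrix.values.loc[sig]
    if trajectory is not None:
        Z = Z[trajectory.values.sort_values(kind="mergesort").index]
    z = stats.zscore(Z.to_numpy(dtype=float), axis=1, ddof=0)
    labels = fcluster(linkage(pdist(z, metric="euclidean"), method="ward"),
                      t=k, criterion="maxclust")
    return pd.Series(labels, index=sig, name="cluster")


@dataclass
class PanelReport:
    """Result of screening a curated protein panel against the axis."""

    panel: list
    detected: list
    records: pd.DataFrame  # r/p/q/significant restricted to the panel (BH within panel)
    intensities: pd.DataFrame  # panel proteins × samples, samples ordered by axis
    note: str = "BH correction computed within the panel"


def screen_panel(
    matrix: ProteomeMatrix,
    panel,
    trajectory: TrajectoryResult,
    sig_threshold: float = SIG_THRESHOLD,
) -> PanelReport:
    """Intersect a curated panel with the matrix and report associations."""
    panel = list(panel)
    if len(panel) == 0:
        raise ValueError("panel is empty")
    deduped = list(dict.fromkeys(panel))
    if len(deduped) < len(panel):
        warnings.warn("duplicate ids in panel were de-duplicated")
    detected = [p for p in deduped if p in matrix.protein_ids]
    if not detected:
        warnings.warn("no panel protein detected in the matrix")
        empty = pd.DataFrame(columns=["r", "p", "q", "significant", "rank", "tested"])
        return PanelReport(deduped, [], empty, pd.DataFrame())
    sub = matrix.subset_proteins(detected)
    records = correlate_with_axis(sub, trajectory, sig_threshold)
    order = trajectory.values.sort_values(kind="mergesort").index
    return PanelReport(deduped, detected, records, sub.values[order])


def ora_hypergeometric(query, gene_sets: dict, background) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    For each gene set: population = background, successes = set ∩ background,
    draws = |query|, p = P(X >= overlap); BH adjustment across tested sets.
    Sets disjoint from the background are skipped with a warning.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        missing = sorted(query - background)[:5]
        raise ValueError(f"query is not a subset of background (e.g. {missing})")
    rows = []
    for name, members in gene_sets.items():
        members_bg = set(members) & background
        if not members_bg:
            warnings.warn(f"gene set {name!r} has no member in the background; skipped")
            continue
        overlap = len(query & members_bg)
        p = float(stats.hypergeom.sf(overlap - 1, len(background),
                                     len(members_bg), len(query)))
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": len(members_bg),
                "query_size": len(query),
                "background_size": len(background),
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out
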