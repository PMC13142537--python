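"""Perseus-style preprocessing of the intensity matrix.

Order of operations in the standard pipeline: contaminant removal ->
group-wise detection filtering -> cell-quality filtering -> per-sample
downshifted-normal imputation of the remaining missing values. Observed
values are never altered by any step; imputation only fills gaps and marks
them in the ``imputed`` mask.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import MatrixError, ProteomeMatrix

TAU_ID = "MAPT"


def log2_transform(matrix: ProteomeMatrix) -> ProteomeMatrix:
    """log2-transform raw (linear-scale) intensities; non-positive -> missing."""
    out = matrix.copy()
    v = out.values.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        lv = np.where(v > 0, np.log2(np.where(v > 0, v, 1.0)), np.nan)
    out.values.loc[:, :] = lv
    out.detected.loc[:, :] = ~np.isnan(lv)
    out.log.append("log2_transform")
    return out


def remove_contaminants(matrix: ProteomeMatrix, prefix: str = "Cont_") -> ProteomeMatrix:
    """Drop rows whose protein id starts with the contaminant prefix."""
    keep = ~matrix.protein_ids.astype(str).str.startswith(prefix)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        warnings.warn("all proteins flagged as contaminants; matrix is empty")
    out = matrix.subset_proteins(matrix.protein_ids[keep])
    out.log.append(f"remove_contaminants: removed {n_removed}")
    return out


def filter_proteins_by_detection(
    matrix: ProteomeMatrix, min_frac: float, group_col: str = "ptau_status"
) -> ProteomeMatrix:
    """Keep proteins detected in at least ``min_frac`` of samples of either
    pTau group (inclusive >=). 0.7 for mini-pools, 0.3 for single cells."""
    groups = matrix.samples[group_col]
    kept = None
    levels = ["positive", "negative"] if group_col == "ptau_status" else \
        sorted(groups.unique())
    for level in levels:
        ids = groups.index[groups == level]
        if len(ids) == 0:
            raise MatrixError(f"group {level!r} is empty")
        frac = matrix.detected[ids].mean(axis=1)
        ok = frac >= min_frac
        kept = ok if kept is None else (kept | ok)
    out = matrix.subset_proteins(matrix.protein_ids[kept])
    out.log.append(
        f"filter_proteins_by_detection(min_frac={min_frac}): "
        f"removed {int((~kept).sum())}"
    )
    return out


def filter_cells(
    matrix: ProteomeMatrix,
    min_proteins: int = 1000,
    tau_low_percentile: float = 5.0,
    tau_id: str = TAU_ID,
) -> ProteomeMatrix:
    """Cell-quality filter: drop samples with fewer than ``min_proteins``
    detected proteins, then drop samples with observed tau below the given
    percentile of observed tau across the remaining samples.

    The percentile uses linear interpolation between order statistics.
    Samples in which tau itself was not detected are also dropped at the
    second step (they cannot be placed on the tau axis).
    """
    if tau_id not in matrix.protein_ids:
        raise MatrixError(f"tau row {tau_id!r} absent from matrix")
    counts = matrix.detected.sum(axis=0)
    keep1 = counts >= min_proteins
    m = matrix.subset_samples(matrix.sample_ids[keep1])

    tau = m.values.loc[tau_id].where(m.detected.loc[tau_id])
    observed = tau.dropna()
    if len(observed) == 0:
        raise MatrixError(f"tau row {tau_id!r} has no observed values after filtering")
    cut = np.percentile(observed.to_numpy(), tau_low_percentile)
    keep2 = tau >= cut  # NaN compares False -> undetected tau dropped
    out = m.subset_samples(m.sample_ids[keep2])
    out.log.append(
        f"filter_cells: removed {int((~keep1).sum())} low-count and "
        f"{int((~keep2).sum())} low-tau samples (cut={cut:.3f})"
    )
    return out


def impute_downshifted_normal(
    matrix: ProteomeMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
) -> ProteomeMatrix:
    """Impute missing values from a downshifted normal, per sample.

    For each sample, the mean mu and standard deviation sigma (ddof=1) of its
    observed values are computed, and each missing entry is drawn from
    Normal(mu - downshift*sigma, (width*sigma)^2). Observed entries are
    untouched; the ``imputed`` mask records filled positions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    out = matrix.copy()
    vals = out.values
    imputed = pd.DataFrame(False, index=vals.index, columns=vals.columns)
    n_filled = 0
    for sid in vals.columns:
        col = vals[sid]
        obs = col.dropna()
        missing = col.index[col.isna()]
        if len(missing) == 0:
            continue
        if len(obs) < 2:
            raise MatrixError(
                f"sample {sid!r} has fewer than 2 observed values; cannot impute"
            )
        mu = float(obs.mean())
        sigma = float(obs.std(ddof=1))
        draws = rng.normal(mu - downshift * sigma, width * sigma, len(missing))
        vals.loc[missing, sid] = draws
        imputed.loc[missing, sid] = True
        n_filled += len(missing)
    out.imputed = imputed
    out.log.append(
        f"impute_downshifted_normal(width={width}, downshift={downshift}): "
        f"filled {n_filled}"
    )
    return out


def preprocess_matrix(
    matrix: ProteomeMatrix,
    min_frac: float = 0.3,
    min_proteins: int = 1000,
    tau_low_percentile: float = 5.0,
    tau_id: str = TAU_ID,
    contaminant_prefix: str = "Cont_",
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
) -> ProteomeMatrix:
    """Full preprocessing chain in the standard order."""
    m = remove_contaminants(matrix, contaminant_prefix)
    m = filter_proteins_by_detection(m, min_frac)
    m = filter_cells(m, min_proteins, tau_low_percentile, tau_id)
    return impute_downshifted_normal(m, width, downshift, seed)
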