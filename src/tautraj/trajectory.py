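"""Ordering samples along the disease (tau-accumulation) axis.

Two orderings are supported, mirroring the two capture modes:

* ``tau_proxy_ordering`` — log2 tau (MAPT) intensity as the axis, used for
  single-cell cohorts where tau abundance itself orders the cells;
* ``diffusion_pseudotime`` — diffusion-map pseudotime from a chosen root
  sample, used for mini-pool cohorts: PCA reduction, kNN graph, adaptive
  Gaussian kernel, Markov-matrix eigendecomposition, multiscale diffusion
  space, and Euclidean distance from the root, min–max scaled to [0, 1].

``bin_by_tau`` provides the 5 equal-width tau bins used for pathway trends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .matrix import MatrixError, ProteomeMatrix

TAU_ID = "MAPT"


@dataclass
class TrajectoryResult:
    """Per-sample scalar ordering along the disease axis."""

    values: pd.Series  # indexed by sample_id
    method: str  # "tau_proxy" | "diffusion_pseudotime"
    root_sample: str | None = None
    parameters: dict = field(default_factory=dict)
    degenerate: bool = False

    def ranks(self) -> pd.Series:
        """1-based ranks; ties broken by stable sample-id order."""
        idx = np.lexsort((self.values.index.to_numpy(), self.values.to_numpy()))
        ranks = pd.Series(0, index=self.values.index, dtype=int)
        ranks.iloc[idx] = np.arange(1, len(ranks) + 1)
        return ranks


def tau_proxy_ordering(matrix: ProteomeMatrix, tau_id: str = TAU_ID) -> TrajectoryResult:
    """Use log2 tau intensity per sample as the trajectory value."""
    if tau_id not in matrix.protein_ids:
        raise MatrixError(f"tau row {tau_id!r} absent from matrix")
    vals = matrix.values.loc[tau_id].copy()
    if vals.isna().any():
        raise MatrixError("tau row has missing values; impute first")
    vals.name = "tau_proxy"
    degenerate = bool(np.ptp(vals.to_numpy()) == 0)
    if degenerate:
        warnings.warn("all tau values equal; ordering is degenerate")
    return TrajectoryResult(vals, "tau_proxy", None, {"tau_id": tau_id}, degenerate)


def diffusion_pseudotime(
    matrix: ProteomeMatrix,
    root_sample: str,
    k_graph: int = 10,
    knn_dm: int = 5,
    n_components: int = 5,
    n_pcs: int = 20,
) -> TrajectoryResult:
    """Diffusion-map pseudotime from a root sample.

    The kernel bandwidth is adaptive: for each sample it equals the distance
    to its ``knn_dm``-th nearest neighbour. Eigenvector signs are fixed by
    making the largest-magnitude entry of each eigenvector positive, so the
    result is deterministic and invariant to sample order.
    """
    matrix.require_complete("diffusion_pseudotime")
    ids = matrix.sample_ids
    n = len(ids)
    if root_sample not in ids:
        raise MatrixError(f"root sample {root_sample!r} not in matrix")
    if n < n_components + 2:
        raise MatrixError(
            f"need at least n_components + 2 = {n_components + 2} samples, got {n}"
        )
    X = matrix.values.T.to_numpy(dtype=float)
    n_pcs_eff = min(n_pcs, n - 1, X.shape[1])
    X = PCA(n_components=n_pcs_eff, svd_solver="full").fit_transform(X)

    k = min(k_graph, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    sigma = dist[:, min(knn_dm, k) - 1]
    sigma = np.maximum(sigma, 1e-12)

    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    w = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    W = coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    A = (W + W.T) / 2.0

    # connectivity is a property of the kNN graph itself, not of the kernel
    # weights (which can underflow between far-apart groups)
    adj = coo_matrix((np.ones_like(w), (rows, cols)), shape=(n, n)).tocsr()
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise MatrixError(
            f"kNN graph is disconnected ({n_comp} components of sizes "
            f"{sizes.tolist()}); increase k_graph"
        )

    d = np.asarray(A.sum(axis=1)).ravel()
    d_isqrt = 1.0 / np.sqrt(d)
    S = (A.multiply(d_isqrt[:, None]).multiply(d_isqrt[None, :])).toarray()
    S = (S + S.T) / 2.0
    eigval, eigvec = np.linalg.eigh(S)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    lam = eigval[1:n_components + 1]
    phi = d_isqrt[:, None] * eigvec[:, 1:n_components + 1]
    # fixed sign convention: largest-magnitude entry positive
    for j in range(phi.shape[1]):
        i = int(np.argmax(np.abs(phi[:, j])))
        if phi[i, j] < 0:
            phi[:, j] = -phi[:, j]
    lam = np.clip(lam, None, 1.0 - 1e-10)
    ms = phi * (lam / (1.0 - lam))

    root_i = int(np.where(ids == root_sample)[0][0])
    pt = np.linalg.norm(ms - ms[root_i], axis=1)
    rng_pt = pt.max() - pt.min()
    if rng_pt == 0:
        raise MatrixError("pseudotime is constant; data carry no structure")
    pt = (pt - pt.min()) / rng_pt
    vals = pd.Series(pt, index=ids, name="pseudotime")
    return TrajectoryResult(
        vals,
        "diffusion_pseudotime",
        root_sample,
        {"k_graph": k_graph, "knn_dm": knn_dm, "n_components": n_components,
         "n_pcs": n_pcs_eff},
    )


def bin_by_tau(trajectory: TrajectoryResult, n_bins: int = 5) -> pd.Series:
    """Assign each sample to one of ``n_bins`` equal-width bins of the axis.

    Internal bins are left-closed/right-open; the right edge of the last bin
    is inclusive, so the maximum lands in bin ``n_bins - 1``.
    """
    if trajectory.method != "tau_proxy":
        raise ValueError("bin_by_tau expects a tau-proxy trajectory")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    v = trajectory.values.to_numpy(dtype=float)
    lo, hi = v.min(), v.max()
    if lo == hi:
        raise ValueError("cannot bin: min equals max")
    width = (hi - lo) / n_bins
    labels = np.floor((v - lo) / width).astype(int)
    labels = np.clip(labels, 0, n_bins - 1)
    return pd.Series(labels, index=trajectory.values.index, name="tau_bin")
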