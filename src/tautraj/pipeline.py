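"""Seeded orchestration of the full analysis over a run directory.

``PipelineConfig`` mirrors the per-stage parameters; the capture mode picks
the dataset-appropriate defaults (single-cell: detection >= 0.30, tau-proxy
axis, k = 6 clusters; mini-pool: detection >= 0.70, diffusion pseudotime,
k = 4 clusters). ``run_pipeline`` executes preprocess -> trajectory ->
correlation screen -> clustering -> pathway scores -> breakpoints, writing
each stage's output as TSV plus a JSON manifest (seed, parameters, hash).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import assoc, breakpoints, preprocess, proteostasis, trajectory
from .io import (read_matrix, read_sample_table, write_matrix,
                 write_trajectory_table)

_MODE_DEFAULTS = {
    "single_cell": {"min_frac": 0.3, "cluster_k": 6, "method": "tau_proxy"},
    "mini_pool": {"min_frac": 0.7, "cluster_k": 4,
                  "method": "diffusion_pseudotime"},
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    matrix_path: str = ""
    metadata_path: str | None = None
    out_dir: str = "tautraj_run"
    capture: str = "single_cell"
    seed: int = 0
    # preprocess
    contaminant_prefix: str = "Cont_"
    min_frac: float | None = None  # None -> capture-mode default
    min_proteins: int = 1000
    tau_low_percentile: float = 5.0
    tau_id: str = "MAPT"
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    # trajectory
    method: str | None = None
    root_sample: str | None = None
    k_graph: int = 10
    knn_dm: int = 5
    n_components: int = 5
    n_bins: int = 5
    # association
    sig_threshold: float = 0.05
    cluster_k: int | None = None
    # breakpoints
    n_boot: int = 1000
    mad_threshold: float = 3.0
    range_lo: float = 0.20
    range_hi: float = 0.80

    def resolved(self) -> "PipelineConfig":
        if self.capture not in _MODE_DEFAULTS:
            raise ConfigError(f"unknown capture mode {self.capture!r}")
        d = _MODE_DEFAULTS[self.capture]
        out = PipelineConfig(**asdict(self))
        if out.min_frac is None:
            out.min_frac = d["min_frac"]
        if out.cluster_k is None:
            out.cluster_k = d["cluster_k"]
        if out.method is None:
            out.method = d["method"]
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def run_pipeline(config: PipelineConfig, matrix=None) -> dict:
    """Run the full pipeline; returns a dict of in-memory stage results.

    ``matrix`` may be passed directly (e.g. a synthetic cohort) instead of
    ``config.matrix_path``. All stage outputs land under ``config.out_dir``.
    """
    cfg = config.resolved()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    stage = "load"
    try:
        if matrix is None:
            matrix = read_matrix(cfg.matrix_path, cfg.metadata_path)
        stage = "preprocess"
        m = preprocess.preprocess_matrix(
            matrix,
            min_frac=cfg.min_frac,
            min_proteins=cfg.min_proteins,
            tau_low_percentile=cfg.tau_low_percentile,
            tau_id=cfg.tau_id,
            contaminant_prefix=cfg.contaminant_prefix,
            width=cfg.impute_width,
            downshift=cfg.impute_downshift,
            seed=cfg.seed,
        )
        write_matrix(m, out / "matrix_preprocessed.tsv",
                     out / "sample_metadata.tsv")
        results["matrix"] = m

        stage = "trajectory"
        if cfg.method == "tau_proxy":
            traj = trajectory.tau_proxy_ordering(m, cfg.tau_id)
        else:
            root = cfg.root_sample
            if root is None:
                # default root: the most pTau-negative sample = lowest tau
                neg = m.samples.index[m.samples["ptau_status"] == "negative"]
                pool = neg if len(neg) else m.sample_ids
                root = m.values.loc[cfg.tau_id, pool].idxmin()
            traj = trajectory.diffusion_pseudotime(
                m, root, cfg.k_graph, cfg.knn_dm, cfg.n_components
            )
        write_trajectory_table(traj.values, out / "trajectory.tsv")
        results["trajectory"] = traj

        stage = "correlate"
        records = assoc.correlate_with_axis(m, traj, cfg.sig_threshold)
        records.to_csv(out / "association.tsv", sep="\t",
                       index_label="protein_id")
        results["association"] = records

        stage = "cluster"
        n_sig = int(records["significant"].sum())
        if n_sig >= cfg.cluster_k:
            clusters = assoc.cluster_significant(m, records, cfg.cluster_k, traj)
            clusters.to_frame().to_csv(out / "clusters.tsv", sep="\t",
                                       index_label="protein_id")
            results["clusters"] = clusters

        stage = "scores"
        scores = proteostasis.score_table(m)
        scores.to_csv(out / "pathway_scores.tsv", sep="\t",
                      index_label="sample_id")
        results["scores"] = scores
        if cfg.method == "tau_proxy" and not traj.degenerate and scores.shape[1]:
            bins = trajectory.bin_by_tau(traj, cfg.n_bins)
            trends = []
            for name in scores.columns:
                t = proteostasis.binned_trend(scores[name], bins)
                t.insert(0, "score", name)
                trends.append(t)
            trends = pd.concat(trends)
            trends.to_csv(out / "pathway_trends.tsv", sep="\t", index=False)
            results["trends"] = trends

        stage = "breakpoints"
        report = breakpoints.run_breakpoint_analysis(
            m,
            traj if cfg.method == "tau_proxy"
            else trajectory.tau_proxy_ordering(m, cfg.tau_id),
            n_boot=cfg.n_boot,
            seed=cfg.seed,
            mad_threshold=cfg.mad_threshold,
            range_lo=cfg.range_lo,
            range_hi=cfg.range_hi,
            exclude=(cfg.tau_id,),
        )
        report.table.to_csv(out / "breakpoints.tsv", sep="\t", index=False)
        results["breakpoints"] = report
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    manifest = {
        "tautraj_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg.seed,
        "parameters": asdict(cfg),
        "parameter_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest()[:16],
        "stages": sorted(results.keys()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
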