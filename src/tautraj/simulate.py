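"""Synthetic single-neuron / mini-pool proteome cohorts with known ground truth.

The generator emulates the statistical structure the downstream trajectory
analysis assumes: a latent tau continuum across cells from a handful of
donors, proteins that respond to tau linearly or with a single hinge
(early or late breakpoint), donor random intercepts, Gaussian measurement
noise on the log2 scale, intensity-dependent (MNAR) missingness, and a
phosphopeptide layer carrying a controllable log2 occupancy excess in
pTau-positive cells.

Every draw is routed through one :class:`numpy.random.Generator` seeded from
``CohortConfig.seed``, so identical configurations reproduce bit-identical
cohorts, masks and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .matrix import ProteomeMatrix, make_sample_table

TAU_ID = "MAPT"

RESPONSE_CLASSES = ("null", "linear_up", "linear_down", "early_break", "late_break")


class ConfigError(ValueError):
    """Raised when a CohortConfig field is invalid; message names the field."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    All intensities are log2 scale. ``frac_*`` give the proportions of
    proteins in each response class; the remainder are null (flat).
    Missingness follows a logistic detection-probability curve in the true
    intensity: P(detect) = logistic((value - missing_midpoint) * missing_steepness).
    """

    n_cells: int = 200
    n_donors: int = 8
    n_proteins: int = 1000
    frac_linear_up: float = 0.15
    frac_linear_down: float = 0.15
    frac_early_break: float = 0.10
    frac_late_break: float = 0.10
    tau_range: tuple[float, float] = (12.0, 18.0)
    breakpoint_early: float = 14.0
    breakpoint_late: float = 17.0
    slope_scale: float = 1.0
    donor_sd: float = 0.5
    noise_sd: float = 0.3
    missing_midpoint: float = 13.0
    missing_steepness: float = 1.0
    ptau_threshold: float = 15.0
    label_noise: float = 0.0
    capture: str = "single_cell"
    pool_size: int = 20
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cells", "n_donors", "n_proteins"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_donors > self.n_cells:
            raise ConfigError("n_donors must not exceed n_cells")
        fracs = {
            "frac_linear_up": self.frac_linear_up,
            "frac_linear_down": self.frac_linear_down,
            "frac_early_break": self.frac_early_break,
            "frac_late_break": self.frac_late_break,
        }
        for name, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if sum(fracs.values()) > 1.0 + 1e-12:
            raise ConfigError("frac_* proportions must sum to <= 1")
        lo, hi = self.tau_range
        if not lo < self.breakpoint_early < self.breakpoint_late < hi:
            raise ConfigError(
                "tau_range / breakpoints must satisfy "
                "lo < breakpoint_early < breakpoint_late < hi"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.donor_sd < 0:
            raise ConfigError("donor_sd must be >= 0")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ConfigError("label_noise must be in [0, 1]")
        if self.capture not in ("single_cell", "mini_pool"):
            raise ConfigError("capture must be single_cell or mini_pool")
        if self.pool_size < 1:
            raise ConfigError("pool_size must be >= 1")

    def with_(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Truth tables for a synthetic cohort (test/benchmark use only).

    ``cells``: per-sample latent tau, donor and pTau label.
    ``proteins``: per-protein response class, slopes (alpha1 before / alpha2
    after the hinge), true breakpoint position, baseline.
    ``donor_intercepts``: proteins × donors random-intercept matrix.
    ``beta_true``: injected phospho occupancy excess (log2), set by
    :func:`generate_phospho_layer`.
    """

    cells: pd.DataFrame
    proteins: pd.DataFrame
    donor_intercepts: pd.DataFrame
    beta_true: float | None = None

    def class_counts(self) -> pd.Series:
        return self.proteins["response_class"].value_counts()


def _class_counts(config: CohortConfig) -> dict[str, int]:
    """Largest-remainder apportionment of response classes over proteins."""
    n = config.n_proteins
    fracs = {
        "linear_up": config.frac_linear_up,
        "linear_down": config.frac_linear_down,
        "early_break": config.frac_early_break,
        "late_break": config.frac_late_break,
    }
    raw = {k: f * n for k, f in fracs.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = int(round(sum(raw.values()))) - sum(counts.values())
    order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    # one slot is reserved for the tau row itself
    if sum(counts.values()) > n - 1:
        raise ConfigError(
            "frac_* proportions leave no room for the tau row; reduce them"
        )
    return counts


def _response_values(tau: np.ndarray, cls: str, a1: float, a2: float, bp: float,
                     lo: float) -> np.ndarray:
    """Continuous piecewise-linear response, anchored at the low end of tau."""
    if cls == "null":
        return np.zeros_like(tau)
    if cls in ("linear_up", "linear_down"):
        return a1 * (tau - lo)
    # hinge, continuous at bp
    before = a1 * (tau - lo)
    after = a1 * (bp - lo) + a2 * (tau - bp)
    return np.where(tau <= bp, before, after)


def generate_cohort(config: CohortConfig) -> tuple[ProteomeMatrix, GroundTruth]:
    """Generate a complete (no-missingness) cohort plus its ground truth.

    Each protein's expected value is baseline + piecewise-linear function of
    latent tau + a donor random intercept; observed value adds Gaussian noise.
    Row ``MAPT`` is the tau protein itself: latent tau plus noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.tau_range

    donors = [f"D{i + 1}" for i in range(config.n_donors)]
    # balanced donor assignment, then shuffled
    donor_idx = rng.permutation(
        np.arange(config.n_cells) % config.n_donors
    )

    if config.capture == "mini_pool":
        centers = rng.uniform(lo, hi, config.n_cells)
        member_tau = centers[:, None] + rng.normal(
            0.0, 0.25, (config.n_cells, config.pool_size)
        )
        latent_tau = member_tau.mean(axis=1)
    else:
        member_tau = None
        latent_tau = rng.uniform(lo, hi, config.n_cells)

    ptau = latent_tau > config.ptau_threshold
    if config.label_noise > 0:
        flip = rng.random(config.n_cells) < config.label_noise
        ptau = ptau ^ flip

    counts = _class_counts(config)
    protein_ids = [TAU_ID] + [f"PROT{i:05d}" for i in range(1, config.n_proteins)]
    classes = np.array(["null"] * config.n_proteins, dtype=object)
    classes[0] = "tau"
    slots = rng.permutation(np.arange(1, config.n_proteins))
    pos = 0
    for cls in ("linear_up", "linear_down", "early_break", "late_break"):
        k = counts[cls]
        classes[slots[pos:pos + k]] = cls
        pos += k

    mag = config.slope_scale * rng.uniform(0.75, 1.25, config.n_proteins)
    sign = rng.choice([-1.0, 1.0], config.n_proteins)
    a1 = np.zeros(config.n_proteins)
    a2 = np.zeros(config.n_proteins)
    bp = np.full(config.n_proteins, np.nan)
    for p, cls in enumerate(classes):
        if cls == "tau":
            a1[p] = a2[p] = 1.0
        elif cls == "linear_up":
            a1[p] = a2[p] = mag[p]
        elif cls == "linear_down":
            a1[p] = a2[p] = -mag[p]
        elif cls == "early_break":
            a1[p] = sign[p] * mag[p]
            a2[p] = 0.0
            bp[p] = config.breakpoint_early
        elif cls == "late_break":
            a1[p] = 0.0
            a2[p] = sign[p] * mag[p]
            bp[p] = config.breakpoint_late

    baseline = rng.normal(16.0, 1.5, config.n_proteins)
    baseline[0] = 0.0  # tau row reports latent tau directly

    donor_int = rng.normal(0.0, config.donor_sd, (config.n_proteins, config.n_donors))
    donor_int[0, :] = 0.0  # the axis protein carries no donor offset

    expected = np.empty((config.n_proteins, config.n_cells))
    for p in range(config.n_proteins):
        cls = classes[p]
        if cls == "tau":
            if member_tau is not None:
                resp = member_tau.mean(axis=1)
            else:
                resp = latent_tau
        elif member_tau is not None:
            resp = _response_values(
                member_tau.ravel(), cls, a1[p], a2[p], bp[p], lo
            ).reshape(member_tau.shape).mean(axis=1)
        else:
            resp = _response_values(latent_tau, cls, a1[p], a2[p], bp[p], lo)
        expected[p] = baseline[p] + resp + donor_int[p, donor_idx]

    noise = rng.normal(0.0, config.noise_sd, expected.shape) if config.noise_sd > 0 \
        else np.zeros_like(expected)
    values = expected + noise

    sample_ids = [f"C{i:04d}" for i in range(config.n_cells)]
    samples = make_sample_table(
        sample_ids,
        [donors[d] for d in donor_idx],
        np.where(ptau, "positive", "negative"),
        config.capture,
    )
    vals = pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                        columns=sample_ids)
    matrix = ProteomeMatrix(vals, pd.DataFrame(True, index=vals.index,
                                               columns=vals.columns), samples)

    cells = pd.DataFrame(
        {
            "donor_id": [donors[d] for d in donor_idx],
            "latent_tau": latent_tau,
            "ptau_status": np.where(ptau, "positive", "negative"),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    proteins = pd.DataFrame(
        {
            "response_class": classes,
            "alpha1": a1,
            "alpha2": a2,
            "breakpoint": bp,
            "baseline": baseline,
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )
    truth = GroundTruth(
        cells=cells,
        proteins=proteins,
        donor_intercepts=pd.DataFrame(
            donor_int, index=proteins.index, columns=donors
        ),
    )
    return matrix, truth


def inject_missingness(matrix: ProteomeMatrix, config: CohortConfig) -> ProteomeMatrix:
    """Apply intensity-dependent (MNAR) missingness to a complete matrix.

    Each entry is independently retained with probability
    logistic((value − missing_midpoint) × missing_steepness); dropped entries
    become NaN and are recorded in the detection mask.
    """
    config.validate()
    if not matrix.is_complete:
        raise ValueError("inject_missingness expects a complete matrix")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    v = matrix.values.to_numpy()
    p_keep = expit((v - config.missing_midpoint) * config.missing_steepness)
    keep = rng.random(v.shape) < p_keep
    out = matrix.copy()
    vals = out.values.to_numpy()
    vals[~keep] = np.nan
    out.values.loc[:, :] = vals
    out.detected.loc[:, :] = keep
    out.log.append(f"inject_missingness: dropped {int((~keep).sum())} entries")
    return out


def generate_phospho_layer(
    matrix: ProteomeMatrix,
    truth: GroundTruth,
    beta_true: float,
    occupancy_noise_sd: float = 0.3,
    seed: int = 0,
    a0: float = 2.0,
    a1: float = 0.8,
    donor_sd: float = 0.5,
    tau_id: str = TAU_ID,
) -> pd.DataFrame:
    """Simulate a phosphopeptide (e.g. pT231) intensity per cell.

    phospho = a0 + a1·tau + donor intercept + beta_true·1[pTau-positive] + noise,
    with tau taken from the matrix's tau row (the measured axis, as used by
    the downstream mixed-model fit). ``beta_true`` is recorded on the truth
    object. Returns a long table (one row per sample).
    """
    if tau_id not in matrix.protein_ids:
        raise ValueError(f"matrix has no tau row {tau_id!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    tau = matrix.values.loc[tau_id]
    if tau.isna().any():
        raise ValueError("tau row contains missing values; impute first")
    donors = truth.cells["donor_id"]
    uniq = list(dict.fromkeys(donors))
    d_int = {d: rng.normal(0.0, donor_sd) for d in uniq}
    pos = (truth.cells["ptau_status"] == "positive").astype(float)
    noise = rng.normal(0.0, occupancy_noise_sd, len(tau)) if occupancy_noise_sd > 0 \
        else np.zeros(len(tau))
    phospho = (
        a0
        + a1 * tau.to_numpy()
        + np.array([d_int[d] for d in donors])
        + beta_true * pos.to_numpy()
        + noise
    )
    truth.beta_true = float(beta_true)
    return pd.DataFrame(
        {
            "sample_id": tau.index,
            "donor_id": donors.to_numpy(),
            "ptau_status": truth.cells["ptau_status"].to_numpy(),
            "tau": tau.to_numpy(),
            "phospho": phospho,
        }
    ).set_index("sample_id")


def relabel_proteins(matrix: ProteomeMatrix, truth: GroundTruth,
                     mapping: dict[str, str]) -> tuple[ProteomeMatrix, GroundTruth]:
    """Rename protein rows (e.g. to pathway member gene symbols) in both
    the matrix and the truth tables."""
    out = matrix.copy()
    out.values.rename(index=mapping, inplace=True)
    out.detected.rename(index=mapping, inplace=True)
    if out.imputed is not None:
        out.imputed.rename(index=mapping, inplace=True)
    proteins = truth.proteins.rename(index=mapping)
    di = truth.donor_intercepts.rename(index=mapping)
    return out, GroundTruth(truth.cells, proteins, di, truth.beta_true)
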