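"""Core in-memory containers for log2 protein-by-sample intensity data.

The central object is :class:`ProteomeMatrix`: a proteins × samples table of
log2 intensities with an explicit detection mask (which entries were actually
measured, as opposed to missing or later imputed) and an attached sample
metadata table (donor, pTau status from AT8 immunoreactivity, capture type).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_PTAU = ("positive", "negative")
VALID_CAPTURE = ("single_cell", "mini_pool")


class MatrixError(ValueError):
    """Raised when a ProteomeMatrix or its metadata is malformed."""


def make_sample_table(
    sample_ids,
    donor_ids,
    ptau_status,
    capture="single_cell",
) -> pd.DataFrame:
    """Assemble a validated sample-metadata table indexed by sample id."""
    sample_ids = list(sample_ids)
    if isinstance(capture, str):
        capture = [capture] * len(sample_ids)
    tab = pd.DataFrame(
        {
            "donor_id": list(donor_ids),
            "ptau_status": list(ptau_status),
            "capture": list(capture),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    _check_sample_table(tab)
    return tab


def _check_sample_table(tab: pd.DataFrame) -> None:
    if tab.index.duplicated().any():
        dup = tab.index[tab.index.duplicated()][0]
        raise MatrixError(f"duplicate sample id: {dup!r}")
    for col in ("donor_id", "ptau_status", "capture"):
        if col not in tab.columns:
            raise MatrixError(f"sample table missing column {col!r}")
    bad = set(tab["ptau_status"]) - set(VALID_PTAU)
    if bad:
        raise MatrixError(f"invalid ptau_status value(s): {sorted(bad)}")
    bad = set(tab["capture"]) - set(VALID_CAPTURE)
    if bad:
        raise MatrixError(f"invalid capture value(s): {sorted(bad)}")


@dataclass
class ProteomeMatrix:
    """Log2 intensity matrix (proteins × samples) with missingness mask.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, rows = proteins, columns = samples.
        ``NaN`` marks missing entries that have not been imputed.
    detected
        Boolean DataFrame aligned with ``values``; ``True`` where a value was
        actually measured. Imputation fills values but never flips this mask.
    samples
        Metadata table indexed by sample id with columns ``donor_id``,
        ``ptau_status`` (positive/negative, AT8-based) and ``capture``
        (single_cell / mini_pool).
    imputed
        Boolean DataFrame marking entries filled by imputation (None until
        imputation has run).
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    samples: pd.DataFrame
    imputed: pd.DataFrame | None = None
    log: list = field(default_factory=list)

    def __post_init__(self):
        v = self.values
        v.index.name = "protein_id"
        self.detected.index.name = "protein_id"
        if self.imputed is not None:
            self.imputed.index.name = "protein_id"
        self.samples.index.name = "sample_id"
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise MatrixError(f"duplicate protein id: {dup!r}")
        if not v.columns.equals(self.detected.columns) or not v.index.equals(
            self.detected.index
        ):
            raise MatrixError("values and detected mask are not aligned")
        if not v.columns.equals(self.samples.index):
            raise MatrixError("sample metadata does not match matrix columns")
        _check_sample_table(self.samples)
        if self.imputed is not None and (
            not v.columns.equals(self.imputed.columns)
            or not v.index.equals(self.imputed.index)
        ):
            raise MatrixError("imputed mask is not aligned with values")

    # -- convenience ------------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def copy(self) -> "ProteomeMatrix":
        return ProteomeMatrix(
            self.values.copy(),
            self.detected.copy(),
            self.samples.copy(),
            None if self.imputed is None else self.imputed.copy(),
            list(self.log),
        )

    def subset_proteins(self, ids) -> "ProteomeMatrix":
        ids = pd.Index(ids)
        return ProteomeMatrix(
            self.values.loc[ids],
            self.detected.loc[ids],
            self.samples,
            None if self.imputed is None else self.imputed.loc[ids],
            list(self.log),
        )

    def subset_samples(self, ids) -> "ProteomeMatrix":
        ids = pd.Index(ids)
        return ProteomeMatrix(
            self.values[ids],
            self.detected[ids],
            self.samples.loc[ids],
            None if self.imputed is None else self.imputed[ids],
            list(self.log),
        )

    def require_complete(self, context: str) -> None:
        if not self.is_complete:
            raise MatrixError(f"{context} requires an imputed (complete) matrix")


def from_values(values: pd.DataFrame, samples: pd.DataFrame) -> ProteomeMatrix:
    """Build a ProteomeMatrix from a value table; NaN entries become missing."""
    detected = ~values.isna()
    return ProteomeMatrix(values.copy(), detected, samples)
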