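"""Composite proteostasis pathway scores and binned trends along the tau axis.

A pathway score is the mean of per-protein z-scores (computed per protein
across all cells) over the pathway's detected members. Built-in definitions
cover the proteasome (20S core + PSME1/PSMF1), the 20S core alone, the 19S
regulatory particle (detected PSMC/PSMD subunits, resolved at runtime), and
the lysosomal acidification machinery (V-ATPase subunits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ProteomeMatrix

_PSMA = [f"PSMA{i}" for i in range(1, 8)]
_PSMB = [f"PSMB{i}" for i in range(1, 9)]
_20S = _PSMA + _PSMB
_ACIDIFICATION = [
    "ATP6V1G1", "ATP6V1G2", "ATP6V1B2", "ATP6V1C1", "ATP6V1E1", "ATP6V1A",
    "ATP6V0D1", "ATP6V1F", "ATP6V0A1", "ATP6V1H", "ATP6V1D",
]


@dataclass(frozen=True)
class PathwayDefinition:
    """A named pathway: explicit members and/or id prefixes resolved at runtime."""

    name: str
    members: tuple = ()
    prefixes: tuple = ()

    def __post_init__(self):
        if not self.members and not self.prefixes:
            raise ValueError(f"pathway {self.name!r} has no members or prefixes")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"pathway {self.name!r} has duplicate members")

    def resolve(self, protein_ids) -> list:
        """Members of this pathway present among ``protein_ids``."""
        ids = pd.Index(protein_ids)
        present = [m for m in self.members if m in ids]
        for pre in self.prefixes:
            present += [p for p in ids if str(p).startswith(pre)
                        and p not in present]
        return present


def builtin_definitions() -> list[PathwayDefinition]:
    """The four named proteostasis scores."""
    return [
        PathwayDefinition("proteasome", tuple(_20S + ["PSME1", "PSMF1"])),
        PathwayDefinition("proteasome_20S", tuple(_20S)),
        PathwayDefinition("proteasome_19S", prefixes=("PSMC", "PSMD")),
        PathwayDefinition("acidification", tuple(_ACIDIFICATION)),
    ]


def pathway_score(matrix: ProteomeMatrix, definition: PathwayDefinition) -> pd.Series:
    """Per-sample score: mean over detected members of per-protein z-scores."""
    matrix.require_complete("pathway_score")
    present = definition.resolve(matrix.protein_ids)
    if not present:
        raise ValueError(f"no member of pathway {definition.name!r} detected")
    requested = list(definition.members) if definition.members else None
    if requested:
        absent = [m for m in requested if m not in present]
        if absent:
            warnings.warn(
                f"pathway {definition.name!r}: {len(absent)} member(s) absent "
                f"and dropped: {absent}"
            )
    z = stats.zscore(matrix.values.loc[present].to_numpy(dtype=float),
                     axis=1, ddof=0)
    return pd.Series(z.mean(axis=0), index=matrix.sample_ids,
                     name=definition.name)


def binned_trend(score: pd.Series, bins: pd.Series) -> pd.DataFrame:
    """Mean ± SEM of a score per tau bin.

    SEM uses the sample standard deviation (n−1 denominator); bins with a
    single sample report SEM as NaN, empty bins are omitted (with a warning
    if the bin range is not contiguous).
    """
    if not score.index.equals(bins.index):
        bins = bins.reindex(score.index)
        if bins.isna().any():
            raise ValueError("bins and score must cover the same samples")
    rows = []
    for b, grp in score.groupby(bins):
        n = len(grp)
        sem = float(grp.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({"bin": int(b), "mean": float(grp.mean()), "sem": sem, "n": n})
    out = pd.DataFrame(rows).sort_values("bin").reset_index(drop=True)
    expected = set(range(int(bins.min()), int(bins.max()) + 1))
    if set(out["bin"]) != expected:
        warnings.warn("some tau bins are empty and omitted from the trend")
    return out


def score_table(matrix: ProteomeMatrix,
                definitions: list[PathwayDefinition] | None = None) -> pd.DataFrame:
    """All pathway scores as one samples × score table."""
    definitions = definitions or builtin_definitions()
    cols = {}
    for d in definitions:
        try:
            cols[d.name] = pathway_score(matrix, d)
        except ValueError as e:
            warnings.warn(str(e))
    return pd.DataFrame(cols)
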