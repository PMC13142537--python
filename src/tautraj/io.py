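"""Readers and writers for the plain-text interchange formats.

The canonical matrix dialect is TSV with protein ids in the first column and
sample ids in the header; empty cells and the sentinel ``NA`` both mean
missing. Sample metadata travels in a second TSV keyed by sample_id. Gene
sets use GMT (set name, description, members, tab-separated). PTM reports
are long-format TSV or parquet with the DIA-NN-style column names (matched
case-insensitively, dots and underscores interchangeable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import MatrixError, ProteomeMatrix, from_values

NA_TOKENS = ["", "NA", "NaN", "nan"]


def read_sample_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    return tab


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_matrix(path, metadata=None) -> ProteomeMatrix:
    """Read a TSV/CSV intensity matrix; orientation resolved via metadata.

    If ``metadata`` (a path or DataFrame) is given, the orientation is
    auto-detected by matching sample ids: the dimension whose labels are a
    subset of the metadata sample ids is taken as samples. If both or
    neither dimension matches, the file is ambiguous and an error is raised.
    Without metadata, proteins-in-rows is assumed and a minimal metadata
    table is synthesized.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0, na_values=NA_TOKENS,
                      keep_default_na=False)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise MatrixError(f"duplicate id in first column: {dup!r}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise MatrixError(f"duplicate id in header: {dup!r}")
    for col in raw.columns:
        if not pd.api.types.is_numeric_dtype(raw[col]):
            bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna()
                           & raw[col].notna()]
            loc = bad.index[0] if len(bad) else "?"
            raise MatrixError(
                f"non-numeric cell in column {col!r} at row {loc!r}"
            )
    if metadata is not None:
        meta = metadata if isinstance(metadata, pd.DataFrame) \
            else read_sample_table(metadata)
        cols_match = set(raw.columns) <= set(meta.index)
        rows_match = set(raw.index) <= set(meta.index)
        if cols_match and not rows_match:
            pass
        elif rows_match and not cols_match:
            raw = raw.T
        elif cols_match and rows_match:
            raise MatrixError("matrix orientation is ambiguous: both axes "
                              "match the metadata sample ids")
        else:
            raise MatrixError("neither matrix axis matches the metadata "
                              "sample ids")
        meta = meta.loc[raw.columns]
    else:
        meta = pd.DataFrame(
            {
                "donor_id": "unknown",
                "ptau_status": "negative",
                "capture": "single_cell",
            },
            index=raw.columns.rename("sample_id"),
        )
    raw.index.name = "protein_id"
    return from_values(raw.astype(float), meta)


def write_matrix(matrix: ProteomeMatrix, path, metadata_path=None) -> None:
    """Write values as TSV (missing -> NA); optionally write metadata too."""
    matrix.values.to_csv(path, sep="\t", index=True, index_label="protein_id",
                         na_rep="NA")
    if metadata_path is not None:
        write_sample_table(matrix.samples, metadata_path)


def read_gmt(path) -> dict:
    """Read a GMT gene-set collection: name -> member list."""
    sets = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise ValueError(
                        f"{path}:{line_no}: GMT line needs name, description "
                        "and at least one member"
                    )
                continue
            name, _desc, *members = parts
            sets[name] = [m for m in members if m]
    return sets


def write_gmt(sets: dict, path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_panel(path) -> list:
    """Read a plain-text protein panel: one id per line, '#' comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def read_trajectory_table(path) -> pd.Series:
    tab = pd.read_csv(path, sep="\t")
    return pd.Series(tab.iloc[:, 1].to_numpy(dtype=float),
                     index=tab.iloc[:, 0], name=tab.columns[1])


def write_trajectory_table(values: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": values.index,
                  values.name or "trajectory_value": values.to_numpy()}) \
        .to_csv(path, sep="\t", index=False)


def read_ptm_report(path) -> pd.DataFrame:
    """Read a long-format PTM report (TSV, or parquet via pyarrow)."""
    p = str(path)
    if p.endswith(".parquet"):
        return pd.read_parquet(path)
    return pd.read_csv(path, sep="\t")
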