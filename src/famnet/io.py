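"""Readers and writers for the pipeline's plain-text TSV dialects.

Matrices are TSV with the row identifier in the first column and one header
row of sample IDs; tables are plain header + rows. All readers validate
schema and value domains and name the offending file (and line where it is
cheap to track) in their errors.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableParseError

__all__ = [
    "read_matrix",
    "read_table",
    "read_mutations",
    "read_survival",
    "read_targets",
    "read_probe_map",
    "read_gene_list",
    "write_table",
]

FLOAT_FORMAT = "%.10g"


def read_matrix(path, index_label: str | None = None,
                value_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Identifier x sample numeric matrix with duplicate/value validation."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed header / ragged rows
        raise TableParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise TableParseError(f"{path}: duplicate row identifier {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise TableParseError(f"{path}: duplicate sample column {dup!r}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise TableParseError(f"{path}: non-numeric matrix cell ({exc})") from exc
    if value_range is not None and df.size:
        lo, hi = value_range
        vals = df.to_numpy()
        if np.nanmin(vals) < lo or np.nanmax(vals) > hi:
            raise TableParseError(f"{path}: values outside [{lo}, {hi}]")
    if index_label:
        df.index.name = index_label
    return df


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing column(s) {missing}")


def read_table(path, columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise TableParseError(f"{path}: {exc}") from exc
    _require_columns(df, columns, path)
    return df


def read_mutations(path) -> pd.DataFrame:
    df = read_table(path, ["sample", "gene", "variant_class"])
    for col in ("sample", "gene"):
        blank = df[col].isna() | (df[col].astype(str).str.strip() == "")
        if blank.any():
            line = int(df.index[blank][0]) + 2  # header is line 1
            raise TableParseError(f"{path}: empty {col} at line {line}")
    return df


def read_survival(path) -> pd.DataFrame:
    df = read_table(path, ["sample", "time", "event"])
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    bad = time.isna() | (time <= 0)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise TableParseError(f"{path}: non-positive or missing time at line {line}")
    bad = ~event.isin([0, 1])
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise TableParseError(f"{path}: event flag not in {{0,1}} at line {line}")
    df["time"] = time.astype(float)
    df["event"] = event.astype(int)
    return df


def read_targets(path) -> pd.DataFrame:
    df = read_table(path, ["tf", "target", "score"])
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        line = int(df.index[scores.isna()][0]) + 2
        raise TableParseError(f"{path}: non-numeric score at line {line}")
    df["score"] = scores.astype(float)
    return df


def read_probe_map(path) -> pd.DataFrame:
    df = read_table(path, ["probe", "gene", "region"])
    return df.dropna(subset=["gene"]).reset_index(drop=True)


def read_gene_list(path) -> list[str]:
    genes = [line.strip() for line in Path(path).read_text().splitlines()
             if line.strip()]
    if not genes:
        raise TableParseError(f"{path}: empty gene list")
    if len(genes) != len(set(genes)):
        raise TableParseError(f"{path}: duplicate gene in list")
    return genes


def write_table(df: pd.DataFrame, path, index: bool = False,
                index_label: str | None = None) -> str:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index,
              index_label=index_label)
    return str(path)
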