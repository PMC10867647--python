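"""Readers and writers for study tables.

Input may be TSV or CSV (dialect inferred from the extension); output is
always TSV with a deterministic column order, floats at 6 significant
digits, and missing cells as empty fields.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_DAYS,
    FEATURE_META_COLS,
    GROUPS,
    FeatureTable,
    MetaboliteMatrix,
    SampleSheet,
    SchemaError,
    TimeProfile,
)

FLOAT_FORMAT = "%.6g"

_SHEET_COLS = ["subject_id", "group", "day", "ion_mode", "is_qc"]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_samples(
    path: str | Path,
    days: tuple[int, ...] = DEFAULT_DAYS,
    groups: tuple[str, ...] = GROUPS,
) -> SampleSheet:
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        dtype={"sample_id": str, "subject_id": str, "group": str, "ion_mode": str},
    )
    missing = {"sample_id", *_SHEET_COLS} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: sample sheet missing columns {sorted(missing)}")
    df = df.set_index("sample_id")[_SHEET_COLS]
    df["day"] = df["day"].astype("Int64")
    df["is_qc"] = df["is_qc"].astype(int).astype(bool)
    return SampleSheet(df, days=days, groups=groups)


def read_features(path: str | Path, sheet: SampleSheet | None = None) -> FeatureTable:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"feature_id": str, "metabolite_name": str})
    required = {"feature_id", *FEATURE_META_COLS}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: feature table missing columns {sorted(missing)}")
    df = df.set_index("feature_id")
    sample_cols = [c for c in df.columns if c not in FEATURE_META_COLS]
    df[sample_cols] = df[sample_cols].astype(float)
    table = FeatureTable(df)
    if sheet is not None:
        table.validate(sheet)
    return table


def read_study(
    feature_path: str | Path,
    meta_path: str | Path,
    days: tuple[int, ...] = DEFAULT_DAYS,
    groups: tuple[str, ...] = GROUPS,
) -> tuple[FeatureTable, SampleSheet]:
    """Read and cross-validate a feature table and its sample sheet."""
    sheet = read_samples(meta_path, days=days, groups=groups)
    table = read_features(feature_path, sheet=sheet)
    return table, sheet


def read_metabolite_matrix(path: str | Path, sheet: SampleSheet) -> MetaboliteMatrix:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"metabolite_name": str})
    if "metabolite_name" not in df.columns:
        raise SchemaError(f"{path}: missing metabolite_name column")
    df = df.set_index("metabolite_name").astype(float)
    return MetaboliteMatrix(df, sheet.subset(df.columns))


# ---------------------------------------------------------------------------
# writers


def _write_df(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="", index=index)


def write_table(obj: Any, path: str | Path) -> None:
    """Serialize any pipeline table to TSV with deterministic layout."""
    if isinstance(obj, SampleSheet):
        out = obj.df.copy()
        out["is_qc"] = out["is_qc"].astype(int)
        _write_df(out, path)
    elif isinstance(obj, FeatureTable):
        _write_df(obj.df, path)
    elif isinstance(obj, MetaboliteMatrix):
        _write_df(obj.values, path)
    elif isinstance(obj, TimeProfile):
        _write_df(obj.values, path)
    elif isinstance(obj, pd.DataFrame):
        _write_df(obj, path, index=obj.index.name is not None)
    elif isinstance(obj, pd.Series):
        _write_df(obj.to_frame(), path)
    else:
        raise TypeError(f"do not know how to serialize {type(obj).__name__}")


def write_study(table: FeatureTable, sheet: SampleSheet, out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    fpath, spath = out / "features.tsv", out / "samples.tsv"
    write_table(table, fpath)
    write_table(sheet, spath)
    return fpath, spath
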