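"""Core containers for longitudinal LC-MS metabolomics studies.

A study is a wide feature table (LC-MS features x samples) plus a sample
sheet describing each injection: which subject and treatment group it came
from, the sampling day, the ionization mode, and whether it is a pooled QC
injection. Containers are thin, validated wrappers around pandas objects so
every pipeline stage can rely on the same invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("C", "A", "AE")
ION_MODES = ("POS", "NEG")
DEFAULT_DAYS = (0, 14, 28, 63, 91)

#: columns of a feature table that are not sample intensities
FEATURE_META_COLS = ("metabolite_name", "ms2_score")


class SchemaError(ValueError):
    """A table does not conform to the study schema."""


class ValidationError(ValueError):
    """A table parses but violates a study invariant."""


@dataclass
class SampleSheet:
    """Sample metadata indexed by sample_id.

    Columns: ``subject_id`` (str, may be missing for QC), ``group``
    (str, one of the study groups, missing for QC), ``day`` (nullable
    integer), ``ion_mode`` ("POS"/"NEG"), ``is_qc`` (bool).
    """

    df: pd.DataFrame
    days: tuple[int, ...] = DEFAULT_DAYS
    groups: tuple[str, ...] = GROUPS

    def __post_init__(self) -> None:
        self.days = tuple(int(d) for d in self.days)
        self.groups = tuple(self.groups)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        df = self.df
        required = {"subject_id", "group", "day", "ion_mode", "is_qc"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"sample sheet missing columns: {sorted(missing)}")
        if df.index.name != "sample_id":
            raise SchemaError("sample sheet must be indexed by sample_id")
        if not df.index.is_unique:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id: {dups}")
        if df["is_qc"].isna().any():
            raise ValidationError("is_qc must be 0/1 for every sample")
        bad_mode = set(df["ion_mode"].dropna()) - set(ION_MODES)
        if bad_mode:
            raise ValidationError(f"unknown ion_mode values: {sorted(bad_mode)}")

        bio = df[~df["is_qc"].astype(bool)]
        for col in ("subject_id", "group", "day"):
            if bio[col].isna().any():
                bad = bio.index[bio[col].isna()].tolist()
                raise ValidationError(
                    f"non-QC samples missing {col}: {bad[:5]}"
                )
        bad_group = set(bio["group"]) - set(self.groups)
        if bad_group:
            raise ValidationError(f"unknown group values: {sorted(bad_group)}")
        bad_day = set(bio["day"].astype(int)) - set(self.days)
        if bad_day:
            raise ValidationError(f"days outside the study grid: {sorted(bad_day)}")
        key = bio[["subject_id", "day", "ion_mode"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValidationError(
                f"(subject_id, day, ion_mode) not unique: {dup}"
            )

    # -- accessors -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def biological(
        self,
        group: str | None = None,
        day: int | None = None,
        ion_mode: str | None = None,
    ) -> pd.DataFrame:
        """Non-QC sample rows, optionally filtered."""
        out = self.df[~self.df["is_qc"].astype(bool)]
        if group is not None:
            if group not in self.groups:
                raise ValueError(f"unknown group {group!r}; study has {self.groups}")
            out = out[out["group"] == group]
        if day is not None:
            out = out[out["day"].astype("Int64") == day]
        if ion_mode is not None:
            out = out[out["ion_mode"] == ion_mode]
        return out

    def qc_ids(self, ion_mode: str | None = None) -> list[str]:
        qc = self.df[self.df["is_qc"].astype(bool)]
        if ion_mode is not None:
            qc = qc[qc["ion_mode"] == ion_mode]
        return list(qc.index)

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        ids = list(sample_ids)
        return SampleSheet(self.df.loc[ids].copy(), days=self.days, groups=self.groups)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, SampleSheet):
            return NotImplemented
        return self.df.equals(other.df) and self.days == other.days


@dataclass
class FeatureTable:
    """Raw LC-MS features: identification metadata plus intensity columns.

    ``df`` is indexed by feature_id with columns ``metabolite_name``,
    ``ms2_score`` and then one float column per sample_id. Intensities are
    strictly positive where present; missing cells are NaN.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, sheet: SampleSheet | None = None) -> None:
        df = self.df
        if df.index.name != "feature_id":
            raise SchemaError("feature table must be indexed by feature_id")
        for col in FEATURE_META_COLS:
            if col not in df.columns:
                raise SchemaError(f"feature table missing column {col!r}")
        if not df.index.is_unique:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature_id: {dups}")
        if df.columns.duplicated().any():
            raise ValidationError("duplicate column names in feature table")
        inten = df[self.sample_ids]
        if not inten.empty and (inten.to_numpy(dtype=float) <= 0).any():
            bad = inten.columns[(inten <= 0).any(axis=0)].tolist()
            raise ValidationError(
                f"non-positive intensities in sample columns {bad[:5]}"
            )
        if sheet is not None:
            unknown = set(self.sample_ids) - set(sheet.sample_ids)
            if unknown:
                raise SchemaError(
                    f"intensity columns with no sample-sheet record: {sorted(unknown)[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [c for c in self.df.columns if c not in FEATURE_META_COLS]

    @property
    def intensities(self) -> pd.DataFrame:
        return self.df[self.sample_ids]

    def restrict_samples(self, sample_ids: Sequence[str], drop_empty: bool = True) -> "FeatureTable":
        """Keep only the given intensity columns; optionally drop all-missing rows."""
        cols = list(FEATURE_META_COLS) + list(sample_ids)
        sub = self.df[cols].copy()
        if drop_empty:
            keep = sub[list(sample_ids)].notna().any(axis=1)
            sub = sub[keep]
        return FeatureTable(sub)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.df.equals(other.df)


@dataclass
class MetaboliteMatrix:
    """Collapsed metabolite x sample intensity matrix with its sample sheet."""

    values: pd.DataFrame  # index metabolite_name, columns sample_id
    samples: SampleSheet

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.name != "metabolite_name":
            raise SchemaError("metabolite matrix must be indexed by metabolite_name")
        if not v.index.is_unique:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate metabolite rows: {dups}")
        if not v.columns.is_unique:
            raise ValidationError("duplicate sample columns")
        unknown = set(v.columns) - set(self.samples.sample_ids)
        if unknown:
            raise SchemaError(f"matrix columns with no sample record: {sorted(unknown)[:5]}")
        if not v.empty and (v.to_numpy(dtype=float) <= 0).any():
            raise ValidationError("metabolite intensities must be strictly positive")

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TimeProfile:
    """Per-group metabolite x timepoint summary matrix (medians over samples)."""

    values: pd.DataFrame  # index metabolite_name, columns int days
    standardized: bool = False
    dropped_zero_variance: list[str] = field(default_factory=list)

    @property
    def timepoints(self) -> list[int]:
        return [int(c) for c in self.values.columns]

    def __len__(self) -> int:
        return len(self.values)
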