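from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chronomet.datatypes import FeatureTable, MetaboliteMatrix, SampleSheet
from chronomet.simulate import make_fixture


def build_sheet(rows: list[tuple], days=(0, 14, 28, 63, 91)) -> SampleSheet:
    """rows: (sample_id, subject_id, group, day, ion_mode, is_qc)."""
    df = pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "group", "day", "ion_mode", "is_qc"]
    ).set_index("sample_id")
    df["day"] = df["day"].astype("Int64")
    return SampleSheet(df, days=days)


def build_features(records: list[dict], sample_ids: list[str]) -> FeatureTable:
    """records: dicts with feature_id, metabolite_name, ms2_score, intensities."""
    df = pd.DataFrame(records).set_index("feature_id")
    df = df.reindex(columns=["metabolite_name", "ms2_score", *sample_ids])
    return FeatureTable(df)


def matrix_from_log2(
    log2: np.ndarray, metabolites: list[str], sheet: SampleSheet
) -> MetaboliteMatrix:
    vals = pd.DataFrame(
        2.0**log2,
        index=pd.Index(metabolites, name="metabolite_name"),
        columns=sheet.sample_ids,
    )
    return MetaboliteMatrix(vals, sheet)


def one_group_sheet(n_subjects: int, days=(0, 14, 28, 63, 91), group="C") -> SampleSheet:
    rows = [
        (f"{group}{s:02d}_d{d:03d}_POS", f"{group}{s:02d}", group, d, "POS", False)
        for s in range(n_subjects)
        for d in days
    ]
    return build_sheet(rows, days=days)


@pytest.fixture(scope="session")
def tiny_study():
    """Small synthetic study shared by read-only tests."""
    table, sheet, truth, annotation, classes = make_fixture("tiny", seed=7)
    return table, sheet, truth, annotation, classes
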