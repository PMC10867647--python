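"""MS2 filtering, metabolite collapse, and QC summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chronomet.preprocess import (
    collapse_to_metabolites,
    filter_ms2,
    qc_report,
    split_ion_mode,
)

from conftest import build_features, build_sheet


@pytest.fixture
def four_sample_sheet():
    return build_sheet(
        [
            ("s1", "r1", "C", 0, "POS", False),
            ("s2", "r1", "C", 63, "POS", False),
            ("s3", "r2", "C", 0, "POS", False),
            ("s4", "r2", "C", 63, "POS", False),
        ]
    )


def feats(rows, sample_ids=("s1", "s2", "s3", "s4")):
    return build_features(rows, list(sample_ids))


class TestFilterMS2:
    def test_threshold_is_strict_and_missing_scores_drop(self, four_sample_sheet):
        table = feats(
            [
                dict(feature_id="f1", metabolite_name="a", ms2_score=0.2, s1=1, s2=1, s3=1, s4=1),
                dict(feature_id="f2", metabolite_name="b", ms2_score=0.5, s1=1, s2=1, s3=1, s4=1),
                dict(feature_id="f3", metabolite_name="c", ms2_score=0.9, s1=1, s2=1, s3=1, s4=1),
                dict(feature_id="f4", metabolite_name="d", ms2_score=None, s1=1, s2=1, s3=1, s4=1),
            ]
        )
        # brute-force expectation over the four rows at the default cutoff
        expected = [
            r["feature_id"]
            for r in table.df.reset_index().to_dict("records")
            if pd.notna(r["ms2_score"]) and r["ms2_score"] > 0.5
        ]
        out = filter_ms2(table, 0.5)
        assert list(out.df.index) == expected == ["f3"]

    def test_score_just_above_threshold_retained(self, four_sample_sheet):
        table = feats(
            [dict(feature_id="f1", metabolite_name="a", ms2_score=0.51, s1=1, s2=1, s3=1, s4=1)]
        )
        assert len(filter_ms2(table, 0.5)) == 1

    def test_bad_threshold_rejected(self, four_sample_sheet):
        table = feats(
            [dict(feature_id="f1", metabolite_name="a", ms2_score=0.9, s1=1, s2=1, s3=1, s4=1)]
        )
        with pytest.raises(ValueError):
            filter_ms2(table, 1.5)


class TestCollapse:
    def test_elementwise_max_of_duplicate_features(self, four_sample_sheet):
        table = feats(
            [
                dict(feature_id="f1", metabolite_name="glycine", ms2_score=0.9,
                     s1=3.0, s2=7.0, s3=3.0, s4=7.0),
                dict(feature_id="f2", metabolite_name="glycine", ms2_score=0.8,
                     s1=5.0, s2=2.0, s3=5.0, s4=2.0),
            ]
        )
        out = collapse_to_metabolites(table, four_sample_sheet)
        np.testing.assert_array_equal(
            out.values.loc["glycine"].to_numpy(), [5.0, 7.0, 5.0, 7.0]
        )

    def test_single_feature_passes_through(self, four_sample_sheet):
        table = feats(
            [dict(feature_id="f1", metabolite_name="serine", ms2_score=0.9,
                  s1=1.0, s2=2.0, s3=3.0, s4=4.0)]
        )
        out = collapse_to_metabolites(table, four_sample_sheet)
        np.testing.assert_array_equal(out.values.loc["serine"], [1.0, 2.0, 3.0, 4.0])

    def test_missing_cells_ignored_and_all_missing_stays_missing(self, four_sample_sheet):
        table = feats(
            [
                dict(feature_id="f1", metabolite_name="x", ms2_score=0.9,
                     s1=3.0, s2=None, s3=1.0, s4=1.0),
                dict(feature_id="f2", metabolite_name="x", ms2_score=0.8,
                     s1=None, s2=None, s3=2.0, s4=2.0),
            ]
        )
        out = collapse_to_metabolites(table, four_sample_sheet)
        row = out.values.loc["x"]
        assert row["s1"] == 3.0 and np.isnan(row["s2"]) and row["s3"] == 2.0

    def test_collapse_is_idempotent_and_value_preserving(self, tiny_study):
        table, sheet, *_ = tiny_study
        sub, ssheet = split_ion_mode(table, sheet, "POS")
        once = collapse_to_metabolites(sub, ssheet)
        # re-collapsing a one-feature-per-metabolite table is the identity
        refeat = once.values.copy()
        refeat.insert(0, "metabolite_name", refeat.index)
        refeat.insert(1, "ms2_score", 0.9)
        refeat.index = pd.Index([f"f_{m}" for m in refeat.index], name="feature_id")
        twice = collapse_to_metabolites(type(table)(refeat), ssheet)
        pd.testing.assert_frame_equal(once.values, twice.values)
        # every collapsed value occurs among the contributing features
        inten = sub.intensities
        for met in once.metabolites:
            rows = inten[sub.df["metabolite_name"] == met]
            for col in once.values.columns:
                v = once.values.loc[met, col]
                if not np.isnan(v):
                    assert v in rows[col].values
        # row count equals distinct surviving names
        assert len(once) == sub.df["metabolite_name"].nunique()

    def test_best_feature_mode_picks_highest_mean_row(self, four_sample_sheet):
        table = feats(
            [
                dict(feature_id="f1", metabolite_name="x", ms2_score=0.9,
                     s1=10.0, s2=10.0, s3=10.0, s4=10.0),
                dict(feature_id="f2", metabolite_name="x", ms2_score=0.8,
                     s1=1.0, s2=99.0, s3=1.0, s4=1.0),
            ]
        )
        # f2 has the higher mean intensity (25.5 vs 10), so its whole row wins
        out = collapse_to_metabolites(table, four_sample_sheet, method="best_feature")
        np.testing.assert_array_equal(out.values.loc["x"], [1.0, 99.0, 1.0, 1.0])


class TestQCReport:
    def test_cv_zero_for_constant_and_hand_value(self):
        sheet = build_sheet(
            [
                ("s1", "r1", "C", 0, "POS", False),
                ("s2", "r2", "C", 0, "POS", False),
                ("s3", "r3", "C", 14, "POS", False),
                ("q1", None, None, None, "POS", True),
                ("q2", None, None, None, "POS", True),
                ("q3", None, None, None, "POS", True),
            ]
        )
        vals = pd.DataFrame(
            {"s1": [1.0, 1.0], "s2": [2.0, 2.0], "s3": [3.0, 3.0],
             "q1": [4.0, 1.0], "q2": [4.0, 3.0], "q3": [4.0, 2.0]},
            index=pd.Index(["const", "var"], name="metabolite_name"),
        )
        from chronomet.datatypes import MetaboliteMatrix

        report = qc_report(MetaboliteMatrix(vals, sheet))
        assert report.cv["const"] == 0.0
        # QC intensities (1, 3, 2): sd = 1, mean = 2
        assert report.cv["var"] == pytest.approx(0.5)
        # two-sample case: (1, 3) -> sd/mean = sqrt(2)/2
        vals2 = vals[["s1", "s2", "s3", "q1", "q2"]].copy()
        vals2.loc["var", ["q1", "q2"]] = [1.0, 3.0]
        report2 = qc_report(MetaboliteMatrix(vals2, sheet.subset(vals2.columns)))
        assert report2.cv["var"] == pytest.approx(np.sqrt(2) / 2)

    def test_single_qc_sample_warns_not_raises(self):
        sheet = build_sheet(
            [
                ("s1", "r1", "C", 0, "POS", False),
                ("s2", "r2", "C", 0, "POS", False),
                ("q1", None, None, None, "POS", True),
            ]
        )
        vals = pd.DataFrame(
            {"s1": [1.0], "s2": [2.0], "q1": [3.0]},
            index=pd.Index(["m"], name="metabolite_name"),
        )
        from chronomet.datatypes import MetaboliteMatrix

        with pytest.warns(UserWarning, match="QC"):
            report = qc_report(MetaboliteMatrix(vals, sheet))
        assert report.cv.empty and report.n_qc == 1

    def test_pca_separates_two_sample_blocks(self):
        """Two blocks of samples with opposite intensity offsets land on
        opposite sides of PC1."""
        sheet = build_sheet(
            [
                ("s1", "r1", "C", 0, "POS", False),
                ("s2", "r2", "C", 0, "POS", False),
                ("s3", "r3", "C", 14, "POS", False),
                ("s4", "r4", "C", 14, "POS", False),
            ]
        )
        rng = np.random.default_rng(5)
        base = rng.uniform(8, 12, size=(6, 1))
        offset = np.array([[1.0, 1.0, -1.0, -1.0]])
        vals = pd.DataFrame(
            2.0 ** (base + offset + rng.normal(0, 0.01, (6, 4))),
            index=pd.Index([f"m{i}" for i in range(6)], name="metabolite_name"),
            columns=sheet.sample_ids,
        )
        from chronomet.datatypes import MetaboliteMatrix

        report = qc_report(MetaboliteMatrix(vals, sheet))
        pc1 = report.pca_scores["PC1"]
        assert np.sign(pc1["s1"]) == np.sign(pc1["s2"]) != np.sign(pc1["s3"])
        assert not np.any(np.diff(report.explained_variance_ratio) > 0)
        assert report.explained_variance_ratio.sum() <= 1 + 1e-9
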