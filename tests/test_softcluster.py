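"""Median profiles, standardization, fuzzy c-means, and cluster-count selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chronomet.datatypes import TimeProfile
from chronomet.patterns import archetype_templates
from chronomet.softcluster import (
    ClusterResult,
    DminCurve,
    core_members,
    dmin_curve,
    estimate_fuzzifier,
    fuzzy_cmeans,
    heatmap_matrix,
    select_optimal_c,
    standardize_profile,
    timepoint_medians,
)

from conftest import build_sheet, matrix_from_log2
from helpers import reference_fcm

DAYS = (0, 14, 28, 63, 91)


def profile_from(values: np.ndarray, days=DAYS, standardized=False) -> TimeProfile:
    df = pd.DataFrame(
        values,
        index=pd.Index([f"m{i}" for i in range(len(values))], name="metabolite_name"),
        columns=list(days),
    )
    return TimeProfile(df, standardized=standardized)


def std_profile(values: np.ndarray, days=DAYS) -> TimeProfile:
    return standardize_profile(profile_from(values, days))


class TestTimepointMedians:
    def test_odd_and_even_sample_medians(self):
        rows = [
            (f"r{s}_d{d:03d}", f"r{s}", "C", d, "POS", False)
            for s in range(3)
            for d in (0, 14)
        ]
        sheet = build_sheet(rows)
        log2 = np.log2(
            np.array([[1.0, 1.0, 2.0, 3.0, 9.0, 9.0]])  # day0: 1,2,9; day14: 1,3,9
        )
        matrix = matrix_from_log2(log2, ["m"], sheet)
        matrix.values.loc["m", "r2_d014"] = np.nan  # day14 becomes even-n: (1, 3)
        prof = timepoint_medians(matrix, "C")
        # day 0 median of (1, 2, 9) is 2; day 14 median of (1, 3) is the
        # middle-pair mean 2; profiles store log2 of the median
        assert prof.values.loc["m", 0] == pytest.approx(np.log2(2.0))
        assert prof.values.loc["m", 14] == pytest.approx(np.log2(2.0))

    def test_empty_cell_is_an_error_naming_both(self):
        rows = [("r0_d000", "r0", "C", 0, "POS", False),
                ("r0_d014", "r0", "C", 14, "POS", False)]
        sheet = build_sheet(rows)
        matrix = matrix_from_log2(np.array([[3.0, 3.0]]), ["glyc"], sheet)
        matrix.values.loc["glyc", "r0_d014"] = np.nan
        with pytest.raises(ValueError, match=r"glyc.*14"):
            timepoint_medians(matrix, "C")


class TestStandardize:
    def test_rows_become_zero_mean_unit_sd(self):
        prof = std_profile(np.array([[1.0, 2, 3, 4, 5], [5.0, 1, 4, 2, 3]]))
        z = prof.values.to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_constant_row_removed_and_recorded(self):
        prof = std_profile(np.array([[1.0, 2, 3, 4, 5], [2.0, 2, 2, 2, 2]]))
        assert prof.dropped_zero_variance == ["m1"]
        assert list(prof.values.index) == ["m0"]

    def test_standardization_is_idempotent_in_values(self):
        prof = std_profile(np.array([[1.0, 2, 3, 4, 5]]))
        again = standardize_profile(
            TimeProfile(prof.values.copy(), standardized=False)
        )
        np.testing.assert_allclose(
            again.values.to_numpy(), prof.values.to_numpy(), atol=1e-9
        )
        with pytest.raises(ValueError, match="already"):
            standardize_profile(prof)

    def test_all_flat_is_an_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            std_profile(np.ones((3, 5)))


class TestFuzzyCMeans:
    def test_single_cluster_is_column_mean_with_full_membership(self):
        rng = np.random.default_rng(1)
        prof = std_profile(rng.normal(size=(8, 5)))
        res = fuzzy_cmeans(prof, 1, seed=4)
        np.testing.assert_array_equal(res.membership.to_numpy(), np.ones((8, 1)))
        np.testing.assert_allclose(
            res.centroids[0], prof.values.to_numpy().mean(axis=0), atol=1e-12
        )

    def test_equidistant_point_splits_membership(self):
        from chronomet.softcluster import _memberships

        # a point at equal squared distance from two centroids
        u = _memberships(np.array([[4.0, 4.0]]), m=2.0)
        np.testing.assert_array_equal(u, [[0.5, 0.5]])
        # coincident with one centroid: crisp membership there
        u = _memberships(np.array([[0.0, 4.0]]), m=2.0)
        np.testing.assert_array_equal(u, [[1.0, 0.0]])
        # coincident with two centroids: equal split among the zeros only
        u = _memberships(np.array([[0.0, 0.0, 9.0]]), m=2.0)
        np.testing.assert_array_equal(u, [[0.5, 0.5, 0.0]])

    def test_matches_naive_reference_from_shared_init(self):
        rng = np.random.default_rng(9)
        prof = std_profile(rng.normal(size=(20, 5)))
        x = prof.values.to_numpy()
        sweeps = 25
        for c in (2, 3, 4):
            seed = 100 + c
            res = fuzzy_cmeans(prof, c, m=2.0, seed=seed, tol=0.0, max_iter=sweeps)
            init = x[np.random.default_rng(seed).choice(len(x), size=c, replace=False)]
            u_ref, _, obj_ref = reference_fcm(x, init, 2.0, sweeps)
            np.testing.assert_allclose(res.membership.to_numpy(), u_ref, atol=1e-8)
            assert res.objective == pytest.approx(obj_ref, abs=1e-8)

    def test_argument_validation(self):
        prof = std_profile(np.random.default_rng(0).normal(size=(5, 5)))
        with pytest.raises(ValueError):
            fuzzy_cmeans(prof, 0, seed=0)
        with pytest.raises(ValueError):
            fuzzy_cmeans(prof, 6, seed=0)
        with pytest.raises(ValueError):
            fuzzy_cmeans(prof, 2, m=1.0, seed=0)
        with pytest.raises(ValueError, match="standardized"):
            fuzzy_cmeans(profile_from(np.ones((4, 5)) * 2), 2, seed=0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(6, 25),
        c=st.integers(2, 4),
        m=st.floats(1.2, 3.0),
    )
    def test_membership_rows_sum_to_one_and_objective_decreases(self, seed, n, c, m):
        rng = np.random.default_rng(seed)
        prof = std_profile(rng.normal(size=(n, 5)))
        res = fuzzy_cmeans(prof, c, m=m, seed=seed)
        sums = res.membership.to_numpy().sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        trace = np.array(res.objective_trace)
        assert np.all(np.diff(trace) <= 1e-10)


class TestFuzzifier:
    def test_numeric_settings_pass_through(self):
        prof = std_profile(np.random.default_rng(0).normal(size=(10, 5)))
        assert estimate_fuzzifier(prof, 2.0) == 2.0
        assert estimate_fuzzifier(prof, 1.5) == 1.5

    def test_estimate_mode_exceeds_validity_bound(self):
        prof = std_profile(np.random.default_rng(0).normal(size=(50, 5)))
        m = estimate_fuzzifier(prof, "estimate")
        assert m > 1.0

    def test_invalid_settings_rejected(self):
        prof = std_profile(np.random.default_rng(0).normal(size=(10, 5)))
        with pytest.raises(ValueError):
            estimate_fuzzifier(prof, 1.0)
        with pytest.raises(ValueError):
            estimate_fuzzifier(prof, "guess")


class TestDminSelection:
    def test_same_seed_gives_identical_curve(self):
        rng = np.random.default_rng(2)
        prof = std_profile(rng.normal(size=(30, 5)))
        c1 = dmin_curve(prof, c_max=6, seed=5)
        c2 = dmin_curve(prof, c_max=6, seed=5)
        assert c1.dmin == c2.dmin
        assert all(v >= 0 for v in c1.dmin.values())

    def test_stated_elbow_rule_on_spec_curve(self):
        curve = DminCurve({2: 10.0, 3: 9.5, 4: 4.0, 5: 3.8, 6: 3.7}, repeats=1)
        # relative drops: r(2)=.05, r(3)=.58, r(4)=.05, r(5)=.026 -> last >= 0.2 is c=3
        assert select_optimal_c(curve, delta=0.2) == (3, False)

    def test_flat_curve_falls_back_to_c_min(self):
        curve = DminCurve({2: 5.0, 3: 4.9, 4: 4.85, 5: 4.8}, repeats=1)
        with pytest.warns(UserWarning, match="falling back"):
            out = select_optimal_c(curve, delta=0.2)
        assert out == (2, True)

    def test_force_c_overrides(self):
        curve = DminCurve({2: 10.0, 3: 9.5, 4: 4.0, 5: 3.9}, repeats=1)
        assert select_optimal_c(curve, force_c=6).c == 6

    def test_sharp_drop_past_three_planted_archetypes(self):
        """With 3 well-separated shapes at noise sd 0.1, Dmin collapses
        beyond c=3 and the elbow rule recovers c=3."""
        rng = np.random.default_rng(8)
        temps = archetype_templates(DAYS)
        shapes = [temps[0].values, temps[1].values, temps[4].values]
        rows = np.vstack([s + rng.normal(0, 0.1, 5) for s in shapes for _ in range(30)])
        prof = std_profile(rows)
        curve = dmin_curve(prof, c_max=6, seed=8)
        assert curve.dmin[4] < 0.5 * curve.dmin[3]
        assert select_optimal_c(curve, delta=0.2).c == 3


class TestCoreAndHeatmap:
    def make_result(self, memberships: np.ndarray, days=(0, 14, 28)) -> ClusterResult:
        c = memberships.shape[1]
        idx = pd.Index([f"m{i}" for i in range(len(memberships))], name="metabolite_name")
        return ClusterResult(
            c=c, m=2.0, centroids=np.zeros((c, len(days))),
            membership=pd.DataFrame(memberships, index=idx, columns=range(c)),
            objective=0.0, objective_trace=[0.0], n_iter=1, seed=0,
            timepoints=list(days),
        )

    def test_strict_membership_threshold(self):
        res = self.make_result(np.array([[0.71, 0.29], [0.70, 0.30], [0.30, 0.70]]))
        core = core_members(res, 0.7)
        assert list(core.table["metabolite_name"]) == ["m0"]

    def test_single_cluster_everything_is_core(self):
        res = self.make_result(np.ones((4, 1)))
        assert len(core_members(res, 0.7).table) == 4

    def test_heatmap_rows_sorted_by_cluster_then_membership(self):
        res = self.make_result(
            np.array([[0.80, 0.20], [0.90, 0.10], [0.75, 0.25], [0.10, 0.90]])
        )
        core = core_members(res, 0.7)
        prof = std_profile(
            np.arange(20, dtype=float).reshape(4, 5) ** 2
        )
        hm = heatmap_matrix(res, core, prof)
        expected = sorted(
            zip(core.table["cluster"], -core.table["membership"],
                core.table["metabolite_name"])
        )
        assert list(hm.index) == [name for _, _, name in expected]
        assert list(hm.index) == ["m1", "m0", "m2", "m3"]

    def test_empty_core_warns_and_writes_header_only(self):
        res = self.make_result(np.full((3, 2), 0.5))
        core = core_members(res, 0.7)
        prof = std_profile(np.arange(15, dtype=float).reshape(3, 5) ** 2)
        with pytest.warns(UserWarning, match="empty"):
            hm = heatmap_matrix(res, core, prof)
        assert hm.empty
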