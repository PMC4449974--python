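import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dcde.chimax import (
    ChimaxConfig,
    ContingencyTable,
    adjust_pvalues,
    adjusted_residual,
    expected_counts,
    pearson_chi2,
    quadrant_partition,
    select_optimal_thresholds,
)

NO_FLOOR = ChimaxConfig(min_expected=0.0)

# reference partition counts for one focal gene in a large two-class study
REF_TABLE = ContingencyTable(hdc_hde=999, hdc_lde=1090, ldc_hde=8403, ldc_lde=14744)


def closed_form_chi2(t: ContingencyTable) -> float:
    a, b, c, d = t.hdc_hde, t.hdc_lde, t.ldc_hde, t.ldc_lde
    n = t.n
    return n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d))


class TestQuadrantPartition:
    def test_all_points_below_both_thresholds(self):
        table, labels = quadrant_partition([0.1, 0.2, 0.3], [0.1, 0.2, 0.3], 1.0, 1.0)
        assert (table.hdc_hde, table.hdc_lde, table.ldc_hde, table.ldc_lde) == (0, 0, 0, 3)
        assert set(labels) == {3}

    def test_threshold_boundary_is_inclusive(self):
        table, _ = quadrant_partition([1.0, 5.0], [1.0, 5.0], 5.0, 5.0)
        assert (table.hdc_hde, table.ldc_lde) == (1, 1)
        assert table.hdc_lde == 0 and table.ldc_hde == 0

    def test_counts_match_set_membership_oracle(self):
        rng = np.random.default_rng(99)
        z = rng.random(100) * 5
        t = rng.random(100) * 5
        z_thr, t_thr = 2.0, 3.0
        table, labels = quadrant_partition(z, t, z_thr, t_thr)
        sets = {
            "HDC_HDE": {k for k in range(100) if z[k] >= z_thr and t[k] >= t_thr},
            "HDC_LDE": {k for k in range(100) if z[k] >= z_thr and t[k] < t_thr},
            "LDC_HDE": {k for k in range(100) if z[k] < z_thr and t[k] >= t_thr},
            "LDC_LDE": {k for k in range(100) if z[k] < z_thr and t[k] < t_thr},
        }
        assert table.hdc_hde == len(sets["HDC_HDE"])
        assert table.hdc_lde == len(sets["HDC_LDE"])
        assert table.ldc_hde == len(sets["LDC_HDE"])
        assert table.ldc_lde == len(sets["LDC_LDE"])
        assert table.n == 100
        for k in range(100):
            name = ["HDC_HDE", "HDC_LDE", "LDC_HDE", "LDC_LDE"][labels[k]]
            assert k in sets[name]

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            quadrant_partition([], [], 0.0, 0.0)


class TestChi2:
    def test_proportional_table_gives_zero(self):
        t = ContingencyTable(10, 20, 30, 60)
        assert pearson_chi2(t) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table_closed_form(self):
        assert pearson_chi2(ContingencyTable(3, 0, 0, 3)) == pytest.approx(6.0)

    def test_reported_partition_counts_match_closed_form(self):
        assert pearson_chi2(REF_TABLE) == pytest.approx(closed_form_chi2(REF_TABLE), abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2(ContingencyTable(0, 0, 5, 5))

    def test_expected_counts_reported_value(self):
        exp = expected_counts(REF_TABLE)
        assert exp["HDC_HDE"] == pytest.approx(778.3, abs=0.05)

    def test_expected_counts_uniform(self):
        exp = expected_counts(ContingencyTable(5, 5, 5, 5))
        assert all(v == 5.0 for v in exp.values())

    @given(st.tuples(*[st.integers(0, 80)] * 4))
    @settings(deadline=None)
    def test_expected_cells_conserve_total(self, cells):
        t = ContingencyTable(*cells)
        if t.n == 0:
            return
        assert sum(expected_counts(t).values()) == pytest.approx(t.n)


class TestSelectOptimalThresholds:
    def test_two_cluster_brute_force(self):
        """Three points at (1,1) and three at (5,5): brute force over the six
        candidates puts the optimum at (5,5) with chi-square n = 6."""
        z = np.array([1, 1, 1, 5, 5, 5.0])
        t = np.array([1, 1, 1, 5, 5, 5.0])
        res = select_optimal_thresholds(z, t, config=NO_FLOOR)
        assert (res.z_star, res.t_star) == (5.0, 5.0)
        assert res.chi2 == pytest.approx(6.0)
        assert res.direction == "positive"

    def test_all_points_identical_flagged(self):
        res = select_optimal_thresholds([2.0] * 8, [3.0] * 8, config=NO_FLOOR)
        assert not res.valid
        assert np.isnan(res.chi2)

    @pytest.mark.parametrize("seed", range(20))
    def test_fast_equals_naive_on_random_points(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        z = np.abs(rng.standard_normal(n))
        t = np.abs(rng.standard_t(10, n))
        for config in (NO_FLOOR, ChimaxConfig(min_expected=5.0)):
            fast = select_optimal_thresholds(z, t, config=config)
            naive = select_optimal_thresholds(z, t, config=config, method="naive")
            assert fast.chi2 == naive.chi2
            assert fast.z_star == naive.z_star
            assert fast.t_star == naive.t_star

    def test_ties_resolve_to_smallest_thresholds(self):
        # two symmetric clusters: the candidate at each cluster corner gives
        # the same table, so the lexicographically smallest pair must win
        z = np.array([1, 1, 5, 5.0])
        t = np.array([1, 1, 5, 5.0])
        res = select_optimal_thresholds(z, t, config=NO_FLOOR)
        naive = select_optimal_thresholds(z, t, config=NO_FLOOR, method="naive")
        assert (res.z_star, res.t_star) == (naive.z_star, naive.t_star)

    def test_perfect_association_reaches_n(self):
        """All high-DC points are exactly the high-DE points: the maximal
        chi-square equals the point count and direction is positive."""
        rng = np.random.default_rng(4)
        # t is monotone in z, so one point attains the corner of the high
        # cluster and splits the scatter perfectly
        z = np.concatenate([rng.random(20), rng.random(20) + 2.0])
        t = 2.0 * z
        res = select_optimal_thresholds(z, t)
        assert res.chi2 == pytest.approx(40.0)
        assert res.direction == "positive"
        # the chosen split is perfect: both off-diagonal cells empty
        assert res.table.hdc_lde == 0 and res.table.ldc_hde == 0

    def test_labels_reproduce_stored_counts(self):
        rng = np.random.default_rng(17)
        z = np.abs(rng.standard_normal(300))
        t = np.abs(rng.standard_normal(300))
        res = select_optimal_thresholds(z, t)
        table, labels = quadrant_partition(z, t, res.z_star, res.t_star)
        assert (table.hdc_hde, table.hdc_lde, table.ldc_hde, table.ldc_lde) == (
            res.table.hdc_hde, res.table.hdc_lde, res.table.ldc_hde,
            res.table.ldc_lde)
        np.testing.assert_array_equal(labels, res.labels)

    def test_candidate_mask_excludes_candidates_not_points(self):
        z = np.array([1, 1, 1, 5, 5, 5.0])
        t = np.array([1, 1, 1, 5, 5, 5.0])
        mask = np.array([True, True, True, False, False, False])
        res = select_optimal_thresholds(z, t, config=NO_FLOOR, candidate_mask=mask)
        # the (5,5) candidates are masked out; (1,1) has a zero LDC margin,
        # so no valid candidate remains
        assert not res.valid


class TestAdjustPvalues:
    def test_bonferroni_stage_arithmetic(self):
        s1, _ = adjust_pvalues(np.array([0.004]), 10)
        assert s1[0] == pytest.approx(0.04)

    def test_bonferroni_stage_capped_at_one(self):
        s1, _ = adjust_pvalues(np.array([0.5]), 10)
        assert s1[0] == 1.0

    def test_bh_stage_step_up(self):
        raw = np.array([0.01, 0.02, 0.03])
        _, s2 = adjust_pvalues(raw, 1)
        np.testing.assert_allclose(s2, [0.03, 0.03, 0.03])

    def test_nan_passes_through(self):
        s1, s2 = adjust_pvalues(np.array([0.01, np.nan]), 5)
        assert np.isnan(s1[1]) and np.isnan(s2[1])
        assert s1[0] == pytest.approx(0.05)

    def test_valid_candidate_multiplier_option(self):
        config = ChimaxConfig(bonferroni_by_valid=True)
        s1, _ = adjust_pvalues(np.array([0.004, 0.004]), 10, config=config,
                               n_valid=np.array([5, 2]))
        np.testing.assert_allclose(s1, [0.02, 0.008])


class TestAdjustedResidual:
    def test_independent_table_gives_zero(self):
        d, direction, p = adjusted_residual(ContingencyTable(10, 20, 30, 60))
        assert d == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)

    def test_hand_computed_value(self):
        # obs11 = 3, exp11 = 2, denominator sqrt(2 * 0.5 * 0.5)
        d, direction, _ = adjusted_residual(ContingencyTable(3, 1, 1, 3))
        assert d == pytest.approx((3 - 2) / np.sqrt(0.5), abs=1e-9)
        assert d == pytest.approx(1.414214, abs=1e-6)
        assert direction == "positive"

    def test_direction_follows_observed_vs_expected(self):
        _, direction, p = adjusted_residual(ContingencyTable(1, 9, 9, 1))
        assert direction == "negative"
        assert p > 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_squared_residual_equals_chi2(self, seed):
        """Algebraic identity for 2x2 tables: d^2 == Pearson chi-square."""
        rng = np.random.default_rng(seed)
        cells = rng.integers(1, 60, size=4)
        table = ContingencyTable(*map(int, cells))
        d, _, _ = adjusted_residual(table)
        assert d**2 == pytest.approx(pearson_chi2(table), rel=1e-10)


def test_null_chi2_distribution_against_reference():
    """The raw chi-square of one fixed table agrees with scipy's
    contingency test (no continuity correction)."""
    table = ContingencyTable(30, 12, 18, 40)
    ref = stats.chi2_contingency(
        [[table.hdc_hde, table.hdc_lde], [table.ldc_hde, table.ldc_lde]],
        correction=False)
    assert pearson_chi2(table) == pytest.approx(ref.statistic, rel=1e-12)
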