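"""Randomisation trend tests: statistics, tails, and permutation engine."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pyra import (
    TEST_IDS,
    randomisation_table,
    randomisation_test,
    stat_linear_slope,
    stat_positive_diffs,
    stat_runs_median,
    stat_runs_updown,
)
from pyra.randtests import _batch_runs, _batch_stats


def brute_runs(signs):
    """Independent run counter: explicit scan over a sign list."""
    signs = [s for s in signs if s != 0]
    if not signs:
        return 0
    runs = 1
    for a, b in zip(signs, signs[1:]):
        if a != b:
            runs += 1
    return runs


class TestStatistics:
    def test_slope_exact_line(self):
        t = np.arange(1, 8)
        assert stat_linear_slope(2.0 * t + 1.0, t) == pytest.approx(2.0)

    def test_slope_constant_series(self):
        assert stat_linear_slope(np.full(5, 3.0)) == pytest.approx(0.0)

    def test_slope_hand_computed(self):
        assert stat_linear_slope([1.0, 3.0, 2.0], [1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_slope_degenerate_times(self):
        with pytest.raises(ValueError, match="times"):
            stat_linear_slope([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])

    def test_runs_median_monotone(self):
        assert stat_runs_median([9.0, 7.0, 5.0, 3.0, 1.0]) == 2

    def test_runs_median_alternating(self):
        assert stat_runs_median([1.0, 9.0, 2.0, 8.0, 3.0, 7.0]) == 6

    def test_runs_median_all_equal_rejected(self):
        with pytest.raises(ValueError, match="median"):
            stat_runs_median([4.0, 4.0, 4.0])

    def test_positive_diffs(self):
        assert stat_positive_diffs(np.arange(10.0)) == 9
        assert stat_positive_diffs(np.arange(10.0)[::-1]) == 0
        assert stat_positive_diffs([1.0, 1.0, 2.0, 0.0, 3.0]) == 2

    def test_runs_updown_monotone(self):
        assert stat_runs_updown(np.arange(6.0)) == 1

    def test_runs_updown_alternating(self):
        assert stat_runs_updown([1.0, 5.0, 2.0, 6.0, 3.0]) == 4

    def test_runs_updown_with_tied_step(self):
        values = [1.0, 3.0, 2.0, 4.0, 4.0, 5.0]
        assert stat_runs_updown(values) == brute_runs(np.sign(np.diff(values))) == 3

    def test_runs_updown_constant_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            stat_runs_updown([2.0, 2.0, 2.0])

    @given(st.lists(st.integers(-5, 5), min_size=3, max_size=30))
    def test_run_counters_match_brute_force(self, raw):
        values = np.array(raw, dtype=float)
        med = np.median(values)
        expected_med = brute_runs(np.sign(values - med))
        if expected_med == 0:
            with pytest.raises(ValueError):
                stat_runs_median(values)
        else:
            assert stat_runs_median(values) == expected_med
        expected_ud = brute_runs(np.sign(np.diff(values)))
        if expected_ud == 0:
            with pytest.raises(ValueError):
                stat_runs_updown(values)
        else:
            assert stat_runs_updown(values) == expected_ud


class TestInvariances:
    @given(st.floats(-50, 50))
    def test_location_shift_leaves_all_statistics_unchanged(self, shift):
        rng = np.random.default_rng(8)
        v = rng.normal(size=24)
        assert stat_linear_slope(v + shift) == pytest.approx(stat_linear_slope(v), abs=1e-9)
        assert stat_runs_median(v + shift) == stat_runs_median(v)
        assert stat_positive_diffs(v + shift) == stat_positive_diffs(v)
        assert stat_runs_updown(v + shift) == stat_runs_updown(v)

    def test_monotone_transform_invariance_of_order_statistics(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=30)
        w = np.exp(v)  # strictly increasing transform
        assert stat_runs_median(w) == stat_runs_median(v)
        assert stat_positive_diffs(w) == stat_positive_diffs(v)
        assert stat_runs_updown(w) == stat_runs_updown(v)


class TestBatchEngine:
    def test_batch_runs_matches_scalar_on_random_sign_rows(self):
        rng = np.random.default_rng(10)
        mat = rng.integers(-1, 2, size=(50, 15))
        counts = _batch_runs(mat)
        for row, c in zip(mat, counts):
            assert c == brute_runs(row)

    def test_batch_stats_match_scalar_statistics(self):
        rng = np.random.default_rng(11)
        mat = rng.normal(size=(20, 40))
        med = float(np.median(mat[0]))
        np.testing.assert_allclose(
            _batch_stats(mat, "RT1"),
            [stat_linear_slope(r) for r in mat], rtol=1e-10)
        assert list(_batch_stats(mat, "RT2", median=med)) == [
            brute_runs(np.sign(r - med)) for r in mat]
        assert list(_batch_stats(mat, "RT3")) == [stat_positive_diffs(r) for r in mat]
        assert list(_batch_stats(mat, "RT4")) == [stat_runs_updown(r) for r in mat]


class TestRandomisationTest:
    def test_determinism(self):
        v = np.random.default_rng(12).normal(size=40)
        a = randomisation_test(v, "RT1", B=500, seed=3)
        b = randomisation_test(v, "RT1", B=500, seed=3)
        assert a.p_value == b.p_value

    def test_p_value_floor(self):
        # a strictly increasing series maximises the positive-diff count, so
        # under the two-sided rule the observed value sits at the extreme
        v = np.arange(20.0)
        res = randomisation_test(v, "RT3", B=999, seed=0)
        assert res.p_value >= 1.0 / (999 + 1)
        assert res.p_value < 0.01

    def test_strong_trend_detected_by_slope_and_median_runs(self):
        rng = np.random.default_rng(13)
        v = np.linspace(100, 20, 120) + rng.normal(0, 3, 120)
        assert randomisation_test(v, "RT1", B=999, seed=1).p_value < 0.01
        assert randomisation_test(v, "RT2", B=999, seed=1).p_value < 0.01

    def test_tail_override(self):
        rng = np.random.default_rng(14)
        v = rng.normal(size=60)
        lower = randomisation_test(v, "RT3", B=999, seed=2, tail="lower")
        upper = randomisation_test(v, "RT3", B=999, seed=2, tail="upper")
        # both tails computed from the same permutation stream must overlap
        assert lower.p_value + upper.p_value >= 1.0

    @pytest.mark.parametrize("test_id", TEST_IDS)
    def test_matches_exact_enumeration_at_n6(self, test_id):
        """B=5000 Monte-Carlo p-value vs exhaustive 720-ordering enumeration."""
        values = np.array([0.8, 2.9, 1.7, 4.1, 3.2, 0.3])
        stat_fn = {
            "RT1": stat_linear_slope,
            "RT2": stat_runs_median,
            "RT3": stat_positive_diffs,
            "RT4": stat_runs_updown,
        }[test_id]
        observed = float(stat_fn(values))
        perms = np.array([p for p in itertools.permutations(values)])
        exact_stats = np.array([float(stat_fn(p)) for p in perms])
        if test_id == "RT1":
            exact_extreme = np.abs(exact_stats) >= abs(observed)
        elif test_id in ("RT2", "RT4"):
            exact_extreme = exact_stats <= observed
        else:
            centre = (len(values) - 1) / 2.0  # exact null mean of RT3
            exact_extreme = np.abs(exact_stats - centre) >= abs(observed - centre)
        p_exact = exact_extreme.mean()

        res = randomisation_test(values, test_id, B=5000, seed=17)
        mc_se = np.sqrt(p_exact * (1 - p_exact) / 5000)
        assert abs(res.p_value - p_exact) < 3 * mc_se + 2 / 5001

    def test_updown_runs_permutation_mean_matches_closed_form(self):
        """E[runs up/down] over permutations of n distinct values = (2n-1)/3."""
        n = 50
        v = np.random.default_rng(15).normal(size=n)
        from pyra.randtests import _batch_stats, _perm_matrix

        perm = _batch_stats(_perm_matrix(v, 4000, np.random.default_rng(16)), "RT4")
        expected = (2 * n - 1) / 3
        se = perm.std(ddof=1) / np.sqrt(len(perm))
        assert abs(perm.mean() - expected) < 4 * se

    def test_table_reports_all_four(self):
        v = np.random.default_rng(18).normal(size=30)
        table = randomisation_table(v, B=200, seed=4)
        assert set(table) == set(TEST_IDS)
        for tid, res in table.items():
            assert res.test_id == tid
            assert 1 / 201 <= res.p_value <= 1.0
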