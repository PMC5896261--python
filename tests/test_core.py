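"""Unit and property tests for the two-group effect sizes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sortstat import (
    COHEN_D_BAND,
    SORTING_BAND,
    CalibrationBand,
    EffectSizeError,
    GroupedSample,
    ZeroSpreadError,
    classify_effect,
    cohens_d,
    effect_sizes,
    median,
    sorting_statistic,
)

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)
small_samples = st.lists(finite_floats, min_size=1, max_size=25)


class TestMedian:
    @pytest.mark.parametrize(
        "values, expected",
        [([1, 2, 3], 2.0), ([1, 2, 3, 10], 2.5), ([5], 5.0), ([2, 2, 2, 2], 2.0)],
    )
    def test_examples(self, values, expected):
        assert median(values) == expected

    def test_empty_raises(self):
        with pytest.raises(EffectSizeError, match="no data"):
            median([])

    def test_non_finite_raises(self):
        with pytest.raises(EffectSizeError, match="non-finite"):
            median([1.0, math.nan])


class TestCohensD:
    def test_identical_groups_zero(self):
        d, _ = cohens_d(GroupedSample([2, 4, 6], [2, 4, 6]))
        assert d == 0.0

    def test_joint_mode_hand_computed(self):
        # sample variance of {1..6} is 3.5; d = -3 / sqrt(3.5)
        d, sigma = cohens_d(GroupedSample([1, 2, 3], [4, 5, 6]), "joint")
        assert sigma == pytest.approx(math.sqrt(3.5))
        assert d == pytest.approx(-3 / math.sqrt(3.5))
        assert d == pytest.approx(-1.60357, abs=1e-5)
        assert d < 0  # mean_x < mean_y forces the sign

    def test_pooled_mode_hand_computed(self):
        # within-group variances are both 1 -> pooled sigma 1
        d, sigma = cohens_d(GroupedSample([1, 2, 3], [4, 5, 6]), "pooled")
        assert sigma == pytest.approx(1.0)
        assert d == pytest.approx(-3.0)

    def test_zero_spread_raises(self):
        with pytest.raises(ZeroSpreadError):
            cohens_d(GroupedSample([3, 3], [3, 3]))

    def test_pooled_needs_two_per_group(self):
        with pytest.raises(EffectSizeError):
            cohens_d(GroupedSample([1], [2, 3]), "pooled")


class TestSortingStatistic:
    def test_equal_medians_zero(self):
        # both medians are 2.5 despite different spreads
        res = sorting_statistic(GroupedSample([1, 2, 3, 10], [0, 2, 3, 4]))
        assert res.ds == 0.0

    def test_perfect_separation_one(self):
        res = sorting_statistic(GroupedSample([4, 5, 6], [1, 2, 3]))
        assert res.ds == 1.0
        assert not res.swapped

    def test_interleaved_thirds(self):
        # medians 4 vs 3; sorted joint (6,5,4,3,2,1): first-3 median 5, last-3 median 2
        res = sorting_statistic(GroupedSample([2, 4, 6], [1, 3, 5]))
        assert res.ds == pytest.approx(1 / 3)
        assert (res.median_hi, res.median_lo) == (4.0, 3.0)
        assert (res.z_med_hi, res.z_med_lo) == (5.0, 2.0)
        assert not res.swapped

    def test_swap_recorded_and_value_unchanged(self):
        fwd = sorting_statistic(GroupedSample([2, 4, 6], [1, 3, 5]))
        rev = sorting_statistic(GroupedSample([1, 3, 5], [2, 4, 6]))
        assert rev.ds == fwd.ds
        assert rev.swapped and not fwd.swapped
        assert rev.ds_signed == -fwd.ds_signed

    def test_constant_data_zero(self):
        assert sorting_statistic(GroupedSample([7, 7], [7, 7, 7])).ds == 0.0

    def test_descending_equals_ascending_with_roles_exchanged(self):
        # sorting ascending and taking the last n / first m gives the same value
        rng = np.random.default_rng(7)
        for _ in range(50):
            n, m = rng.integers(1, 12, size=2)
            x, y = rng.normal(size=n), rng.normal(size=m)
            res = sorting_statistic(GroupedSample(x, y))
            if res.ds == 0.0:
                continue
            hi = np.sort(np.concatenate([x, y]))  # ascending
            n_hi = res.n_hi
            alt = (res.median_hi - res.median_lo) / (
                np.median(hi[-n_hi:]) - np.median(hi[: len(hi) - n_hi])
            )
            assert res.ds == pytest.approx(alt, abs=1e-12)


class TestProperties:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(small_samples, small_samples)
    def test_bounded_zero_one(self, x, y):
        assert 0.0 <= sorting_statistic(GroupedSample(x, y)).ds <= 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(small_samples, small_samples)
    def test_group_swap_symmetry(self, x, y):
        assert sorting_statistic(GroupedSample(x, y)).ds == pytest.approx(
            sorting_statistic(GroupedSample(y, x)).ds, abs=1e-15
        )

    # integer-valued samples keep median gaps >= 0.5, so the 1e-12 band is
    # meaningful and not swamped by cancellation of large transformed values
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(-50, 50).map(float), min_size=1, max_size=25),
        st.lists(st.integers(-50, 50).map(float), min_size=1, max_size=25),
        st.floats(-10, 10).filter(lambda a: abs(a) > 1e-2),
        st.floats(-10, 10),
    )
    def test_affine_invariance(self, x, y, a, b):
        base = sorting_statistic(GroupedSample(x, y)).ds
        mapped = sorting_statistic(
            GroupedSample(a * np.asarray(x) + b, a * np.asarray(y) + b)
        ).ds
        assert mapped == pytest.approx(base, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(small_samples, small_samples, st.floats(0.1, 10), st.floats(-10, 10))
    def test_cohens_d_affine_equivariance(self, x, y, a, b):
        try:
            d0, _ = cohens_d(GroupedSample(x, y))
        except EffectSizeError:
            return
        d1, _ = cohens_d(GroupedSample(a * np.asarray(x) + b, a * np.asarray(y) + b))
        assert d1 == pytest.approx(d0, rel=1e-9, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(small_samples, small_samples, st.randoms(use_true_random=False))
    def test_tie_indifference_under_shuffle(self, x, y, rnd):
        base = sorting_statistic(GroupedSample(x, y)).ds
        xs, ys = list(x), list(y)
        rnd.shuffle(xs)
        rnd.shuffle(ys)
        assert sorting_statistic(GroupedSample(xs, ys)).ds == base

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(small_samples, small_samples)
    def test_zero_iff_equal_medians(self, x, y):
        res = sorting_statistic(GroupedSample(x, y))
        assert (res.ds == 0.0) == (np.median(x) == np.median(y))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(small_samples, small_samples)
    def test_sorted_joint_medians_dominate(self, x, y):
        res = sorting_statistic(GroupedSample(x, y))
        assert res.z_med_hi >= res.median_hi
        assert res.z_med_lo <= res.median_lo
        assert res.median_hi >= res.median_lo


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "value, band, expected",
        [
            (0.45, SORTING_BAND, "medium"),
            (0.8, COHEN_D_BAND, "large"),
            (-0.8, COHEN_D_BAND, "large"),  # |d| is classified
            (0.0, COHEN_D_BAND, "negligible"),
            (0.0, SORTING_BAND, "negligible"),
            (0.19999, SORTING_BAND, "negligible"),
            (0.2, COHEN_D_BAND, "small"),
            (0.5, COHEN_D_BAND, "medium"),
            (0.7, SORTING_BAND, "large"),
        ],
    )
    def test_anchors(self, value, band, expected):
        assert classify_effect(value, band) == expected

    def test_malformed_band_rejected(self):
        with pytest.raises(ValueError):
            CalibrationBand("sorting", (0.5, 0.45, 0.7))

    def test_nan_rejected(self):
        with pytest.raises(EffectSizeError):
            classify_effect(math.nan, COHEN_D_BAND)


class TestEffectSizes:
    def test_bundle_matches_components(self):
        sample = GroupedSample([2, 4, 6], [1, 3, 5])
        res = effect_sizes(sample)
        d, sigma = cohens_d(sample)
        assert res.d == d and res.d_sigma == sigma
        assert res.ds == pytest.approx(1 / 3)
        assert not res.swapped

    def test_separation_positive_mean(self):
        res = effect_sizes(GroupedSample([4, 5, 6], [1, 2, 3]))
        assert res.ds == 1.0 and res.d > 0

    def test_constant_data_ds_defined_d_nan(self):
        res = effect_sizes(GroupedSample([3, 3, 3], [3, 3]))
        assert res.ds == 0.0
        assert not res.d_defined

    def test_missing_values_dropped_by_from_raw(self):
        sample = GroupedSample.from_raw([1, 2, math.nan, 3], [4, math.inf, 5, 6])
        assert sample.n == 3 and sample.m == 3
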