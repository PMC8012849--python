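import numpy as np
import pytest
from scipy import stats

import nirsbmi as nb
from nirsbmi.features import FEATURES


class TestScalarFeatures:
    @pytest.mark.parametrize(
        "x,expected",
        [([2, 4, 6], 4.0), ([5, 5, 5], 5.0), ([1, 2, 3, 4], 2.5)],
    )
    def test_mean(self, x, expected):
        assert nb.mean(x) == pytest.approx(expected)

    def test_mean_empty_rejected(self):
        with pytest.raises(ValueError):
            nb.mean([])

    @pytest.mark.parametrize("x,expected", [([1, 2, 3], 1.0), ([4, 4, 4], 0.0)])
    def test_variance_sample_denominator(self, x, expected):
        assert nb.variance(x) == pytest.approx(expected)

    def test_variance_quadratic_scaling(self, rng):
        x = rng.normal(size=50)
        assert nb.variance(2 * x) == pytest.approx(4 * nb.variance(x))

    def test_stdev_is_sqrt_variance(self, rng):
        x = rng.normal(size=30)
        assert nb.stdev(x) == pytest.approx(np.sqrt(nb.variance(x)))

    def test_variance_single_point_rejected(self):
        with pytest.raises(ValueError):
            nb.variance([1.0])

    @pytest.mark.parametrize(
        "x,dt,expected",
        [
            ([0, 1, 2, 3], 1.0, 1.0),
            ([7, 7, 7], 1.0, 0.0),
            ([0, 2], 0.125, 16.0),  # two-point rise over run 2 / 0.125
        ],
    )
    def test_slope(self, x, dt, expected):
        assert nb.slope(x, dt) == pytest.approx(expected)

    def test_kurtosis_two_point_symmetric(self):
        # mu=0, sigma^2=1, fourth moments sum to 4 -> 4/(4*1) = 1
        assert nb.kurtosis([-1, 1, -1, 1]) == pytest.approx(1.0)

    def test_kurtosis_matches_normal_reference(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        assert nb.kurtosis(x) == pytest.approx(3.0, abs=0.2)

    def test_kurtosis_constant_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            nb.kurtosis([2, 2, 2])

    def test_skewness_symmetric_is_zero(self):
        assert nb.skewness([-2, -1, 1, 2]) == pytest.approx(0.0)

    def test_skewness_hand_value(self):
        # [0,0,0,1]: mu=0.25, population sigma^2=0.1875 -> 2/sqrt(3)
        assert nb.skewness([0, 0, 0, 1]) == pytest.approx(2 / np.sqrt(3))

    def test_skewness_sign_flip(self, rng):
        x = rng.exponential(size=200)
        assert nb.skewness(-x) == pytest.approx(-nb.skewness(x))

    def test_moments_agree_with_scipy(self, rng):
        x = rng.normal(size=64)
        assert nb.kurtosis(x) == pytest.approx(
            stats.kurtosis(x, fisher=False, bias=True)
        )
        assert nb.skewness(x) == pytest.approx(stats.skew(x, bias=True))


class TestExtractFeatures:
    def test_19_windows_per_20s_epoch(self, default_subject, dual_schedule):
        _, _, series = default_subject
        fm = nb.extract_features(series, dual_schedule)
        assert fm.n_rows == 19 * 10 * 2  # windows x trials x levels
        per_epoch = np.bincount(fm.epoch_id)
        assert np.all(per_epoch == 19)

    def test_constant_series_mean_feature_is_constant(self, dual_schedule):
        n = dual_schedule.n_samples
        series = nb.HemodynamicSeries(
            hbo=np.ones((2, n)), hbr=np.ones((2, n)), sampling_rate=8.0
        )
        fm = nb.extract_features(series, dual_schedule, feature_set=("mean",))
        assert np.allclose(fm.X.values, 1.0)

    def test_class_means_ordered_by_amplitude(self, default_subject, dual_schedule):
        _, _, series = default_subject
        fm = nb.extract_features(series, dual_schedule, feature_set=("mean",))
        m1 = fm.X.values[fm.y == "mwl1"].mean()
        m2 = fm.X.values[fm.y == "mwl2"].mean()
        assert m2 > m1

    def test_invariant_to_excluded_channel(self, default_subject, dual_schedule):
        _, _, series = default_subject
        keep = np.arange(6)
        a = nb.extract_features(series, dual_schedule, channels=keep)
        b = nb.extract_features(series, dual_schedule, channels=np.arange(7))
        np.testing.assert_array_equal(
            a.X.values, b.X[a.X.columns].values
        )

    def test_all_six_features_supported(self, default_subject, dual_schedule):
        _, _, series = default_subject
        fm = nb.extract_features(
            series, dual_schedule, feature_set=tuple(FEATURES), channels=[0, 1]
        )
        assert fm.X.shape[1] == len(FEATURES) * 2
        assert not fm.X.isna().any().any()

    def test_channel_average_mode(self, default_subject, dual_schedule):
        _, _, series = default_subject
        fm = nb.extract_features(series, dual_schedule, channel_average=True)
        assert fm.X.shape[1] == 2  # mean + slope of the spatial average

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"channels": []},
            {"window_s": 25.0},
            {"feature_set": ("mean", "nope")},
        ],
    )
    def test_invalid_arguments_rejected(self, default_subject, dual_schedule, kwargs):
        _, _, series = default_subject
        with pytest.raises(ValueError):
            nb.extract_features(series, dual_schedule, **kwargs)

    def test_labels_only_from_task_epochs(self, default_subject, dual_schedule):
        _, _, series = default_subject
        fm = nb.extract_features(series, dual_schedule)
        assert set(np.unique(fm.y)) == {"mwl1", "mwl2"}
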