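import numpy as np
import pytest

from roma_ppg.agreement import (cohens_kappa, error_metrics, landis_koch_band,
                                pearson_with_ci, point_biserial, welch_t)
from roma_ppg.errors import DataError
from roma_ppg.signal_io import HRSeries


def series(hr):
    return HRSeries(np.arange(len(hr), dtype=float), hr)


class TestErrorMetrics:
    def test_identical_series_all_zero(self):
        s = series(np.full(10, 80.0))
        stats = error_metrics(s, s)
        assert (stats.rmse, stats.mae, stats.mae_pct, stats.accuracy5) == (0.0, 0.0, 0.0, 100.0)
        assert stats.n == 10

    def test_hand_arithmetic_with_nminus1_denominator(self):
        stats = error_metrics(series([100.0, 110.0]), series([102.0, 108.0]))
        assert stats.rmse == pytest.approx(np.sqrt(8.0), abs=1e-3)  # 2.828
        assert stats.mae == 2.0
        assert stats.mae_pct == pytest.approx(100 * (2 / 100 + 2 / 110) / 2, abs=1e-3)  # 1.909
        assert stats.accuracy5 == 100.0

    def test_accuracy_counts_within_5_bpm(self):
        stats = error_metrics(series([100.0, 100.0]), series([100.0, 110.0]))
        assert stats.accuracy5 == 50.0

    def test_standard_denominator_option(self):
        x, y = series([100.0, 110.0]), series([102.0, 108.0])
        nm1 = error_metrics(x, y).rmse
        standard = error_metrics(x, y, rmse_denominator="n").rmse
        assert standard == pytest.approx(2.0)
        assert nm1 >= standard

    def test_rmse_mae_sign_symmetric_but_mae_pct_not(self):
        x = series([100.0, 120.0, 90.0, 105.0])
        y = series([104.0, 115.0, 95.0, 100.0])
        a, b = error_metrics(x, y), error_metrics(y, x)
        assert a.rmse == b.rmse and a.mae == b.mae
        assert a.mae_pct != b.mae_pct

    def test_rmse_at_least_mae(self, rng):
        for _ in range(20):
            x = series(rng.uniform(60, 180, 30))
            y = series(rng.uniform(60, 180, 30))
            stats = error_metrics(x, y, rmse_denominator="n")
            assert stats.rmse >= stats.mae - 1e-12

    def test_outlier_mask_excluded(self):
        x = series([100.0, 100.0, 100.0])
        y = series([100.0, 50.0, 100.0])
        mask = np.array([False, True, False])
        assert error_metrics(x, y, outlier_mask=mask).mae == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            error_metrics(series([100.0]), series([100.0]))


class TestPointBiserial:
    def test_binary_equals_continuous_gives_one(self):
        assert point_biserial([0, 1, 0, 1], [0.0, 1.0, 0.0, 1.0]) == pytest.approx(1.0)

    def test_hand_pearson_value(self):
        assert point_biserial([0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0]) == pytest.approx(
            2.0 / np.sqrt(5.0), abs=1e-3)  # 0.894

    def test_equal_group_means_give_zero(self):
        assert point_biserial([0, 0, 1, 1], [1.0, 3.0, 2.0, 2.0]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_general_pearson_formula(self, rng):
        for _ in range(20):
            b = rng.integers(0, 2, 30).astype(float)
            if b.min() == b.max():
                continue
            c = rng.normal(size=30)
            expected = np.corrcoef(b, c)[0, 1]
            assert point_biserial(b, c) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            point_biserial([1, 1, 1], [1.0, 2.0, 3.0])


class TestCohensKappa:
    def test_identical_vectors_give_one(self):
        k, band = cohens_kappa([1, 0, 1, 0], [1, 0, 1, 0])
        assert k == 1.0 and band == "almost perfect agreement"

    def test_hand_computed_two_by_two(self):
        k, _ = cohens_kappa([1, 1, 0, 0, 1, 0], [1, 0, 0, 0, 1, 1])
        assert k == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_landis_koch_bands(self):
        assert landis_koch_band(0.872) == "almost perfect agreement"
        assert landis_koch_band(0.72) == "substantial agreement"
        assert landis_koch_band(0.5) == "moderate agreement"
        assert landis_koch_band(0.3) == "fair agreement"
        assert landis_koch_band(0.1) == "slight agreement"
        assert landis_koch_band(-0.2) == "poor agreement"

    def test_both_raters_constant_equal_defined_as_one(self):
        k, _ = cohens_kappa([1, 1, 1], [1, 1, 1])
        assert k == 1.0

    def test_kappa_never_exceeds_one(self, rng):
        for _ in range(30):
            a = rng.integers(0, 2, 20)
            b = rng.integers(0, 2, 20)
            k, _ = cohens_kappa(a, b)
            assert k <= 1.0 + 1e-12


class TestWelchT:
    def test_identical_groups_t_zero(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        _, p = welch_t(a, b)
        assert p < 1e-10

    def test_single_observation_group_rejected(self):
        with pytest.raises(DataError):
            welch_t([1.0], [1.0, 2.0])

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DataError):
            welch_t([2.0, 2.0], [3.0, 3.0])


def test_pearson_ci_brackets_r(rng):
    x = rng.normal(size=50)
    y = x + rng.normal(0, 0.5, 50)
    r, lo, hi = pearson_with_ci(x, y)
    assert lo < r < hi
    assert 0.5 < r <= 1.0
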