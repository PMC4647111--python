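"""Weighted spline smoothing, bleach correction, logistic fit, Pearson r."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from supersample import (
    BleachConfig,
    LogisticParams,
    ResampledSignal,
    SplineConfig,
    bleach_correct,
    fit_double_exponential,
    fit_logistic,
    pearson_r,
    smooth_weighted_spline,
    weighted_spline,
)
from supersample.curves import logistic


def random_xyw(rng, n=25):
    x = np.sort(rng.uniform(0, 1, size=n))
    y = rng.normal(size=n)
    w = rng.integers(1, 6, size=n).astype(float)
    return x, y, w


class TestWeightedSpline:
    def test_p_one_interpolates(self, rng):
        x, y, w = random_xyw(rng)
        f = weighted_spline(x, y, w, SplineConfig(p=1.0))
        np.testing.assert_allclose(f(x), y, atol=1e-9)

    def test_p_zero_is_weighted_least_squares_line(self, rng):
        x, y, w = random_xyw(rng)
        f = weighted_spline(x, y, w, SplineConfig(p=0.0))
        # independent oracle: numpy polynomial weighted fit (sqrt-weights)
        c = np.polynomial.polynomial.polyfit(x, y, 1, w=np.sqrt(w))
        np.testing.assert_allclose(f(x), c[0] + c[1] * x, atol=1e-9)

    def test_straight_line_data_is_fixed_point_for_every_p(self):
        x = np.linspace(0, 1, 12)
        y = 2.0 - 3.0 * x
        w = np.ones_like(x)
        for p in (0.0, 0.2, 0.6, 1.0):
            f = weighted_spline(x, y, w, SplineConfig(p=p))
            np.testing.assert_allclose(f(x), y, atol=1e-8)

    def test_linearity_in_y(self, rng):
        x, y1, w = random_xyw(rng)
        y2 = rng.normal(size=len(x))
        cfg = SplineConfig(p=0.4)
        f12 = weighted_spline(x, y1 + y2, w, cfg)(x)
        f1 = weighted_spline(x, y1, w, cfg)(x)
        f2 = weighted_spline(x, y2, w, cfg)(x)
        np.testing.assert_allclose(f12, f1 + f2, atol=1e-8)

    def test_residual_decreases_and_roughness_increases_with_p(self, rng):
        x, y, w = random_xyw(rng, n=40)
        ps = [0.05, 0.2, 0.5, 0.8, 0.99]
        residuals, roughness = [], []
        xg = np.linspace(x[0], x[-1], 2000)
        for p in ps:
            f = weighted_spline(x, y, w, SplineConfig(p=p))
            residuals.append(np.sum(w * (y - f(x)) ** 2))
            d2 = np.gradient(np.gradient(f(xg), xg), xg)
            roughness.append(np.trapezoid(d2**2, xg))
        assert all(a >= b - 1e-9 for a, b in zip(residuals, residuals[1:]))
        assert all(a <= b + 1e-6 * max(roughness) for a, b in zip(roughness, roughness[1:]))

    def test_heavier_points_are_pulled_closer(self, rng):
        """The smoothing applied to a point is inversely related to its weight."""
        x = np.linspace(0, 1, 30)
        y = np.zeros_like(x)
        y[15] = 1.0  # outlier bump
        cfg = SplineConfig(p=0.3)
        light = weighted_spline(x, y, np.ones_like(x), cfg)(x)[15]
        w_heavy = np.ones_like(x)
        w_heavy[15] = 30.0
        heavy = weighted_spline(x, y, w_heavy, cfg)(x)[15]
        assert abs(1.0 - heavy) < abs(1.0 - light)

    def test_invalid_inputs(self, rng):
        x, y, w = random_xyw(rng)
        with pytest.raises(ValueError):
            SplineConfig(p=1.5)
        with pytest.raises(ValueError):
            weighted_spline(x[:3], y[:3], w[:3], SplineConfig(p=0.5))

    def test_resampled_wrapper_fits_on_weighted_bins_only(self):
        # bins 2/5 are gap-filled (weight 0): the spline must ignore their values
        values = np.array([0.0, 1.0, 99.0, 3.0, 4.0, -99.0, 6.0, 7.0])
        weight = np.array([3, 2, 0, 1, 2, 0, 3, 1])
        rs = ResampledSignal(
            rate_hz=100.0,
            values=values,
            bin_weight=weight,
            missing_mask=weight == 0,
            filled=True,
        )
        smoothed = smooth_weighted_spline(rs, SplineConfig(p=1.0))
        assert len(smoothed) == 8
        present = weight > 0
        np.testing.assert_allclose(smoothed[present], values[present], atol=1e-9)
        assert abs(smoothed[2]) < 10  # interpolant, not the sentinel value


class TestBleachCorrect:
    def make_rs(self, t, values, weight=None):
        n = len(t)
        weight = np.ones(n, dtype=int) if weight is None else weight
        return ResampledSignal(
            rate_hz=1.0 / (t[1] - t[0]),
            values=values,
            bin_weight=weight,
            missing_mask=np.zeros(n, dtype=bool),
            origin_s=t[0],
        )

    def test_flat_zero_trace_unchanged(self):
        t = np.linspace(0, 1, 50)
        rs = self.make_rs(t, np.zeros(50))
        corrected, fit = bleach_correct(rs, BleachConfig(exclusion_window_s=(0.4, 0.6)))
        np.testing.assert_allclose(corrected, 0.0, atol=1e-9)
        assert fit.residual_rms < 1e-9

    def test_parameter_recovery_with_event_excluded(self):
        t = np.linspace(0, 1, 200)
        decay = 1.0 * np.exp(-t / 0.05) + 0.5 * np.exp(-t / 0.5)
        event = np.interp(t, [0.45, 0.50, 0.55], [0.0, 0.8, 0.0])
        rs = self.make_rs(t, decay + event)
        corrected, fit = bleach_correct(rs, BleachConfig(exclusion_window_s=(0.44, 0.56)))
        assert fit.converged
        assert fit.params["a1"] == pytest.approx(1.0, rel=1e-6)
        assert fit.params["tau1"] == pytest.approx(0.05, rel=1e-6)
        assert fit.params["a2"] == pytest.approx(0.5, rel=1e-6)
        assert fit.params["tau2"] == pytest.approx(0.5, rel=1e-6)
        np.testing.assert_allclose(corrected, event, atol=1e-7)

    def test_noiseless_fit_residual_tiny(self):
        t = np.linspace(0, 2, 100)
        y = 2.0 * np.exp(-t / 0.3) + 0.7 * np.exp(-t / 1.5) + 0.2
        fit, model = fit_double_exponential(t, y)
        assert fit.residual_rms <= 1e-8 * 2.0
        np.testing.assert_allclose(model(t), y, atol=1e-7)

    def test_exclusion_window_covering_everything_errors(self):
        t = np.linspace(0, 1, 50)
        rs = self.make_rs(t, np.exp(-t))
        with pytest.raises(ValueError):
            bleach_correct(rs, BleachConfig(exclusion_window_s=(-1.0, 2.0)))

    def test_tau_ordering_canonical(self):
        t = np.linspace(0, 1, 120)
        y = 0.5 * np.exp(-t / 0.6) + 1.5 * np.exp(-t / 0.04)
        fit, _ = fit_double_exponential(t, y, include_offset=False)
        assert fit.params["tau1"] <= fit.params["tau2"]


class TestFitLogistic:
    def test_noiseless_parameter_recovery(self):
        x = np.linspace(0.010, 0.030, 40)
        y = logistic(x, 0.2, 0.020, 2000.0)
        params, fit = fit_logistic(x, y)
        assert fit.converged
        assert params.A == pytest.approx(0.2, rel=1e-6)
        assert params.mu == pytest.approx(0.020, rel=1e-6)
        assert params.s == pytest.approx(2000.0, rel=1e-6)

    def test_midpoint_identity(self):
        x = np.linspace(0, 1, 50)
        y = logistic(x, 0.7, 0.4, 12.0) + 0.0
        params, _ = fit_logistic(x, y)
        assert params(np.array([params.mu]))[0] == pytest.approx(params.A / 2)

    def test_time_shift_equivariance(self):
        x = np.linspace(0.0, 0.04, 60)
        y = logistic(x, 0.3, 0.015, 800.0)
        p0, _ = fit_logistic(x, y)
        p1, _ = fit_logistic(x + 0.005, y)
        assert p1.mu == pytest.approx(p0.mu + 0.005, rel=1e-6)
        assert p1.A == pytest.approx(p0.A, rel=1e-6)
        assert p1.s == pytest.approx(p0.s, rel=1e-6)

    def test_positive_slope_rises(self):
        x = np.linspace(-1, 1, 201)
        y = logistic(x, 1.0, 0.0, 5.0)
        assert np.all(np.diff(y) > 0)
        assert y[100] == pytest.approx(0.5)

    def test_flat_input_errors(self):
        with pytest.raises(ValueError):
            fit_logistic(np.linspace(0, 1, 10), np.ones(10))

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            fit_logistic(np.arange(4.0), np.arange(4.0))


class TestPearsonR:
    def test_identical_and_inverted(self, rng):
        a = rng.normal(size=30)
        assert pearson_r(a, a) == pytest.approx(1.0)
        assert pearson_r(a, -a) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 6.5, sd_a^2 = 5, sd_b^2 = 8.75 -> r = 6.5 / sqrt(43.75)
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson_r(a, b) == pytest.approx(6.5 / np.sqrt(43.75), abs=1e-12)

    def test_nan_pairs_excluded(self):
        a = np.array([1.0, np.nan, 3.0, 4.0, 2.0])
        b = np.array([1.0, 2.0, 3.0, np.nan, 2.5])
        assert pearson_r(a, b) == pytest.approx(
            pearson_r(np.array([1.0, 3.0, 2.0]), np.array([1.0, 3.0, 2.5]))
        )

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            pearson_r(np.arange(3.0), np.arange(4.0))
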