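"""Harmonic stride modelling, analytic integration, and Gibbs behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import cumulative_trapezoid, trapezoid

from gaitdisp import (HarmonicStrideModel, analytic_integrate, fit_harmonics,
                      gibbs_overshoot_fraction, normalized_rmsd)


def _gait_like_model(rng, N=20):
    T = rng.uniform(0.8, 1.4)
    k = np.arange(1, N + 1)
    amp = 2.0 * np.where(k <= 6, 1.0, (6.0 / k) ** 2)
    a = (amp * rng.standard_normal(N))[:, None]
    b = (amp * rng.standard_normal(N))[:, None]
    return HarmonicStrideModel(T, N, [0.0], a, b)


class TestFit:
    def test_constant_signal_dc_only(self):
        t = np.arange(100) / 100.0
        m = fit_harmonics(np.full(100, 2.5), t, 1.0, 20)
        assert m.a0[0] == pytest.approx(2.5, abs=1e-10)
        assert np.abs(m.a).max() < 1e-10 and np.abs(m.b).max() < 1e-10

    def test_single_cosine_recovered(self):
        T = 1.3
        t = np.arange(120) / 120.0 * T
        m = fit_harmonics(np.cos(2 * np.pi * t / T), t, T, 20)
        assert m.a[0, 0] == pytest.approx(1.0, abs=1e-10)
        mask = np.ones_like(m.a, dtype=bool)
        mask[0] = False
        assert np.abs(m.a[mask]).max() < 1e-10
        assert np.abs(m.b).max() < 1e-10

    def test_self_inverse_roundtrip(self, rng):
        """Coefficients drawn at random are recovered exactly from synthesis."""
        T, N, M = 1.1, 20, 100
        t = np.arange(M) / M * T
        a = rng.standard_normal((N, 3))
        b = rng.standard_normal((N, 3))
        a0 = rng.standard_normal(3)
        model = HarmonicStrideModel(T, N, a0, a, b)
        fit = fit_harmonics(model.evaluate(t), t, T, N)
        assert np.abs(fit.a - a).max() < 1e-9
        assert np.abs(fit.b - b).max() < 1e-9
        assert np.abs(fit.a0 - a0).max() < 1e-9

    def test_short_stride_reduces_order(self):
        t = np.arange(20) / 20.0
        with pytest.warns(UserWarning, match="reduced"):
            m = fit_harmonics(np.sin(2 * np.pi * t), t, 1.0, 20)
        assert m.N == 9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_harmonics(np.zeros(2), np.arange(2.0), 1.0, 20)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.floats(-3, 3), st.floats(-3, 3), st.integers(0, 2**31 - 1))
def test_fit_linearity(alpha, beta, seed):
    """fit(αx + βy) = α·fit(x) + β·fit(y) coefficient-wise."""
    rng = np.random.default_rng(seed)
    T, N, M = 1.0, 8, 60
    t = np.arange(M) / M * T
    x = rng.standard_normal(M)
    y = rng.standard_normal(M)
    fx, fy = fit_harmonics(x, t, T, N), fit_harmonics(y, t, T, N)
    fxy = fit_harmonics(alpha * x + beta * y, t, T, N)
    assert np.allclose(fxy.a, alpha * fx.a + beta * fy.a, atol=1e-8)
    assert np.allclose(fxy.b, alpha * fx.b + beta * fy.b, atol=1e-8)


class TestAnalyticIntegration:
    def test_single_harmonic_closed_form(self):
        """cos acceleration, T = 1 s: displacement −(1/2π)² cos(2πt)."""
        m = HarmonicStrideModel(1.0, 1, [0.0], [[1.0]], [[0.0]])
        d = analytic_integrate(m, 2)
        assert d.a[0, 0] == pytest.approx(-(1.0 / (2 * np.pi)) ** 2, rel=1e-12)
        assert d.b[0, 0] == 0.0
        assert d.quantity == "displacement"

    def test_velocity_coefficient_mapping(self):
        m = HarmonicStrideModel(2.0, 2, [0.5], [[1.0], [0.2]], [[0.3], [-0.4]])
        v = analytic_integrate(m, 1)
        scale = 2.0 / (2 * np.pi)
        assert v.a[0, 0] == pytest.approx(-scale * 0.3)
        assert v.b[0, 0] == pytest.approx(scale * 1.0)
        assert v.a[1, 0] == pytest.approx(-scale / 2 * -0.4)
        assert v.b[1, 0] == pytest.approx(scale / 2 * 0.2)
        assert v.a0[0] == 0.0  # constant term discarded

    def test_matches_numeric_double_integration(self, rng):
        """Closed-period 10 kHz trapezoid with per-pass mean removal."""
        worst = 0.0
        for _ in range(100):
            m = _gait_like_model(rng)
            t = np.linspace(0.0, m.T, int(m.T * 1e4) + 1)
            acc = m.evaluate(t)[:, 0]
            acc = acc - trapezoid(acc, t) / m.T
            vel = cumulative_trapezoid(acc, t, initial=0.0)
            vel -= trapezoid(vel, t) / m.T
            disp = cumulative_trapezoid(vel, t, initial=0.0)
            disp -= trapezoid(disp, t) / m.T
            d_analytic = analytic_integrate(m, 2).evaluate(t)[:, 0]
            worst = max(worst, np.abs(disp - d_analytic).max())
        assert worst < 1e-6

    def test_zero_model_integrates_to_zero(self):
        m = HarmonicStrideModel(1.0, 3, [0.0], np.zeros((3, 1)), np.zeros((3, 1)))
        t = np.linspace(0, 1, 50)
        assert np.abs(analytic_integrate(m, 2).evaluate(t)).max() == 0.0

    def test_displacement_zero_mean_per_stride(self, rng):
        m = _gait_like_model(rng)
        d = analytic_integrate(m, 2)
        assert np.all(d.a0 == 0.0)
        t = np.linspace(0.0, m.T, 20001)
        assert abs(trapezoid(d.evaluate(t)[:, 0], t) / m.T) < 1e-12

    def test_invalid_order_rejected(self, rng):
        with pytest.raises(ValueError):
            analytic_integrate(_gait_like_model(rng), 3)


class TestNormalizedRmsd:
    def test_perfect_reconstruction_zero(self, rng):
        x = rng.standard_normal(100)
        assert normalized_rmsd(x, x) == 0.0

    def test_zero_reconstruction_is_100(self, rng):
        x = rng.standard_normal(100)
        assert normalized_rmsd(x, np.zeros(100)) == pytest.approx(100.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalized_rmsd(np.zeros(10), np.ones(10))


class TestGibbs:
    def _unit_step(self, m=4096):
        x = np.zeros(m)
        x[m // 2:] = 1.0
        return x

    def test_large_order_approaches_asymptotic_constant(self):
        res = gibbs_overshoot_fraction(self._unit_step(), 200)
        assert res.overshoot_fraction == pytest.approx(0.0895, abs=0.002)
        assert res.oscillation_frequency_hz == pytest.approx(200.0)

    def test_order_20_overshoot_about_nine_percent(self):
        res = gibbs_overshoot_fraction(self._unit_step(), 20)
        assert 0.085 <= res.overshoot_fraction <= 0.095

    def test_continuous_signal_rejected(self):
        t = np.linspace(0, 1, 512, endpoint=False)
        with pytest.raises(ValueError):
            gibbs_overshoot_fraction(np.sin(2 * np.pi * t), 20)

    def test_displacement_domain_attenuation_below_one_mm(self):
        """A gait-scale acceleration jump leaves sub-mm Gibbs ripples in the
        displacement because the k-th ripple is scaled by 1/k²."""
        T, N, M = 1.0, 20, 128
        t = np.arange(M) / M * T
        jump = 2.0  # m/s², a large boundary discontinuity
        x = np.where(t < T / 2, -jump / 2, jump / 2)
        model = fit_harmonics(x, t, T, N)
        d = analytic_integrate(model, 2)
        td = np.linspace(0, T, 20001)
        # displacement of the true (piecewise) signal: triangle-wave-like;
        # compare against a very high order fit as truth
        x_hi = np.where(np.linspace(0, T, 4096, endpoint=False) < T / 2,
                        -jump / 2, jump / 2)
        model_hi = fit_harmonics(x_hi, np.linspace(0, T, 4096, endpoint=False),
                                 T, 400)
        d_hi = analytic_integrate(model_hi, 2)
        err = np.abs(d.evaluate(td) - d_hi.evaluate(td)).max()
        assert err < 1e-3  # < 1 mm
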