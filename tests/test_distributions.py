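"""Gamma/exponential/empirical waiting-time laws: densities, moments,
hazards, the chain-convolution identity, and least-squares fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import fftconvolve

import rtnet as rt
from rtnet.distributions import (
    EmpiricalRT,
    ExhaustedSupportError,
    fit_gamma_to_samples,
)


class TestGammaDensity:
    @pytest.mark.parametrize("shape,rate,t,expected", [
        (1.0, 1.0, 0.0, 1.0),                 # exponential density at 0 = rate
        (2.0, 1.0, 1.0, np.exp(-1.0)),        # mode of gamma(2,1) at t=(a-1)/b
    ])
    def test_pointwise_values(self, shape, rate, t, expected):
        assert rt.gamma_density(rt.GammaRT(shape, rate), t) == pytest.approx(expected)

    def test_moments(self, gamma_10_10):
        assert gamma_10_10.mean == pytest.approx(1.0)
        assert gamma_10_10.cv == pytest.approx(1.0 / np.sqrt(10.0))

    def test_mode_location(self):
        law = rt.GammaRT(2.0, 1.0)
        t = np.linspace(0, 10, 5001)
        assert t[np.argmax(law.pdf(t))] == pytest.approx(1.0, abs=1e-2)

    @pytest.mark.parametrize("shape,rate", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (2.0, -3.0)])
    def test_invalid_parameters(self, shape, rate):
        with pytest.raises(ValueError):
            rt.GammaRT(shape, rate)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rt.gamma_density(rt.GammaRT(2.0, 1.0), -0.5)

    @pytest.mark.parametrize("shape,rate", [(1.0, 1.0), (6.25, 0.9921), (20.0, 4.0)])
    def test_density_normalized(self, shape, rate):
        law = rt.GammaRT(shape, rate)
        t = np.linspace(0, law.mean + 30 * law.sd, 200001)
        assert np.trapezoid(law.pdf(t), t) == pytest.approx(1.0, abs=1e-5)

    def test_density_normalized_subunit_shape(self):
        # integrable singularity at the origin for shape < 1
        from scipy.integrate import quad

        law = rt.GammaRT(0.5, 2.0)
        total, _ = quad(law.pdf, 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)


class TestGammaFromMoments:
    @pytest.mark.parametrize("mean,cv,shape,rate", [
        (6.3, 0.4, 6.25, 0.992063),    # IL-2 secretion onset summary
        (1.0, 1.0, 1.0, 1.0),          # CV 1 is the exponential case
        (3.6, 0.5, 4.0, 1.111111),     # TNF-alpha secretion onset summary
    ])
    def test_summary_conversion(self, mean, cv, shape, rate):
        law = rt.gamma_from_moments(mean, cv)
        assert law.shape == pytest.approx(shape, rel=1e-6)
        assert law.rate == pytest.approx(rate, rel=1e-4)

    @given(mean=st.floats(0.01, 100.0), cv=st.floats(0.05, 3.0))
    @settings(max_examples=50, derandomize=True)
    def test_moment_round_trip(self, mean, cv):
        law = rt.gamma_from_moments(mean, cv)
        assert law.mean == pytest.approx(mean, rel=1e-9)
        assert law.cv == pytest.approx(cv, rel=1e-9)

    @pytest.mark.parametrize("mean,cv", [(0.0, 0.5), (-1.0, 0.5), (1.0, 0.0), (1.0, -0.2)])
    def test_invalid_inputs(self, mean, cv):
        with pytest.raises(ValueError):
            rt.gamma_from_moments(mean, cv)


class TestHazard:
    def test_exponential_memoryless(self):
        law = rt.GammaRT(1.0, 2.5)
        for tau in (0.0, 0.3, 5.0):
            assert rt.hazard(law, tau) == pytest.approx(2.5)

    def test_zero_at_origin_for_multistep(self):
        assert rt.hazard(rt.GammaRT(2.0, 1.0), 0.0) == pytest.approx(0.0)

    def test_asymptote_is_rate(self):
        # gamma hazard tends to the rate parameter for large waiting times
        assert rt.hazard(rt.GammaRT(2.0, 1.0), 50.0) == pytest.approx(1.0, rel=0.03)

    def test_exhausted_support_signaled(self):
        with pytest.raises(ExhaustedSupportError):
            rt.hazard(rt.GammaRT(1.0, 1.0), 1e4)

    @given(shape=st.floats(0.5, 30.0), rate=st.floats(0.1, 10.0))
    @settings(max_examples=30, derandomize=True)
    def test_hazard_survival_consistency(self, shape, rate):
        # phi(t) * hazard(t) == psi(t) wherever the survival is not tiny
        law = rt.GammaRT(shape, rate)
        t = np.linspace(0, law.mean + 4 * law.sd, 200)[1:]  # hazard diverges at 0 for shape < 1
        phi = law.sf(t)
        mask = phi > 1e-12
        np.testing.assert_allclose(phi[mask] * law.hazard(t[mask]),
                                   law.pdf(t)[mask], atol=1e-9, rtol=1e-7)


class TestConvolutionIdentity:
    def test_single_step_is_exponential(self):
        law = rt.convolve_uniform_chain(1, 3.0)
        assert law.shape == 1.0 and law.rate == 3.0

    def test_two_step_closed_form(self):
        # density mu^2 t e^(-mu t), peaking at t = 1/mu
        law = rt.convolve_uniform_chain(2, 1.0)
        t = np.linspace(0, 10, 2001)
        np.testing.assert_allclose(law.pdf(t), t * np.exp(-t), atol=1e-12)

    @pytest.mark.parametrize("n,dt,T", [(10, 1e-4, 4.0), (20, 5e-5, 6.0)])
    def test_numeric_convolution_oracle(self, n, dt, T):
        # independent oracle: iterated trapezoid-corrected numerical
        # convolution of n exponential densities
        mu = 10.0
        t = np.arange(0, T, dt)
        f = mu * np.exp(-mu * t)
        acc = f.copy()
        for _ in range(n - 1):
            full = fftconvolve(acc, f)[: t.size] * dt
            full -= 0.5 * dt * (acc[0] * f + f[0] * acc)
            acc = full
        law = rt.convolve_uniform_chain(n, mu)
        assert np.max(np.abs(acc - law.pdf(t))) < 1e-6

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            rt.convolve_uniform_chain(0, 1.0)


class TestEmpiricalRT:
    def test_normalization_flag_enforced(self):
        t = np.linspace(0, 5, 100)
        with pytest.raises(ValueError, match="integrates"):
            EmpiricalRT(t, np.full_like(t, 3.0), is_normalized=True)

    def test_requires_increasing_grid(self):
        with pytest.raises(ValueError):
            EmpiricalRT(np.array([0.0, 1.0, 1.0]), np.ones(3), is_normalized=False)

    def test_csv_round_trip(self, tmp_path, gamma_10_10):
        grid = gamma_10_10.default_grid(500)
        emp = EmpiricalRT(grid, gamma_10_10.pdf(grid), is_normalized=False).normalized()
        path = tmp_path / "curve.csv"
        emp.to_csv(path)
        back = EmpiricalRT.from_csv(path)
        np.testing.assert_allclose(back.density, emp.density, rtol=1e-6)

    def test_json_round_trip(self, tmp_path):
        law = rt.GammaRT(6.25, 0.9921)
        path = tmp_path / "law.json"
        law.to_json(path)
        back = rt.GammaRT.from_json(path)
        assert back == law

    def test_exponential_serialization_family(self):
        rec = rt.GammaRT(1.0, 2.0).to_record()
        assert rec["family"] == "exponential"
        assert rt.GammaRT.from_record(rec).rate == 2.0


class TestFitting:
    def test_self_fit_recovers_parameters(self):
        law = rt.gamma_from_moments(6.3, 0.4)
        grid = law.default_grid(800)
        emp = EmpiricalRT(grid, law.pdf(grid), is_normalized=False).normalized()
        fit = rt.fit_gamma(emp)
        assert fit.fitted.shape == pytest.approx(law.shape, rel=0.01)
        assert fit.rmse < 1e-6

    def test_bimodal_mixture_fits_worse_than_components(self):
        a, b = rt.GammaRT(20.0, 4.0), rt.GammaRT(20.0, 1.0)
        grid = np.linspace(0, 40, 1500)
        mix = EmpiricalRT(grid, 0.5 * a.pdf(grid) + 0.5 * b.pdf(grid),
                          is_normalized=False).normalized()
        mix_rmse = rt.fit_gamma(mix).rmse
        for law in (a, b):
            solo = EmpiricalRT(grid, law.pdf(grid), is_normalized=False).normalized()
            assert mix_rmse > rt.fit_gamma(solo).rmse

    def test_monte_carlo_parameter_recovery(self, rng):
        samples = rt.GammaRT(10.0, 10.0).rvs(20000, rng)
        fit = fit_gamma_to_samples(samples)
        assert fit.fitted.shape == pytest.approx(10.0, rel=0.10)
        assert fit.fitted.rate == pytest.approx(10.0, rel=0.10)

    def test_exponential_fit_fixes_shape(self, rng):
        law = rt.GammaRT(1.0, 0.5)
        grid = law.default_grid(600)
        emp = EmpiricalRT(grid, law.pdf(grid), is_normalized=False).normalized()
        fit = rt.fit_exponential(emp)
        assert fit.fitted.shape == 1.0
        assert fit.fitted.rate == pytest.approx(0.5, rel=1e-3)

    def test_rejects_unnormalized_and_degenerate(self):
        t = np.linspace(0, 5, 50)
        with pytest.raises(ValueError):
            rt.fit_gamma(EmpiricalRT(t, np.exp(-t), is_normalized=False))
        with pytest.raises(ValueError):
            rt.fit_gamma(EmpiricalRT(t, np.zeros_like(t), is_normalized=False))
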