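"""Master-equation motif models: first-passage densities, the gamma closed
form for the irreversible chain, and log-normal cell-to-cell heterogeneity."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest, ks_2samp, lognorm

import rtnet as rt
from rtnet.intracellular import (
    ChainModel,
    HeterogeneitySpec,
    heterogeneous_rt,
    lognormal_from_mean_cv,
    parallel_chain_rt,
    shape_vs_complexity_scan,
    solve_model_rt,
)
from rtnet.metrics import bimodality_score


class TestChainFlux:
    @pytest.mark.parametrize("n", [1, 5, 10, 20])
    def test_irreversible_chain_matches_gamma(self, n):
        # ODE flux into the absorbing state == closed-form gamma(n, n*lambda)
        law = rt.GammaRT(float(n), float(n))
        extent = law.mean + (30 if n == 1 else 10) * law.sd  # exp tail is heavy
        grid = np.linspace(0, extent, 20000 if n == 1 else 2000)
        emp = solve_model_rt(ChainModel(n_steps=n, base_rate=1.0), grid)
        assert np.max(np.abs(emp.density - law.pdf(grid))) < 1e-6

    def test_mean_preserved_across_chain_length(self):
        # the n-step chain is mean-matched to the single step with rate lambda
        for n in (1, 4, 16):
            law = ChainModel(n_steps=n, base_rate=2.0).closed_form()
            assert law.mean == pytest.approx(0.5)

    def test_response_cv_decreases_with_steps(self):
        cvs = [ChainModel(n_steps=n, base_rate=1.0).closed_form().cv
               for n in (1, 2, 5, 10, 20)]
        assert all(a > b for a, b in zip(cvs, cvs[1:]))
        assert cvs[-1] == pytest.approx(1.0 / np.sqrt(20.0))

    def test_short_grid_raises(self):
        with pytest.raises(ValueError, match="probability mass"):
            solve_model_rt(ChainModel(n_steps=10, base_rate=1.0),
                           np.linspace(0, 0.5, 200))

    def test_crosstalk_shortcut_induces_bimodality(self):
        grid = np.linspace(0, 3, 2000)
        crosstalk = solve_model_rt(
            ChainModel(n_steps=10, base_rate=1.0, variant="crosstalk",
                       shortcut_index=1, shortcut_rate=1.0),
            grid, mass_tolerance=5e-2)
        plain = solve_model_rt(ChainModel(n_steps=10, base_rate=1.0), grid)
        assert bimodality_score(crosstalk) > 10 * bimodality_score(plain)

    @pytest.mark.parametrize("variant,kwargs", [
        ("reversible", {"backward_rate": 2.0}),
        ("cascade", {}),
    ])
    def test_numeric_variants_yield_normalized_density(self, variant, kwargs):
        model = ChainModel(n_steps=5, base_rate=1.0, variant=variant, **kwargs)
        ref = rt.GammaRT(5.0, 5.0)
        grid = np.linspace(0, 60 * ref.mean, 4000)
        emp = solve_model_rt(model, grid, mass_tolerance=5e-2)
        assert emp.total_mass == pytest.approx(1.0, abs=1e-6)
        assert np.all(emp.density >= 0)


class TestParallelChain:
    def test_single_molecule_reduces_to_chain(self):
        grid = np.linspace(0, 3, 1000)
        one = parallel_chain_rt(10, 1, 10.0, grid)
        law = rt.GammaRT(10.0, 10.0)
        np.testing.assert_allclose(one.density, law.pdf(grid) /
                                   np.trapezoid(law.pdf(grid), grid), atol=1e-9)

    def test_two_single_steps_race_is_double_rate_exponential(self):
        grid = np.linspace(0, 5, 2000)
        emp = parallel_chain_rt(1, 2, 1.0, grid)
        ref = rt.GammaRT(1.0, 2.0)
        np.testing.assert_allclose(
            emp.density, ref.pdf(grid) / np.trapezoid(ref.pdf(grid), grid),
            atol=1e-6)

    def test_first_order_statistic_accelerates(self):
        grid = np.linspace(0, 3, 2000)
        mean_1 = parallel_chain_rt(10, 1, 10.0, grid).mean()
        mean_5 = parallel_chain_rt(10, 5, 10.0, grid).mean()
        assert mean_5 < mean_1

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            parallel_chain_rt(10, 0, 1.0, np.linspace(0, 3, 100))


class TestLognormal:
    def test_degenerate_cv_zero(self):
        mu, sigma = lognormal_from_mean_cv(1.0, 0.0)
        assert sigma == 0.0 and np.exp(mu) == pytest.approx(1.0)

    def test_unit_cv_closed_form(self):
        _, sigma = lognormal_from_mean_cv(1.0, 1.0)
        assert sigma**2 == pytest.approx(np.log(2.0))

    def test_sample_moments_recovered(self, rng):
        mu, sigma = lognormal_from_mean_cv(1.0, 0.5)
        draws = rng.lognormal(mu, sigma, size=100_000)
        assert draws.mean() == pytest.approx(1.0, rel=0.02)
        assert draws.std() / draws.mean() == pytest.approx(0.5, rel=0.02)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            lognormal_from_mean_cv(1.0, -0.1)


class TestHeterogeneity:
    def test_homogeneous_limit_matches_closed_form(self):
        samples = heterogeneous_rt(ChainModel(10, 1.0),
                                   HeterogeneitySpec(cv=0.0, n_cells=20000, seed=1))
        assert kstest(samples, rt.GammaRT(10.0, 10.0).cdf).statistic < 0.02

    @pytest.mark.parametrize("cv", [0.25, 0.5, 1.0, 2.0])
    def test_heterogeneous_single_step_is_monotone(self, cv):
        # a heterogeneous single-step process can never develop a peak:
        # bin counts must be nonincreasing up to binomial noise
        samples = heterogeneous_rt(ChainModel(1, 1.0, variant="single"),
                                   HeterogeneitySpec(cv=cv, n_cells=20000, seed=2))
        counts, _ = np.histogram(samples, bins=40,
                                 range=(0, np.quantile(samples, 0.99)))
        for j in range(len(counts) - 1):
            noise = 3.0 * np.sqrt(counts[j] + counts[j + 1] + 1)
            assert counts[j + 1] <= counts[j] + noise

    def test_single_step_marginal_matches_quadrature(self):
        # marginal density integral lambda e^(-lambda t) g(lambda) dlambda
        samples = heterogeneous_rt(ChainModel(1, 1.0, variant="single"),
                                   HeterogeneitySpec(cv=0.5, n_cells=50000, seed=3))
        mu, sigma = lognormal_from_mean_cv(1.0, 0.5)

        def marginal_cdf(t):
            return quad(lambda lam: (1 - np.exp(-lam * t))
                        * lognorm.pdf(lam, sigma, scale=np.exp(mu)),
                        0, np.inf)[0]

        for t in (0.5, 1.0, 2.0):
            assert (samples <= t).mean() == pytest.approx(marginal_cdf(t), abs=0.01)

    def test_ssa_path_equivalent_to_closed_form(self):
        het = HeterogeneitySpec(cv=0.5, n_cells=20000, seed=4)
        closed = heterogeneous_rt(ChainModel(5, 1.0), het)
        ssa = heterogeneous_rt(ChainModel(5, 1.0),
                               HeterogeneitySpec(cv=0.5, n_cells=20000, seed=5),
                               method="ssa")
        assert ks_2samp(closed, ssa).statistic < 0.02

    def test_reversible_ssa_matches_master_equation(self):
        model = ChainModel(4, 1.0, variant="reversible", backward_rate=1.0)
        samples = heterogeneous_rt(model, HeterogeneitySpec(cv=0.0, n_cells=5000, seed=6),
                                   method="ssa")
        grid = np.linspace(0, np.quantile(samples, 0.999) * 2, 4000)
        emp = solve_model_rt(model, grid, mass_tolerance=5e-2)
        cdf_grid = emp.cdf_values()
        ks = np.max(np.abs(np.interp(np.sort(samples), grid, cdf_grid)
                           - np.arange(1, samples.size + 1) / samples.size))
        assert ks < 0.03


class TestShapeScan:
    def test_homogeneous_chain_recovers_exact_shape(self):
        tab = shape_vs_complexity_scan("irreversible", [5], [0.0])
        assert tab["alpha"].iloc[0] == pytest.approx(5.0, abs=0.01)

    def test_fitted_shape_nonincreasing_in_heterogeneity(self):
        # heterogeneity lengthens tails and advances peaks: fitted alpha drops
        tab = shape_vs_complexity_scan("irreversible", [10], [0.0, 0.5, 1.0],
                                       n_cells=20000, seed=7)
        alphas = tab.sort_values("cv")["alpha"].to_numpy()
        assert all(a >= b for a, b in zip(alphas, alphas[1:]))

    @pytest.mark.parametrize("cv", [0.5, 1.0])
    def test_single_step_shape_bounded_by_one(self, cv):
        # monotone densities cannot support a fitted shape above 1
        tab = shape_vs_complexity_scan("single", [1], [cv],
                                       n_cells=20000, seed=8)
        assert tab["alpha"].iloc[0] <= 1.0 + 0.05
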