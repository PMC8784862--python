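"""Distribution estimation: parametric fits, discretization, non-parametric
adjustment, and denoiser aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ideas import (
    CellDistributionTable,
    IndividualDistribution,
    adjust_log_counts,
    aggregate_cell_distributions,
    discretize,
    fit_nb_individual,
    fit_zinb_individual,
    kde_density,
    sample_from_cell_distributions,
)
from ideas.distribution import choose_support


def _nb_draws(rng, mu, theta, size):
    return rng.negative_binomial(theta, theta / (theta + mu), size=size)


def _depth_design(rng, n, base_mu, theta=None, pi=0.0, slope=1.0):
    """Counts whose mean scales with read depth; returns (counts, covars, truth mu)."""
    logrd = rng.normal(9.0, 0.3, n)
    ref = np.median(logrd)
    mu_cell = base_mu * np.exp(slope * (logrd - ref))
    if theta is None:
        y = rng.poisson(mu_cell)
    else:
        y = _nb_draws(rng, mu_cell, theta, n)
    if pi > 0:
        y = np.where(rng.random(n) < pi, 0, y)
    return y, logrd.reshape(-1, 1), np.array([ref])


class TestNBFit:
    def test_recovers_conditional_mean_and_dispersion(self):
        rng = np.random.default_rng(0)
        y, covars, ref = _depth_design(rng, 2000, base_mu=5.0, theta=2.0)
        fit = fit_nb_individual(y, covars, ref)
        assert fit.status == "ok"
        assert abs(fit.mu - 5.0) / 5.0 < 0.05
        assert abs(fit.theta - 2.0) / 2.0 < 0.20
        assert fit.pi == 0.0

    def test_poisson_data_gives_near_poisson_fit(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(3.0, 2000)
        fit = fit_nb_individual(y)
        assert fit.status in ("ok", "fallback_poisson")
        assert abs(fit.mu - 3.0) / 3.0 < 0.05
        # variance/mean of the fitted NB law is 1 + mu/theta
        vm_ratio = 1.0 + (0.0 if np.isinf(fit.theta) else fit.mu / fit.theta)
        assert vm_ratio <= 1.1

    def test_all_zero_counts_fail(self):
        fit = fit_nb_individual(np.zeros(100, dtype=int))
        assert fit.status == "failed"
        assert fit.mu is None

    def test_too_few_cells_fail(self):
        fit = fit_nb_individual(np.array([1, 2, 3]), min_cells=10)
        assert fit.status == "failed"

    def test_conditioning_consistency_under_depth_doubling(self):
        # doubling every read depth while keeping the per-depth law fixed
        # leaves the conditional fit at the (new) median unchanged
        rng = np.random.default_rng(7)
        logrd = rng.normal(9.0, 0.3, 4000)
        mu_cell = 4.0 * np.exp(logrd - 9.0)
        y = _nb_draws(rng, mu_cell, 2.0, 4000)
        fit1 = fit_nb_individual(y, logrd.reshape(-1, 1), np.array([np.median(logrd)]))
        logrd2 = logrd + np.log(2)
        mu_cell2 = 4.0 * np.exp(logrd2 - 9.0)
        y2 = _nb_draws(np.random.default_rng(8), mu_cell2, 2.0, 4000)
        fit2 = fit_nb_individual(y2, logrd2.reshape(-1, 1), np.array([np.median(logrd2)]))
        # conditional mean at median depth doubles with the depth; dividing it
        # back recovers the original conditional law up to sampling error
        assert abs(fit2.mu / 2.0 - fit1.mu) / fit1.mu < 0.08


class TestZINBFit:
    def test_recovers_zero_inflation(self):
        rng = np.random.default_rng(2)
        y, covars, ref = _depth_design(rng, 5000, base_mu=5.0, theta=2.0, pi=0.3)
        fit = fit_zinb_individual(y, covars, ref)
        assert fit.status == "ok"
        assert abs(fit.pi - 0.3) <= 0.05

    def test_pure_nb_data_falls_back_or_collapses(self):
        rng = np.random.default_rng(3)
        y = _nb_draws(rng, 5.0, 2.0, 5000)
        fit = fit_zinb_individual(y)
        assert fit.ok
        assert fit.status == "fallback_nb" or fit.pi < 0.02

    def test_constant_positive_counts_fail(self):
        fit = fit_zinb_individual(np.full(100, 4))
        assert fit.status == "failed"


class TestDiscretize:
    def test_poisson_pmf_at_zero(self):
        d = IndividualDistribution(kind="parametric", pi=0.0, mu=1.0, theta=np.inf)
        disc = discretize(d, 50)
        np.testing.assert_allclose(disc.pmf[0], np.exp(-1.0), rtol=1e-12)

    def test_degenerate_pi_rejected(self):
        with pytest.raises(ValueError, match="pi"):
            IndividualDistribution(kind="parametric", pi=1.0, mu=2.0, theta=1.0)

    def test_mass_and_mean_against_direct_summation(self):
        d = IndividualDistribution(kind="parametric", pi=0.0, mu=2.0, theta=1.0)
        disc = discretize(d, 200)
        assert abs(disc.pmf.sum() - 1.0) < 1e-12
        mean = (np.arange(201) * disc.pmf).sum()
        assert abs(mean - 2.0) < 1e-6

    def test_small_support_warns_about_tail(self):
        d = IndividualDistribution(kind="parametric", pi=0.0, mu=50.0, theta=2.0)
        with pytest.warns(UserWarning, match="tail"):
            discretize(d, 5)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_parametric_density_is_proper(self, seed):
        rng = np.random.default_rng(seed)
        d = IndividualDistribution(
            kind="parametric",
            pi=rng.uniform(0, 0.6),
            mu=rng.uniform(0.2, 20),
            theta=rng.uniform(0.3, 10),
        )
        disc = discretize(d, choose_support([d]))
        assert np.all(disc.pmf >= 0)
        assert abs(disc.pmf.sum() - 1.0) < 1e-10


class TestAdjustedLogCounts:
    def test_constant_covariate_is_noop(self):
        y = np.array([0, 1, 2, 3, 4, 5, 6, 7])
        out = adjust_log_counts(y, np.full((8, 1), 2.0))
        np.testing.assert_allclose(out.sample, np.log1p(y), atol=1e-10)

    def test_perfect_linear_fit_leaves_zero_residuals(self):
        logrd = np.linspace(8, 10, 20)
        ylog = 1.0 * logrd - 3.0
        counts = np.exp(ylog) - 1.0
        out = adjust_log_counts(counts, logrd.reshape(-1, 1))
        np.testing.assert_allclose(out.sample, out.sample[0], atol=1e-8)
        np.testing.assert_allclose(out.sample[0], np.median(logrd) - 3.0, atol=1e-8)

    def test_adjusted_variance_matches_noise_variance(self):
        rng = np.random.default_rng(4)
        logrd = rng.normal(9, 0.5, 5000)
        noise = rng.normal(0, 0.3, 5000)
        counts = np.exp(2.0 * logrd + noise) - 1.0
        out = adjust_log_counts(counts, logrd.reshape(-1, 1))
        assert abs(np.var(out.sample) - 0.09) / 0.09 < 0.10

    def test_too_few_cells_fail(self):
        out = adjust_log_counts(np.array([1.0, 2.0]), np.ones((2, 1)))
        assert out.status == "failed"


class TestKDE:
    def test_normal_density_at_mode(self):
        rng = np.random.default_rng(5)
        sample = IndividualDistribution(
            kind="empirical_sample", sample=rng.normal(0, 1, 5000)
        )
        grid = np.linspace(-5, 5, 1024)
        dens = kde_density(sample, grid)
        at0 = dens.density[np.argmin(np.abs(grid))]
        assert abs(at0 - stats.norm.pdf(0)) / stats.norm.pdf(0) < 0.10

    def test_integrates_to_one(self):
        rng = np.random.default_rng(6)
        sample = IndividualDistribution(
            kind="empirical_sample", sample=rng.exponential(2.0, 300)
        )
        grid = np.linspace(-5, 30, 2048)
        dens = kde_density(sample, grid)
        assert abs(np.trapezoid(dens.density, grid) - 1.0) < 1e-6

    def test_degenerate_sample_fails(self):
        sample = IndividualDistribution(kind="empirical_sample", sample=np.full(50, 1.3))
        assert kde_density(sample, np.linspace(0, 3, 64)).status == "failed"


def _table(rows):
    return CellDistributionTable(pd.DataFrame(rows))


class TestCellDistributionAggregation:
    def test_poisson_mixture_mean(self):
        tab = _table(
            [
                {"gene": "g", "cell": "c1", "lambda": 1.0},
                {"gene": "g", "cell": "c2", "lambda": 3.0},
            ]
        )
        agg = aggregate_cell_distributions(tab, "g", ["c1", "c2"], K=60)
        mean = (np.arange(61) * agg.pmf).sum()
        np.testing.assert_allclose(mean, 2.0, atol=1e-8)

    def test_identical_cells_equal_single_discretization(self):
        rows = [
            {"gene": "g", "cell": f"c{i}", "mu": 4.0, "theta": 2.0, "pi": 0.2}
            for i in range(3)
        ]
        agg = aggregate_cell_distributions(_table(rows), "g", ["c0", "c1", "c2"], K=80)
        single = discretize(
            IndividualDistribution(kind="parametric", pi=0.2, mu=4.0, theta=2.0), 80
        )
        np.testing.assert_allclose(agg.pmf, single.pmf, atol=1e-12)

    def test_average_of_poisson_pmfs_oracle(self):
        lams = [1.0, 2.0, 3.0, 4.0, 5.0]
        rows = [
            {"gene": "g", "cell": f"c{i}", "lambda": lam} for i, lam in enumerate(lams)
        ]
        agg = aggregate_cell_distributions(
            _table(rows), "g", [f"c{i}" for i in range(5)], K=100
        )
        y = np.arange(100)
        expected = np.mean([stats.poisson.pmf(y, lam) for lam in lams], axis=0)
        np.testing.assert_allclose(agg.pmf[:100], expected, atol=1e-12)

    def test_cell_order_invariance(self):
        rows = [
            {"gene": "g", "cell": f"c{i}", "lambda": lam}
            for i, lam in enumerate([1.0, 5.0, 2.5])
        ]
        a = aggregate_cell_distributions(_table(rows), "g", ["c0", "c1", "c2"], K=60)
        b = aggregate_cell_distributions(_table(rows), "g", ["c2", "c0", "c1"], K=60)
        np.testing.assert_allclose(a.pmf, b.pmf, atol=1e-15)

    def test_missing_cells_listed(self):
        tab = _table([{"gene": "g", "cell": "c1", "lambda": 1.0}])
        with pytest.raises(KeyError, match="c9"):
            aggregate_cell_distributions(tab, "g", ["c1", "c9"], K=10)


class TestCellDistributionSampling:
    def test_output_length_m_per_cell(self):
        rows = [{"gene": "g", "cell": f"c{i}", "lambda": 2.0} for i in range(10)]
        draws = sample_from_cell_distributions(
            _table(rows), "g", [f"c{i}" for i in range(10)], m=5, rng=0
        )
        assert draws.shape == (50,)

    def test_empirical_mean_matches_analytic_zinb_mean(self):
        rows = [{"gene": "g", "cell": "c1", "mu": 6.0, "theta": 2.0, "pi": 0.25}]
        draws = sample_from_cell_distributions(_table(rows), "g", ["c1"], m=100_000, rng=1)
        expected = (1 - 0.25) * 6.0
        assert abs(draws.mean() - expected) / expected < 0.01

    def test_deterministic_given_seed(self):
        rows = [{"gene": "g", "cell": "c1", "mu": 3.0, "theta": 1.0, "pi": 0.1}]
        a = sample_from_cell_distributions(_table(rows), "g", ["c1"], m=100, rng=42)
        b = sample_from_cell_distributions(_table(rows), "g", ["c1"], m=100, rng=42)
        np.testing.assert_array_equal(a, b)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="out-of-range"):
            _table([{"gene": "g", "cell": "c1", "mu": -1.0, "theta": 1.0, "pi": 0.0}])
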