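import math

import numpy as np
import pytest
import scipy.stats

from hegbayes import (
    ConfigurationError,
    DegenerateTruncationError,
    InformativePrior,
    MCMCConfig,
    P95Constraint,
    UniformPrior,
    gibbs_sample,
    stats_from_table,
    truncated_invgamma_draw,
    truncated_normal_draw,
)
from hegbayes.constants import Z95

from oracles import grid_mu_posterior_cdf, ks_distance_to_grid


class TestTruncatedDraws:
    def test_untruncated_normal_mean(self, rng):
        x = truncated_normal_draw(
            np.zeros(100_000), 1.0, -np.inf, np.inf, rng
        )
        assert abs(x.mean()) < 0.02

    def test_half_normal_mean(self, rng):
        x = truncated_normal_draw(np.zeros(100_000), 1.0, 0.0, np.inf, rng)
        assert x.mean() == pytest.approx(math.sqrt(2 / math.pi), abs=0.01)
        assert x.min() >= 0.0

    def test_far_tail_draws_stay_in_interval(self, rng):
        x = truncated_normal_draw(np.zeros(1_000), 1.0, 8.0, 9.0, rng)
        assert np.all((x >= 8.0) & (x <= 9.0))
        assert np.all(np.isfinite(x))

    def test_degenerate_interval_mass_rejected(self, rng):
        with pytest.raises(DegenerateTruncationError):
            truncated_normal_draw(0.0, 1.0, 39.0, 40.0, rng)

    def test_empty_interval_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            truncated_normal_draw(0.0, 1.0, 1.0, 0.0, rng)

    def test_invgamma_untruncated_mean(self, rng):
        x = truncated_invgamma_draw(3.0, 2.0 * np.ones(100_000), 0.0, np.inf, rng)
        assert x.mean() == pytest.approx(2.0 / (3.0 - 1.0), abs=0.02)

    def test_invgamma_respects_bounds(self, rng):
        x = truncated_invgamma_draw(3.0, 2.0 * np.ones(5_000), 0.5, 1.5, rng)
        assert np.all((x >= 0.5) & (x <= 1.5))

    def test_invgamma_matches_scipy_quantiles(self, rng):
        x = truncated_invgamma_draw(4.0, 3.0 * np.ones(100_000), 0.0, np.inf, rng)
        ref = scipy.stats.invgamma(4.0, scale=3.0)
        for q in (0.1, 0.5, 0.9):
            assert np.quantile(x, q) == pytest.approx(ref.ppf(q), rel=0.02)


class TestGibbsSampler:
    def test_posterior_concentrates_on_truth_for_large_n(self):
        stats = stats_from_table(10_000, 2.0, 2.0)
        draws = gibbs_sample(
            stats,
            UniformPrior(),
            config=MCMCConfig(n_iter=3_000, n_warmup=500, n_chains=2, seed=42),
        )
        assert np.median(draws.pooled("gm")) == pytest.approx(2.0, rel=0.02)
        assert np.median(draws.pooled("gsd")) == pytest.approx(2.0, rel=0.02)

    def test_median_gm_tracks_sample_gm(self):
        stats = stats_from_table(60, 0.9, 2.8)
        draws = gibbs_sample(
            stats,
            UniformPrior(),
            config=MCMCConfig(n_iter=4_000, n_warmup=500, n_chains=2, seed=7),
        )
        assert np.median(draws.pooled("gm")) == pytest.approx(0.9, rel=0.03)

    def test_all_draws_respect_tight_bounds(self):
        prior = UniformPrior(
            mu_lower=math.log(1.2),
            mu_upper=math.log(1.8),
            sigma_lower=math.log(1.5),
            sigma_upper=math.log(2.2),
        )
        stats = stats_from_table(50, 2.0, 2.0)
        draws = gibbs_sample(
            stats, prior, config=MCMCConfig(n_iter=2_000, n_warmup=200, n_chains=2, seed=3)
        )
        assert draws.mu.min() >= prior.mu_lower and draws.mu.max() <= prior.mu_upper
        assert (
            draws.sigma.min() >= prior.sigma_lower
            and draws.sigma.max() <= prior.sigma_upper
        )
        # binding bounds are visible in the truncated-mass report
        assert draws.truncated_mass["mu"] > 0.01

    def test_p95_constraint_holds_for_every_draw(self):
        stats = stats_from_table(14, 1.52, 2.55)
        constraint = P95Constraint(enabled=True, multiplier=2.0, oel=2.0)
        draws = gibbs_sample(
            stats,
            UniformPrior(),
            constraint,
            MCMCConfig(n_iter=3_000, n_warmup=500, n_chains=2, seed=9),
        )
        assert np.all(draws.pooled("p95") < 4.0)

    def test_empty_constraint_region_is_a_config_error(self):
        stats = stats_from_table(14, 1.52, 2.55)
        constraint = P95Constraint(enabled=True, multiplier=1e-5, oel=2.0)
        with pytest.raises(ConfigurationError):
            gibbs_sample(stats, UniformPrior(), constraint, MCMCConfig(seed=0))

    def test_marginal_matches_grid_integration_oracle(self):
        """Gibbs marginal of mu vs a dense-grid brute-force posterior (KS)."""
        stats = stats_from_table(10, 1.5, 2.2)
        s2y0 = math.log(2.0) ** 2
        prior = InformativePrior(
            m0=math.log(1.2),
            v0=s2y0 / 5,
            a0=2.0,
            b0=2.0 * s2y0,
            n0=5,
            mu_lower=-40.0,
            mu_upper=40.0,
            sigma2_lower=1e-8,
            sigma2_upper=1e4,
        )
        draws = gibbs_sample(
            stats,
            prior,
            config=MCMCConfig(n_iter=10_000, n_warmup=1_000, n_chains=2, seed=11),
        )
        mu_grid, cdf = grid_mu_posterior_cdf(stats, prior)
        assert ks_distance_to_grid(draws.pooled("mu"), mu_grid, cdf) < 0.02

    def test_flat_informative_matches_uniform_posterior(self):
        """An informative prior pushed to flatness agrees with the uniform prior."""
        stats = stats_from_table(200, 1.0, 2.5)
        flat = InformativePrior(
            m0=0.0,
            v0=1e6,
            a0=1e-3,
            b0=1e-3,
            n0=2,
            mu_lower=-40.0,
            mu_upper=40.0,
            sigma2_lower=1e-8,
            sigma2_upper=1e4,
        )
        wide_uniform = UniformPrior(
            mu_lower=-40.0, mu_upper=40.0, sigma_lower=1e-4, sigma_upper=100.0
        )
        cfg = dict(n_iter=10_000, n_warmup=1_000, n_chains=2)
        d1 = gibbs_sample(stats, flat, config=MCMCConfig(seed=21, **cfg))
        d2 = gibbs_sample(stats, wide_uniform, config=MCMCConfig(seed=22, **cfg))
        ks = scipy.stats.ks_2samp(d1.pooled("mu"), d2.pooled("mu")).statistic
        assert ks < 0.02

    def test_overdispersed_chains_converge(self):
        from hegbayes import gelman_rubin

        stats = stats_from_table(35, 0.62, 3.53)
        draws = gibbs_sample(
            stats,
            UniformPrior(),
            config=MCMCConfig(n_iter=2_000, n_warmup=500, n_chains=4, seed=5),
        )
        assert gelman_rubin(draws.mu) < 1.05
        assert gelman_rubin(draws.sigma) < 1.05
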