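"""Independent numerical oracles used by the test suite.

These deliberately avoid the sampler's code path: the posterior marginal of
mu is computed by dense-grid numerical integration of the unnormalized joint
density over (mu, sigma^2).
"""

import numpy as np


def grid_mu_posterior_cdf(stats, prior, n_mu=600, n_sig2=600):
    """CDF of the posterior marginal of mu on a dense grid, for an
    informative Normal x InverseGamma prior, by brute-force integration.

    Returns (mu_grid, cdf_values).
    """
    n, ybar, s2 = stats.n, stats.ybar, stats.s_y**2
    # grid wide enough to hold essentially all posterior mass
    post_sd = stats.s_y / np.sqrt(n) + np.sqrt(prior.v0)
    mu_grid = np.linspace(ybar - 8 * post_sd, ybar + 8 * post_sd, n_mu)
    sig2_center = ((n - 1) * s2 + 2 * prior.b0) / (n + 2 * prior.a0)
    sig2_grid = np.geomspace(sig2_center / 50, sig2_center * 50, n_sig2)

    mu = mu_grid[:, None]
    sig2 = sig2_grid[None, :]
    log_prior = (
        -0.5 * (mu - prior.m0) ** 2 / prior.v0
        - (prior.a0 + 1) * np.log(sig2)
        - prior.b0 / sig2
    )
    ss = (n - 1) * s2 + n * (ybar - mu) ** 2
    log_lik = -0.5 * n * np.log(sig2) - ss / (2 * sig2)
    lp = log_prior + log_lik
    joint = np.exp(lp - lp.max())
    marginal = np.trapezoid(joint, sig2_grid, axis=1)
    cdf = np.concatenate(
        [[0.0], np.cumsum((marginal[1:] + marginal[:-1]) / 2 * np.diff(mu_grid))]
    )
    return mu_grid, cdf / cdf[-1]


def ks_distance_to_grid(draws, mu_grid, cdf):
    """Kolmogorov-Smirnov distance between an empirical sample and a gridded CDF."""
    x = np.sort(np.ravel(draws))
    f = np.interp(x, mu_grid, cdf)
    n = len(x)
    upper = np.arange(1, n + 1) / n
    lower = np.arange(0, n) / n
    return float(max(np.max(np.abs(f - upper)), np.max(np.abs(f - lower))))
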