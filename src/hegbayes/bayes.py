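"""Lognormal exposure model: likelihood, priors, and a truncated Gibbs sampler.

Model
-----
Within one homogeneous exposure group (HEG), measured concentrations y_i are
lognormal: log y_i ~ Normal(mu, sigma^2).  The geometric mean is
GM = exp(mu), the geometric standard deviation GSD = exp(sigma), and the
exposure distribution's 95th percentile — the compliance criterion — is
P95 = exp(mu + z95 * sigma) with z95 = 1.6449.

Two prior regimes are supported:

* :class:`UniformPrior` — independent uniforms on mu and on sigma (the log-GSD
  scale), both truncated to finite bounds.  With a uniform prior on sigma the
  full conditional of sigma^2 is InverseGamma((n-1)/2, SS/2) where
  SS = (n-1) s_y^2 + n (ybar - mu)^2; a uniform-on-sigma^2 variant (conditional
  shape n/2 - 1) is available via ``parameterization="sigma2"``.
* :class:`InformativePrior` — elicited from a historical campaign with prior
  weight n0:  mu ~ Normal(m0, v0) with m0 the historical mean-log and
  v0 = s_y0^2 / n0, and sigma^2 ~ InverseGamma((n0-1)/2, (n0-1) s_y0^2 / 2),
  both truncated.  This is the standard chi-square construction:
  (n0-1) s_y0^2 / sigma^2 ~ chi^2_{n0-1}.

The Gibbs sampler alternates the two full conditionals, each drawn by exact
inverse-CDF sampling restricted to its truncation interval.  An optional
joint bound P95 < k * OEL further truncates both conditionals so that every
retained draw satisfies the bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.special import gammaincc, gammainccinv, ndtr, ndtri

from .constants import DEFAULT_OEL, Z95
from .errors import (
    ConfigurationError,
    DegenerateTruncationError,
    InsufficientDataError,
    ValidationError,
)
from .exposure_data import ExposureRecord, HEGStats, summarize_heg

#: Truncation intervals holding less mass than this are treated as empty.
MIN_TRUNCATION_MASS = 1e-300

# Default parameter-space bounds, wide enough to be non-binding for any
# plausible workplace dust series: GM between 0.001 and 100 mg/m3, GSD
# between 1.05 and 10.
DEFAULT_MU_LOWER = math.log(0.001)
DEFAULT_MU_UPPER = math.log(100.0)
DEFAULT_SIGMA_LOWER = math.log(1.05)
DEFAULT_SIGMA_UPPER = math.log(10.0)


@dataclass(frozen=True)
class UniformPrior:
    """Non-informative uniform prior on (mu, sigma), truncated to bounds."""

    mu_lower: float = DEFAULT_MU_LOWER
    mu_upper: float = DEFAULT_MU_UPPER
    sigma_lower: float = DEFAULT_SIGMA_LOWER
    sigma_upper: float = DEFAULT_SIGMA_UPPER
    parameterization: str = "sigma"  # "sigma" (flat on sigma) or "sigma2"

    def __post_init__(self) -> None:
        if not self.mu_lower < self.mu_upper:
            raise ConfigurationError(
                f"mu bounds empty: [{self.mu_lower}, {self.mu_upper}]"
            )
        if self.sigma_lower < 0:
            raise ConfigurationError(f"sigma_lower must be >= 0, got {self.sigma_lower}")
        if not self.sigma_lower < self.sigma_upper:
            raise ConfigurationError(
                f"sigma bounds empty: [{self.sigma_lower}, {self.sigma_upper}]"
            )
        if self.parameterization not in ("sigma", "sigma2"):
            raise ConfigurationError(
                f"parameterization must be 'sigma' or 'sigma2', "
                f"got {self.parameterization!r}"
            )


@dataclass(frozen=True)
class InformativePrior:
    """Truncated Normal x InverseGamma prior elicited from historical data.

    ``m0``/``v0`` are the mean and variance of the truncated-normal prior on
    mu; ``a0``/``b0`` the shape and scale of the truncated inverse-gamma
    prior on sigma^2; ``n0`` the prior sample size that produced them.
    """

    m0: float
    v0: float
    a0: float
    b0: float
    n0: int
    mu_lower: float = DEFAULT_MU_LOWER
    mu_upper: float = DEFAULT_MU_UPPER
    sigma2_lower: float = DEFAULT_SIGMA_LOWER**2
    sigma2_upper: float = DEFAULT_SIGMA_UPPER**2

    def __post_init__(self) -> None:
        if not self.v0 > 0:
            raise ValidationError(f"v0 must be positive, got {self.v0}")
        if not (self.a0 > 0 and self.b0 > 0):
            raise ValidationError(f"a0, b0 must be positive, got {self.a0}, {self.b0}")
        if not self.mu_lower < self.mu_upper:
            raise ConfigurationError(
                f"mu bounds empty: [{self.mu_lower}, {self.mu_upper}]"
            )
        if not 0 <= self.sigma2_lower < self.sigma2_upper:
            raise ConfigurationError(
                f"sigma2 bounds empty: [{self.sigma2_lower}, {self.sigma2_upper}]"
            )


Prior = Union[UniformPrior, InformativePrior]


@dataclass(frozen=True)
class P95Constraint:
    """Optional joint bound P95 < multiplier * oel on every retained draw."""

    enabled: bool = False
    multiplier: float = 2.0
    oel: float = DEFAULT_OEL

    def __post_init__(self) -> None:
        if not self.multiplier > 0:
            raise ValidationError(f"multiplier must be positive, got {self.multiplier}")
        if not self.oel > 0:
            raise ValidationError(f"oel must be positive, got {self.oel}")

    @property
    def log_cap(self) -> float:
        """Upper bound on log P95, i.e. ln(multiplier * oel)."""
        return math.log(self.multiplier * self.oel)


@dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = 20_000  # post-warmup draws per chain
    n_warmup: int = 2_000
    n_chains: int = 4
    seed: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.n_warmup < 0 or self.thin < 1:
            raise ConfigurationError("n_iter >= 1, n_warmup >= 0, thin >= 1 required")
        if self.n_chains < 2:
            raise ConfigurationError("n_chains must be >= 2 (required for R-hat)")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, one row per chain, plus derived quantities."""

    mu: np.ndarray  # (n_chains, n_draws), log mg/m3
    sigma: np.ndarray  # (n_chains, n_draws), log-scale SD
    truncated_mass: dict = field(default_factory=dict)
    config: MCMCConfig | None = None

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def gm(self) -> np.ndarray:
        return np.exp(self.mu)

    @property
    def gsd(self) -> np.ndarray:
        return np.exp(self.sigma)

    @property
    def p95(self) -> np.ndarray:
        return np.exp(self.mu + Z95 * self.sigma)

    def pooled(self, quantity: str) -> np.ndarray:
        """All chains concatenated, for 'mu', 'sigma', 'gm', 'gsd' or 'p95'."""
        return getattr(self, quantity).ravel()


def log_likelihood(stats: HEGStats, mu: float, sigma: float) -> float:
    """Lognormal log-likelihood of a HEG sample via its sufficient statistics.

    Full-constant convention: equals the sum of lognormal log-densities of
    the individual measurements, i.e. includes the -n*ybar Jacobian term and
    the -n/2 ln(2 pi) constant.
    """
    if not sigma > 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    n, ybar, s_y = stats.n, stats.ybar, stats.s_y
    ss = (n - 1) * s_y**2 + n * (ybar - mu) ** 2
    return -n * ybar - 0.5 * n * math.log(2 * math.pi) - n * math.log(sigma) - ss / (
        2 * sigma**2
    )


def elicit_informative_prior(
    past: Sequence[ExposureRecord] | HEGStats,
    n0: int = 5,
    seed: int | None = None,
    mode: str = "moments",
    *,
    p95_cap: float | None = None,
    mu_lower: float = DEFAULT_MU_LOWER,
    mu_upper: float | None = None,
    sigma2_lower: float = DEFAULT_SIGMA_LOWER**2,
    sigma2_upper: float = DEFAULT_SIGMA_UPPER**2,
) -> InformativePrior:
    """Build an informative prior from a historical campaign.

    ``moments`` mode uses the historical campaign's log-scale moments
    directly, downweighted to prior sample size ``n0``; ``subsample`` mode
    instead draws ``n0`` historical records without replacement (under
    ``seed``) and uses the subsample's moments, emulating elicitation from a
    small historical sample.  Either way:

        m0 = ybar0,  v0 = s_y0^2 / n0,
        a0 = (n0 - 1) / 2,  b0 = (n0 - 1) * s_y0^2 / 2.

    ``p95_cap`` (mg/m3), when given, sets the default mu upper bound to
    ln(p95_cap); otherwise a wide cap of ln(100) applies.
    """
    if n0 < 2:
        raise ValidationError(f"n0 must be >= 2, got {n0}")
    if mode not in ("moments", "subsample"):
        raise ValidationError(f"mode must be 'moments' or 'subsample', got {mode!r}")

    if mode == "subsample":
        if isinstance(past, HEGStats):
            raise ValidationError("subsample mode needs raw records, not HEGStats")
        records = list(past)
        if len(records) < n0:
            raise InsufficientDataError(
                f"need >= n0={n0} historical records, got {len(records)}"
            )
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(records), size=n0, replace=False)
        logs = np.log([records[i].concentration for i in idx])
        ybar0 = float(logs.mean())
        s2y0 = float(logs.var(ddof=1))
    else:
        stats = past if isinstance(past, HEGStats) else summarize_heg(list(past))
        ybar0 = stats.ybar
        s2y0 = stats.s_y**2

    if s2y0 <= 0:
        raise ValidationError(
            "historical log-variance is zero; the elicited prior would be degenerate"
        )
    if mu_upper is None:
        mu_upper = math.log(p95_cap) if p95_cap is not None else DEFAULT_MU_UPPER
    return InformativePrior(
        m0=ybar0,
        v0=s2y0 / n0,
        a0=(n0 - 1) / 2,
        b0=(n0 - 1) * s2y0 / 2,
        n0=n0,
        mu_lower=mu_lower,
        mu_upper=mu_upper,
        sigma2_lower=sigma2_lower,
        sigma2_upper=sigma2_upper,
    )


def _trunc_norm_core(rng, mean, sd, lower, upper):
    """Vectorized inverse-CDF truncated-normal draw; returns (draw, mass).

    The interval is reflected into the lower tail before evaluating the
    normal CDF, so the interval mass keeps full relative precision even far
    out in a tail (ndtr underflows gracefully to ~1e-308).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    a = (np.asarray(lower, dtype=float) - mean) / sd
    b = (np.asarray(upper, dtype=float) - mean) / sd
    flip = a > 0
    lo = np.where(flip, -b, a)
    hi = np.where(flip, -a, b)
    f_lo = ndtr(lo)
    f_hi = ndtr(hi)
    mass = f_hi - f_lo
    if np.any(mass < MIN_TRUNCATION_MASS):
        raise DegenerateTruncationError(
            "truncated-normal interval holds numerically zero mass"
        )
    u = rng.uniform(size=np.broadcast(mean, sd, a).shape)
    z = ndtri(f_lo + u * mass)
    z = np.where(flip, -z, z)
    return mean + sd * z, mass


def _trunc_invgamma_core(rng, shape, scale, lower, upper):
    """Vectorized inverse-CDF truncated inverse-gamma draw; returns (draw, mass).

    InverseGamma(shape, scale) CDF at x is gammaincc(shape, scale / x), so the
    quantile function is scale / gammainccinv(shape, p).
    """
    scale = np.asarray(scale, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    with np.errstate(over="ignore", divide="ignore"):
        f_lo = np.where(
            lower > 0, gammaincc(shape, scale / np.maximum(lower, 1e-320)), 0.0
        )
        f_hi = np.where(np.isfinite(upper), gammaincc(shape, scale / upper), 1.0)
    mass = f_hi - f_lo
    if np.any(mass < MIN_TRUNCATION_MASS):
        raise DegenerateTruncationError(
            "truncated inverse-gamma interval holds numerically zero mass"
        )
    u = rng.uniform(size=np.broadcast(scale, lower, upper).shape)
    p = f_lo + u * mass
    return scale / gammainccinv(shape, p), mass


def truncated_normal_draw(mean, sd, lower, upper, rng):
    """Exact inverse-CDF draw from Normal(mean, sd^2) restricted to [lower, upper]."""
    if np.any(np.asarray(sd) <= 0):
        raise ValidationError("sd must be positive")
    if not np.all(np.asarray(lower) < np.asarray(upper)):
        raise ConfigurationError(f"empty truncation interval [{lower}, {upper}]")
    draw, _ = _trunc_norm_core(rng, mean, sd, lower, upper)
    return draw if draw.shape else float(draw)


def truncated_invgamma_draw(shape, scale, lower, upper, rng):
    """Exact inverse-CDF draw from InverseGamma(shape, scale) on [lower, upper]."""
    if not (np.all(np.asarray(shape) > 0) and np.all(np.asarray(scale) > 0)):
        raise ValidationError("shape and scale must be positive")
    if not np.all(np.asarray(lower) < np.asarray(upper)):
        raise ConfigurationError(f"empty truncation interval [{lower}, {upper}]")
    draw, _ = _trunc_invgamma_core(rng, shape, scale, lower, upper)
    return draw if draw.shape else float(draw)


def _initial_states(stats, mu_lo, mu_hi, s2_lo, s2_hi, n_chains):
    """Overdispersed starts around (ybar +/- s_y, s_y * {0.5, 1, 2}), clipped
    strictly inside the bounds."""
    eps_mu = 1e-6 * (mu_hi - mu_lo)
    s_lo, s_hi = math.sqrt(s2_lo), math.sqrt(s2_hi)
    eps_s = 1e-6 * (s_hi - s_lo)
    signs = [1.0, -1.0, 1.0, -1.0]
    factors = [0.5, 1.0, 2.0, 1.0]
    mu0, sig0 = [], []
    s_ref = stats.s_y if stats.s_y > 0 else 0.5 * (s_lo + s_hi)
    for j in range(n_chains):
        m = stats.ybar + signs[j % 4] * s_ref
        s = s_ref * factors[j % 4]
        mu0.append(min(max(m, mu_lo + eps_mu), mu_hi - eps_mu))
        sig0.append(min(max(s, s_lo + eps_s), s_hi - eps_s))
    return np.array(mu0), np.array(sig0) ** 2


def gibbs_sample(
    stats: HEGStats,
    prior: Prior,
    constraint: P95Constraint | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Sample the lognormal posterior of (mu, sigma) by a truncated Gibbs scheme.

    Each iteration draws mu from its truncated-normal full conditional given
    sigma^2, then sigma^2 from its truncated inverse-gamma full conditional
    given mu (see the module docstring for the conditionals).  When the P95
    constraint is enabled both conditionals are additionally truncated so the
    joint draw satisfies exp(mu + z95 sigma) < multiplier * oel.

    Returns retained (post-warmup, thinned) draws for all chains, along with
    the average probability mass removed by truncation in each conditional —
    a direct measure of how strongly the bounds bind.
    """
    if stats.n < 2:
        raise InsufficientDataError(f"stats.n must be >= 2, got {stats.n}")
    config = config or MCMCConfig()
    constraint = constraint or P95Constraint(enabled=False)
    informative = isinstance(prior, InformativePrior)

    n = stats.n
    ybar = stats.ybar
    s2 = stats.s_y**2

    mu_lo, mu_hi = prior.mu_lower, prior.mu_upper
    if informative:
        s2_lo, s2_hi = prior.sigma2_lower, prior.sigma2_upper
        ig_shape = prior.a0 + n / 2
    else:
        s2_lo, s2_hi = prior.sigma_lower**2, prior.sigma_upper**2
        ig_shape = (n - 1) / 2 if prior.parameterization == "sigma" else n / 2 - 1
        if ig_shape <= 0:
            raise ConfigurationError(
                f"uniform-on-sigma2 conditional needs n >= 3, got n={n}"
            )

    if constraint.enabled:
        cap = constraint.log_cap
        if cap <= mu_lo:
            raise ConfigurationError(
                f"P95 cap ln({constraint.multiplier}*{constraint.oel}) = {cap:.4f} "
                f"lies below mu_lower = {mu_lo:.4f}: empty constraint region"
            )
        # sigma small enough that some mu in [mu_lo, cap - z95*sigma] exists
        s2_hi = min(s2_hi, ((cap - mu_lo) / Z95) ** 2)
        if not s2_lo < s2_hi:
            raise ConfigurationError(
                f"P95 cap forces sigma2 <= {s2_hi:.6g}, below sigma2_lower "
                f"= {s2_lo:.6g}: empty constraint region"
            )
        mu_hi = min(mu_hi, cap)

    rng = np.random.default_rng(config.seed)
    n_chains = config.n_chains
    mu, sig2 = _initial_states(stats, mu_lo, mu_hi, s2_lo, s2_hi, n_chains)
    if constraint.enabled:
        # pull starting points inside the joint constraint region
        sig2 = np.minimum(sig2, (0.99 * (cap - mu_lo) / Z95) ** 2)
        mu = np.minimum(mu, cap - Z95 * np.sqrt(sig2) - 1e-9)
        mu = np.maximum(mu, mu_lo + 1e-12)

    total = config.n_warmup + config.n_iter * config.thin
    out_mu = np.empty((n_chains, config.n_iter))
    out_sigma = np.empty((n_chains, config.n_iter))
    cut_mu = 0.0
    cut_s2 = 0.0
    kept = 0

    lo_mu_vec = np.full(n_chains, mu_lo)
    for t in range(total):
        # mu | sigma^2, y
        if informative:
            v = 1.0 / (n / sig2 + 1.0 / prior.v0)
            m = v * (n * ybar / sig2 + prior.m0 / prior.v0)
        else:
            v = sig2 / n
            m = np.full(n_chains, ybar)
        hi_mu = mu_hi
        if constraint.enabled:
            hi_mu = np.minimum(mu_hi, cap - Z95 * np.sqrt(sig2))
        mu, mass_mu = _trunc_norm_core(rng, m, np.sqrt(v), lo_mu_vec, hi_mu)

        # sigma^2 | mu, y
        ss = (n - 1) * s2 + n * (ybar - mu) ** 2
        scale = 0.5 * ss + (prior.b0 if informative else 0.0)
        hi_s2 = s2_hi
        if constraint.enabled:
            hi_s2 = np.minimum(s2_hi, ((cap - mu) / Z95) ** 2)
        sig2, mass_s2 = _trunc_invgamma_core(rng, ig_shape, scale, s2_lo, hi_s2)

        k = t - config.n_warmup
        if k >= 0 and k % config.thin == 0:
            j = k // config.thin
            out_mu[:, j] = mu
            out_sigma[:, j] = np.sqrt(sig2)
            cut_mu += float(np.mean(1.0 - mass_mu))
            cut_s2 += float(np.mean(1.0 - mass_s2))
            kept += 1

    return PosteriorDraws(
        mu=out_mu,
        sigma=out_sigma,
        truncated_mass={
            "mu": cut_mu / max(kept, 1),
            "sigma2": cut_s2 / max(kept, 1),
        },
        config=config,
    )
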