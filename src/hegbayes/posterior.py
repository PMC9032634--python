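"""Posterior summaries, exposure-category probabilities, and MCMC diagnostics.

Summaries are computed on the pooled chains after transforming each draw
(mu, sigma) to the reporting scale — GM, GSD and P95 — so that medians and
credible intervals are empirical quantiles of the transformed draws, not
transforms of the (mu, sigma) quantiles.  Category probabilities are the
fractions of draws whose P95 falls in the SAMI bins relative to the OEL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_OEL
from .bayes import PosteriorDraws
from .errors import ValidationError


@dataclass(frozen=True)
class QuantitySummary:
    median: float
    cri_lower: float  # 2.5th percentile
    cri_upper: float  # 97.5th percentile


@dataclass(frozen=True)
class PosteriorSummary:
    gm: QuantitySummary
    gsd: QuantitySummary
    p95: QuantitySummary


@dataclass(frozen=True)
class CategoryProbabilities:
    """Posterior probability of each SAMI exposure category for the P95."""

    p1: float
    p2: float
    p3: float
    p4: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p1, self.p2, self.p3, self.p4)


@dataclass(frozen=True)
class Diagnostics:
    """Convergence diagnostics per parameter (keys 'mu' and 'sigma')."""

    rhat: dict
    ess_bulk: dict
    ess_tail: dict

    def flagged(self, n_chains: int, rhat_limit: float = 1.05, ess_per_chain: float = 100.0):
        """Parameters failing R-hat <= 1.05 or ESS > 100 per chain."""
        bad = []
        for p in self.rhat:
            if self.rhat[p] > rhat_limit:
                bad.append(p)
            elif min(self.ess_bulk[p], self.ess_tail[p]) <= ess_per_chain * n_chains:
                bad.append(p)
        return bad


def _quantity_summary(x: np.ndarray) -> QuantitySummary:
    med, lo, hi = np.percentile(x, [50.0, 2.5, 97.5])
    return QuantitySummary(median=float(med), cri_lower=float(lo), cri_upper=float(hi))


def summarize_posterior(draws: PosteriorDraws) -> PosteriorSummary:
    """Pooled-chain medians and equal-tailed 95% credible intervals of
    GM, GSD and P95."""
    if draws.mu.size == 0:
        raise ValidationError("no posterior draws to summarize")
    return PosteriorSummary(
        gm=_quantity_summary(draws.pooled("gm")),
        gsd=_quantity_summary(draws.pooled("gsd")),
        p95=_quantity_summary(draws.pooled("p95")),
    )


def category_probabilities(
    draws: PosteriorDraws | np.ndarray, oel: float = DEFAULT_OEL
) -> CategoryProbabilities:
    """Fraction of posterior draws whose P95 lands in each exposure category.

    Bins are lower-inclusive: [0, 0.1), [0.1, 0.5), [0.5, 1), [1, inf) in
    units of the OEL.  Accepts either posterior draws or a raw P95 array.
    """
    if not oel > 0:
        raise ValidationError(f"oel must be positive, got {oel}")
    p95 = draws.pooled("p95") if isinstance(draws, PosteriorDraws) else np.ravel(draws)
    if p95.size == 0:
        raise ValidationError("no draws given")
    r = p95 / oel
    p1 = float(np.mean(r < 0.1))
    p2 = float(np.mean((r >= 0.1) & (r < 0.5)))
    p3 = float(np.mean((r >= 0.5) & (r < 1.0)))
    p4 = float(np.mean(r >= 1.0))
    return CategoryProbabilities(p1=p1, p2=p2, p3=p3, p4=p4)


def gelman_rubin(chains) -> float:
    """Split-R-hat convergence diagnostic.

    Each chain is split in half; with W the mean within-half variance and B
    the between-half variance of the half means (times the half length), the
    statistic is sqrt(((n-1)/n * W + B/n) / W).  Values near 1 indicate the
    chains sample the same distribution; <= 1.05 is the usual pass mark.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValidationError("need >= 2 chains of equal length")
    n = chains.shape[1]
    if n < 4:
        raise ValidationError(f"chains too short for split-R-hat: length {n}")
    half = n // 2
    splits = np.concatenate([chains[:, :half], chains[:, n - half:]], axis=0)
    w = float(splits.var(axis=1, ddof=1).mean())
    b = half * float(splits.mean(axis=1).var(ddof=1))
    if w == 0.0:
        return 1.0  # constant chains: identical by definition
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def effective_sample_size(chains, kind: str = "bulk") -> float:
    """Rank-normalized bulk or tail effective sample size.

    Wraps ArviZ's autocorrelation-based estimator (Geyer initial-monotone
    truncation); 'bulk' rank-normalizes the draws, 'tail' uses the 5%/95%
    exceedance indicators.  A constant chain has no information content and
    returns 0 with a warning.
    """
    if kind not in ("bulk", "tail"):
        raise ValidationError(f"kind must be 'bulk' or 'tail', got {kind!r}")
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValidationError("need >= 2 chains of equal length")
    if np.ptp(chains) == 0.0:
        warnings.warn("constant chains: effective sample size defined as 0")
        return 0.0
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = az.ess(az.convert_to_dataset(chains), method=kind)
    return float(ess["x"].values)


def compute_diagnostics(draws: PosteriorDraws) -> Diagnostics:
    """R-hat and bulk/tail ESS for mu and sigma."""
    rhat, bulk, tail = {}, {}, {}
    for name in ("mu", "sigma"):
        arr = getattr(draws, name)
        rhat[name] = gelman_rubin(arr)
        bulk[name] = effective_sample_size(arr, "bulk")
        tail[name] = effective_sample_size(arr, "tail")
    return Diagnostics(rhat=rhat, ess_bulk=bulk, ess_tail=tail)
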