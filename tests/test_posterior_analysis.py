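import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hegbayes import (
    PosteriorDraws,
    ValidationError,
    category_probabilities,
    effective_sample_size,
    gelman_rubin,
    summarize_posterior,
)
from hegbayes.constants import Z95


def _draws(mu, sigma):
    return PosteriorDraws(mu=np.asarray(mu, float), sigma=np.asarray(sigma, float))


class TestSummaries:
    def test_point_mass_draws(self):
        d = _draws(np.full((2, 600), math.log(2.0)), np.zeros((2, 600)))
        s = summarize_posterior(d)
        assert s.gm.median == pytest.approx(2.0)
        assert s.p95.median == pytest.approx(2.0)
        assert s.gm.cri_lower == s.gm.cri_upper == pytest.approx(2.0)

    def test_p95_closed_form(self):
        d = _draws(
            np.full((2, 600), math.log(1.52)), np.full((2, 600), math.log(2.55))
        )
        s = summarize_posterior(d)
        assert s.p95.median == pytest.approx(7.09, abs=0.01)

    def test_p95_is_quantile_of_transformed_draws(self, rng):
        mu = rng.normal(0.2, 0.3, size=(4, 2_000))
        sigma = rng.gamma(5.0, 0.2, size=(4, 2_000))
        s = summarize_posterior(_draws(mu, sigma))
        expected = np.percentile(np.exp(mu + Z95 * sigma), 50)
        assert s.p95.median == pytest.approx(float(expected), rel=1e-12)
        # and differs from the transform of the (mu, sigma) medians
        plug_in = math.exp(np.median(mu) + Z95 * np.median(sigma))
        assert s.p95.median != pytest.approx(plug_in, rel=1e-6)

    def test_cri_ordering(self, rng):
        s = summarize_posterior(
            _draws(rng.normal(size=(2, 3_000)), rng.gamma(2, 0.3, size=(2, 3_000)))
        )
        for q in (s.gm, s.gsd, s.p95):
            assert q.cri_lower <= q.median <= q.cri_upper

    def test_empty_draws_rejected(self):
        with pytest.raises(ValidationError):
            summarize_posterior(_draws(np.empty((2, 0)), np.empty((2, 0))))


class TestCategoryProbabilities:
    def test_one_draw_per_bin(self):
        c = category_probabilities(np.array([0.1, 0.3, 1.5, 2.5]), oel=2.0)
        assert c.as_tuple() == (0.25, 0.25, 0.25, 0.25)

    def test_all_draws_above_oel(self):
        c = category_probabilities(np.array([2.0, 5.0, 9.9]), oel=2.0)
        assert c.as_tuple() == (0.0, 0.0, 0.0, 1.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_probabilities_sum_to_one(self, seed):
        p95 = np.random.default_rng(seed).lognormal(0.5, 1.0, size=200)
        c = category_probabilities(p95, oel=2.0)
        assert sum(c.as_tuple()) == pytest.approx(1.0, abs=1e-12)

    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=1.0, max_value=10.0),
    )
    def test_p4_monotone_under_upward_shift(self, seed, factor):
        p95 = np.random.default_rng(seed).lognormal(0.0, 1.2, size=300)
        before = category_probabilities(p95, oel=2.0).p4
        after = category_probabilities(p95 * factor, oel=2.0).p4
        assert after >= before


class TestGelmanRubin:
    def test_same_distribution_chains(self, rng):
        chains = rng.normal(size=(2, 5_000))
        assert 0.99 <= gelman_rubin(chains) <= 1.01

    def test_grossly_separated_chains(self, rng):
        chains = np.stack([rng.normal(0, 1, 1_000), rng.normal(5, 1, 1_000)])
        assert gelman_rubin(chains) > 1.5

    def test_hand_computed_toy_value(self):
        # chains {1,2,3,4} twice; split halves [1,2],[3,4],[1,2],[3,4]:
        # W = 0.5, B = 2 * var([1.5,3.5,1.5,3.5]) = 8/3,
        # var+ = W/2 + B/2 = 19/12, R-hat = sqrt(19/6)
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        assert gelman_rubin(chains) == pytest.approx(math.sqrt(19 / 6), abs=1e-12)

    def test_agrees_with_arviz_split_rhat(self, rng):
        import arviz as az

        chains = rng.normal(0.3, 1.1, size=(4, 200)) + np.linspace(
            0, 0.5, 4
        ).reshape(-1, 1)
        ours = gelman_rubin(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains), method="split")["x"])
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_single_chain_rejected(self):
        with pytest.raises(ValidationError):
            gelman_rubin(np.zeros((1, 100)))


class TestEffectiveSampleSize:
    def test_iid_chains_near_nominal(self, rng):
        chains = rng.normal(size=(4, 1_000))
        for kind in ("bulk", "tail"):
            assert effective_sample_size(chains, kind) == pytest.approx(
                4_000, rel=0.15
            )

    def test_ar1_matches_closed_form(self, rng):
        phi, n = 0.5, 10_000
        eps = rng.normal(size=(4, n))
        chains = np.empty((4, n))
        chains[:, 0] = eps[:, 0]
        for t in range(1, n):
            chains[:, t] = phi * chains[:, t - 1] + math.sqrt(1 - phi**2) * eps[:, t]
        expected = 4 * n * (1 - phi) / (1 + phi)
        assert effective_sample_size(chains, "bulk") == pytest.approx(
            expected, rel=0.15
        )

    def test_constant_chain_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert effective_sample_size(np.ones((2, 500))) == 0.0

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValidationError):
            effective_sample_size(rng.normal(size=(2, 100)), "middle")
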