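# hegbayes

Bayesian compliance testing of occupational coal-dust exposure for
homogeneous exposure groups (HEGs) of underground coal-mine workers.

Workplaces group workers into HEGs — sets of employees assumed to share one
exposure distribution — and judge dust control by where an upper percentile
of that distribution sits relative to the occupational exposure limit
(OEL, 2 mg/m³ respirable coal dust as an 8-hour time-weighted average in
South Africa).  The South African Mining Industry Code of Practice (SAMI
CoP) uses a point estimate of the 90th percentile (P90) of the current
measurement campaign only.  This package implements the Bayesian
alternative: a lognormal exposure model whose posterior turns the 95th
percentile (P95) into a full distribution, lets historical campaigns inform
the current assessment through an elicited prior, and expresses control
quality as posterior probabilities of the four regulatory exposure
categories.  It is written for occupational hygienists and biostatisticians
who want percentile-based compliance decisions with honest uncertainty.

## Model

Within a HEG, measured concentrations are lognormal:
log yᵢ ~ N(μ, σ²), with GM = exp(μ), GSD = exp(σ) and
P95 = exp(μ + z₀.₉₅ σ), z₀.₉₅ = 1.6449.  Two prior regimes:

* **Non-informative** — independent uniforms on μ and σ, truncated to wide
  bounds (defaults μ ∈ [ln 0.001, ln 100], σ ∈ [ln 1.05, ln 10]).
* **Informative** — elicited from a historical campaign with mean-log ȳ₀ and
  log-variance s²ᵧ₀, downweighted to a prior sample size n₀ (default 5):
  μ ~ N(ȳ₀, s²ᵧ₀/n₀) and σ² ~ InvGamma((n₀−1)/2, (n₀−1)s²ᵧ₀/2), both
  truncated; the σ² prior follows from (n₀−1)s²ᵧ₀/σ² ~ χ²ₙ₀₋₁.

Posterior sampling is a Gibbs scheme over the truncated full conditionals —
μ | σ² is truncated normal, σ² | μ is truncated inverse-gamma with sum of
squares SS = (n−1)s²ᵧ + n(ȳ−μ)² — drawn by exact inverse-CDF sampling, with
an optional joint bound P95 < k·OEL.  Convergence is checked with
split-R̂ and rank-normalized bulk/tail effective sample sizes.

The exposure categories classify a percentile Q against the OEL:
1 (Q < 0.1·OEL), 2 (0.1·OEL ≤ Q < 0.5·OEL), 3 (0.5·OEL ≤ Q < OEL),
4 (Q ≥ OEL, "poorly controlled").  The Bayesian report gives the posterior
probability of each category for the P95; the SAMI comparator assigns a
single category from the P90 point estimate.

## Worked example

The built-in study is nine HEGs (243 current-campaign measurements) whose
published per-campaign summaries are regenerated as moment-matched synthetic
data, so the posteriors are exactly those of the original sufficient
statistics:

```python
from hegbayes import (MCMCConfig, UniformPrior, category_probabilities,
                      fixture_stats, gibbs_sample, summarize_posterior)

stats = fixture_stats("HEG D")        # n=52, GM 0.42 mg/m3, GSD 3.29
draws = gibbs_sample(stats, UniformPrior(), config=MCMCConfig(seed=1))
s = summarize_posterior(draws)
c = category_probabilities(draws, oel=2.0)
print(round(s.gm.median, 3), round(s.p95.median, 2), round(100 * c.p4, 1))
```

prints `0.42 3.08 96.8`: the posterior median GM is 0.42 mg/m³ (well below
the OEL), but the posterior median P95 is 3.08 mg/m³ — above the limit —
and the probability that HEG D is in category 4 (poorly controlled) is
96.8%.  Central tendency and compliance tell opposite stories, which is the
point of percentile-based testing.

The full study is the numbered scripts:

```sh
python analysis/01_build_fixtures.py    # synthetic study -> results/fixtures/
python analysis/02_sami_comparator.py   # SAMI P90 + categories -> results/sami.csv
python analysis/03_fit_bayesian.py      # both regimes, 4 x 20,000 draws -> results/study/
python analysis/04_p95_figure.py        # P95 medians/CrIs vs OEL -> results/p95_comparison.png
```

In that run only HEG D is below the OEL by the SAMI empirical P90
(category 3); under both Bayesian regimes every HEG's category-4
probability exceeds 96%, the informative-prior credible intervals are
consistently narrower than the non-informative ones, and all 36 fitted
parameters have R̂ ≤ 1.0001 with bulk ESS above 66,000.

A `hegbayes` CLI wraps the same pipeline (`simulate`, `fit`, `study`,
`report`); see `hegbayes --help`.

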