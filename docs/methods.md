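# Methods

## Model and assumptions

Each homogeneous exposure group (HEG) is treated as a single lognormal
population: a worker-shift concentration y (mg/m³, 8-hour TWA respirable
coal dust) satisfies log y ~ N(μ, σ²), with natural logarithms throughout.
The data enter only through the sufficient statistics (n, ȳ, s_y), where ȳ
is the mean and s_y the sample standard deviation (n−1 denominator) of the
log-concentrations; GM = exp(ȳ) and GSD = exp(s_y) are the corresponding
sample summaries.  HEGs are fitted independently — no pooling or hierarchy
across groups — and there is no within-worker/between-worker variance
decomposition: the model assumes the group label captures all structure.
Censored or non-detect values are not handled.

The compliance quantity is the population 95th percentile
P95 = exp(μ + z₀.₉₅σ).  The normal quantiles are fixed at the field's
conventional four decimal places (z₀.₉₅ = 1.6449, z₀.₉ = 1.2816) rather
than recomputed, so closed-form spot checks reproduce published-style
numbers exactly.

## Priors

**Non-informative.**  Independent uniforms on μ and on σ (not σ²), truncated
to μ ∈ [ln 0.001, ln 100] and σ ∈ [ln 1.05, ln 10] by default.  Flat-on-σ is
chosen because it yields the clean conditional
σ² | μ ~ InvGamma((n−1)/2, SS/2) and because boundary-avoiding priors on the
scale (not the variance) are the standard recommendation; a flat-on-σ²
variant (conditional shape n/2 − 1) is exposed via
`UniformPrior(parameterization="sigma2")` for sensitivity analysis.  The
default bounds are deliberately wide: 0.001–100 mg/m³ for the GM covers any
plausible workplace series, and GSD 1.05–10 spans "essentially constant" to
"extremely variable".  Narrower literature choices (e.g. a lower bound of 0
on μ) would force GM ≥ 1 mg/m³ and are not usable as defaults; any bounds
can be set explicitly.

**Informative.**  A historical campaign with n₀' measurements supplies
ȳ₀ and s²ᵧ₀; downweighted to a prior sample size n₀ (default 5, i.e. the
"small prior so current data dominate" convention) the prior is

    μ  ~ N(ȳ₀, s²ᵧ₀ / n₀)          (truncated)
    σ² ~ InvGamma((n₀−1)/2, (n₀−1) s²ᵧ₀ / 2)   (truncated)

the inverse-gamma arising from (n₀−1)s²ᵧ₀/σ² ~ χ²ₙ₀₋₁.  Two eliciting modes
exist: `moments` (default) uses the historical campaign's moments directly,
making results deterministic given the summary table; `subsample` draws n₀
historical records without replacement under a seed, emulating elicitation
from a small historical sample.  Default truncation matches the
non-informative bounds (σ² ∈ [(ln 1.05)², (ln 10)²], μ capped at ln 100 or
at the P95 cap when one is configured).

**P95 cap.**  An optional joint constraint P95 < k·OEL can be enabled
(`StudyConfig(p95_cap_multiplier=k)`).  It is disabled by default: with the
study data the posterior P95 medians sit well above 2·OEL for most groups,
so an active k = 2 cap would change the reported posteriors qualitatively,
and the default keeps the likelihood's information intact.  When enabled,
*both* conditionals are truncated (μ above at ln(k·OEL) − z₀.₉₅σ, σ²
accordingly), so every retained draw satisfies the bound jointly.

## Sampler

A two-block Gibbs sampler over (μ, σ²):

* μ | σ², y — uniform regime: N(ȳ, σ²/n); informative regime: N(m*, v*)
  with v* = (n/σ² + 1/v₀)⁻¹ and m* = v*(nȳ/σ² + m₀/v₀); truncated.
* σ² | μ, y — InvGamma((n−1)/2, SS/2) (uniform on σ),
  InvGamma(n/2 − 1, SS/2) (uniform on σ²), or
  InvGamma(a₀ + n/2, b₀ + SS/2) (informative); SS = (n−1)s²ᵧ + n(ȳ−μ)²;
  truncated.

Both conditional draws are exact inverse-CDF samples on the truncation
interval.  The truncated normal reflects the interval into the lower tail
before evaluating Φ, so the interval mass retains full relative precision
far out in a tail; the truncated inverse-gamma uses the identity
F(x) = Q(a, b/x) (regularized upper incomplete gamma) and its inverse.  An
interval whose mass falls below 1e−300 raises a degenerate-truncation
error, and an empty constraint region is a configuration error naming the
offending bounds.

Defaults: 4 chains × 20,000 post-warmup draws, 2,000 warmup, thin 1.
Chains start overdispersed at μ = ȳ ± s_y and σ = s_y·{0.5, 1, 2}, clipped
inside the bounds.  The sampler reports, per conditional, the average
probability mass removed by truncation over retained iterations — near zero
when bounds are non-binding, and a direct diagnostic when they are not.

## Summaries, categories, diagnostics

Reported quantities are pooled-chain empirical quantiles (median, equal-
tailed 2.5/97.5 credible interval) of the *per-draw transforms* GM, GSD and
P95 — transform-then-summarize, never the transform of parameter quantiles.
Equal-tailed intervals are used rather than HPD.  Category probabilities
are the fractions of draws whose P95 falls in [0, 0.1), [0.1, 0.5),
[0.5, 1), [1, ∞) in OEL units; bins are lower-inclusive, mirroring the
"≥" conventions of the regulatory table, which does not itself state
boundary handling.

Convergence: split-R̂ implemented directly from the between/within-half
variance formula (cross-checked against ArviZ's `method="split"` in the
tests), with ≤ 1.05 the pass mark; bulk and tail effective sample sizes are
delegated to ArviZ's rank-normalized, Geyer-truncated estimator, with
> 100 per chain the pass mark.  A constant chain is assigned ESS 0 with a
warning.  The pipeline flags any fit violating either rule in
`diagnostics.csv`; at the default sizes all study fits pass with R̂ ≤ 1.0001
and bulk ESS above 66,000.

## Synthetic data

The generator emulates single-population lognormal campaigns.  Given a
target (n, GM, GSD) it draws log-concentrations N(ln GM, (ln GSD)²) and, in
moment-matching mode, affinely standardizes them so the sample mean-log and
sd-log hit ln GM and ln GSD exactly; the affine map preserves normality.
Since the posterior depends on data only through (n, ȳ, s_y), the
moment-matched fixtures make every Bayesian result independent of the
synthetic seed — the fixtures are a faithful stand-in for the study's
unavailable raw data *for the posterior*, but not for raw-data-dependent
statistics: the empirical SAMI P90 of a synthetic sample differs from the
original campaign's empirical P90, because a sample percentile is not a
function of the sufficient statistics.  Passing tests therefore demonstrate
correctness of the inference machinery and reproduction of
sufficient-statistic-determined results, not of order-statistic-level ones.
Real data also exhibit non-lognormal tails, correlated repeat measurements
and non-detects, none of which the generator simulates.

The SAMI comparator's default estimator is the empirical 90th sample
percentile (numpy linear interpolation); normal (AM + z₀.₉·SD) and
lognormal (GM·GSD^z₀.₉) variants are exposed because the three can move a
borderline HEG across a category boundary.

## Numerical and design choices

* Natural logs everywhere; sample SDs use the n−1 denominator.
* Seeds: one study seed; per-fit seeds are derived arithmetically from HEG
  index and regime, kept below 2³¹.  Report CSVs are byte-identical across
  runs with the same config.
* Degenerate inputs: constant samples give GSD 1 and are valid data but
  invalid eliciting history (a zero historical log-variance would make the
  prior degenerate and is rejected); n < 2 never reaches the sampler.
* Problem sizes in the analysis scripts (4 × 20,000 draws per fit, nine
  groups, two regimes) are the study's production settings; the test suite
  exercises the same code at smaller sizes where full-size chains add
  nothing to the property under test.

## Known limitations

* Groups with current data but no usable history get only the
  non-informative fit (logged as a warning), matching field reality where
  historical campaigns are missing or incomparable.
* The published posterior GSD medians for some groups are smaller than the
  data GSDs; a single-population lognormal model with non-binding bounds
  cannot produce that, so those particular printed values are not
  reproducible from the summaries alone.  The truncated-mass report exists
  precisely so users can see whether *their* bounds bind.
* The informative prior treats the historical campaign as exchangeable with
  the current one; drifted processes should use the subsample mode with
  caution or skip the informative regime.
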