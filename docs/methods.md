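# Methods

This note documents the models implemented in `nof1bayes`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish about real data.

## Single-trial model

For one participant, measurements `Y_j` at weeks `t_j` under treatments
`A_j ∈ {1..K}` (1 = reference) follow

    Y_j = M_j + e_j,     M_j = m + Σ_{k≠1} δ_k I(A_j = k) + β t_j,

with either i.i.d. errors `e_j ~ N(0, σ²)`, AR(1) errors
`e_j = ρ_e e_{j−1} + ε_j`, `ε_j ~ N(0, σ²)`, or the autoregressive-outcome
form `Y_j = M_j + ρ_Y Y_{j−1} + ε_j`. The arm-based parameterization
replaces `m` and the contrasts by one mean per arm; the two forms give
identical likelihoods when `m_k = m + δ_k`. Time is measured in study
weeks, 0-based at the first baseline measurement. Period boundaries come
from the input data (participants may cross over early), never from a
fixed grid.

**Likelihood.** Under AR(1) errors the default (`likelihood_mode="exact"`)
is the joint density from the conditional decomposition: the first
observation from its stationary marginal `N(M_1, σ²/(1−ρ_e²))`, each later
observation conditionally normal given its predecessor. Across a gap of
`Δ` weeks (a skipped or missing measurement) the conditional is
`N(M_j + ρ_e^Δ (y_{j−1} − M_{j−1}), σ²(1−ρ_e^{2Δ})/(1−ρ_e²))`, which is
exactly the marginalization of the unit-lag model over the unobserved
weeks; with unit gaps throughout it reproduces the dense multivariate
normal with covariance `σ² ρ^{|i−j|}/(1−ρ²)` (verified to 1e−8 in the
tests). A `stationary_product` mode multiplying the stationary marginals
as if observations were independent is retained for comparison because
the model is sometimes written in that product form; it discards the
cross-time correlation and is not recommended for inference or
imputation. Non-integer gaps require `ρ_e > 0` (a real power of a
negative base is undefined); weekly designs always have integer gaps.

For the autoregressive-outcome form, `δ_k` and `β` are *conditional on
the previous outcome*: they compare measurements whose previous outcomes
were equal. The package reports this conditional coefficient and does
not attempt to derive a marginal effect. This form also assumes
consecutive measurements (each conditional uses the immediately
preceding row); it is not gap-aware.

**Trend.** The trend covariate is used on the raw week scale. An earlier
design centered time at the trial mean to decorrelate intercept and
slope; with systematic-scan Gibbs using exact Gaussian conditionals the
mixing gain was negligible, and uncentered time keeps the intercept
interpretable as the week-0 level, so centering was dropped.

**Priors.** On a bounded outcome scale (lower, upper) the defaults are
deliberately noninformative but range-respecting: treatment means
Uniform(lower, upper) — (34, 78) for child-reported and (38, 78) for
parent-reported PROMIS pain-interference T-scores — contrasts
Uniform(−width, width) (so ±44 for the PROMIS range), correlations
Uniform(−1, 1), standard deviations Uniform(0, 1000), trend slopes
N(0, 10⁶). Contrast priors are bounded uniforms rather than diffuse
normals because the outcome range bounds any achievable contrast.

## Sampler

Inference is by systematic-scan Metropolis-within-Gibbs over a posterior
assembled as a sum of dependency-tagged log-density terms (each update
touches only the terms that involve the parameter, which is what makes
per-individual parameter blocks affordable).

- *Mean-type parameters* (means, contrasts, trend slopes, random-effect
  means): their full conditionals in the normal/AR(1) models are exactly
  Gaussian. The conditional is identified by probing the conditional
  log-density at three points (a quadratic has three degrees of freedom),
  and the update draws from the implied normal truncated to the prior
  support via the inverse CDF. This is an exact conjugate Gibbs step; no
  Metropolis correction is needed. If a conditional turns out flat or
  non-concave (e.g., a parameter with no data), the update falls back to
  a random-walk step.
- *Standard deviations* use random-walk Metropolis on the log scale;
  *correlations* on the Fisher-z scale (with the tanh Jacobian); the
  intercept–effect correlation additionally rejects any proposal that
  makes the structured covariance non-positive-definite.
- Step sizes adapt toward 0.44 acceptance during warmup only
  (Robbins–Monro schedule) and are frozen afterwards, so the post-warmup
  chain is a fixed Markov kernel.
- Chains receive distinct deterministic substreams of the seed
  (`SeedSequence.spawn`), making every run exactly reproducible.

Defaults: 4 chains, 2500 warmup, 2500 draws, R-hat threshold 1.05
(the CLI uses 2 chains × 1000/1000 for speed). R-hat is the split-chain
potential scale reduction factor; a single chain is split in half.
Zero-variance parameters report R-hat 1 with a degenerate-parameter
warning. Quantiles use linear interpolation between order statistics
(numpy's default percentile definition), fixed and documented here
because interval endpoints depend on the convention. Point estimates are
posterior medians.

## Multilevel model

Each first-level parameter family is *common* (one shared value), *fixed*
(free per individual, no pooling), or *random* (drawn from a population
distribution). Residual variances are restricted to common or fixed — a
hierarchy on variances would need its own prior structure and is not
modeled. Random error correlations are modeled on the Fisher-z scale.

The structured intercept–effect covariance over `(μ_i, δ_i2, …, δ_iK)`
places `σ_μ²` top-left, `ρ_μδ σ_μ σ_δ` along the first row/column, and
`σ_δ² P(0.5)` in the contrast block. Because all contrasts share the
reference arm and (under a constant treatment variance) must have equal
variance, their pairwise correlation is forced to 0.5 exactly. The
contrast block is (K−1)×(K−1) — the modeled vector has K−1 contrast
entries plus the intercept (some write-ups print the block as K×K; the
K−1 dimension is the one consistent with the vector being modeled).
Positive definiteness requires
`|ρ_μδ| < sqrt((1 + 0.5(K−2))/(K−1))`; the bound is enforced by an
attempted Cholesky factorization at every evaluation and violating
proposals are rejected.

Subgroup structure enters the population effect means as
`d_k = d_{0k} + Σ_j d_{jk} x_jk` over individual-level covariates;
`subgroup_effect` returns per-draw effects at two covariate settings and
their difference, ready for statements like "P(improvement larger for
girls)". Within-individual covariates (Eq.-style `γ_li z_lij`) enter the
first-level mean with common or per-individual coefficients; the
exponential-decay carryover covariate `z = 2^{−(t−t*)/half-life}` is the
supplied special case. In repeating ABAB-type sequences carryover can be
confounded with sequence structure; `check_carryover_identifiable` runs a
design-matrix rank check and the covariate should not be fit when it
fails. The enumeration of all 2·C(K,2) directional crossover parameters
is not implemented; only the covariate form is.

The default meta configuration mirrors a typical fixed-intercept
meta-analysis of randomized N-of-1 trials: fixed intercepts (each with an
independent bounded-uniform prior, treated as nuisance parameters —
this implicitly adjusts for stratification factors), random treatment
effects, common ρ_e and common σ².

## Missing data

*Missing at random.* A missing outcome slot is a state variable updated
once per sweep from its exact conditional normal given the currently
filled neighbors and parameters (AR(1) is Markov, so the nearest filled
neighbor on each side suffices; moments come from conditioning the 2- or
3-dimensional joint normal). The tests verify that this data augmentation
leaves the parameter posterior unchanged relative to simply skipping the
missing row (which the gap-aware likelihood handles analytically).

*Missing not at random.* Dropout in crossover diet trials marks lack of
benefit, so imputing withdrawals from the pooled posterior would be
biased toward the completers' benefit. The MNAR procedure stratifies on
the three completion groups, fits the multilevel model within each
stratum alone (default: fixed intercepts, random effects, common ρ_e and
σ² — the same configuration as the stratum meta-analyses; the
random-effects layer is what gives a never-observed treatment contrast a
proper posterior for imputation), and draws M completed datasets using M
evenly spaced posterior draws per stratum. Design slots are expanded
until every participant has at least 1 baseline and 6 per-period
measurements (configurable); treatments for never-entered periods come
from the randomization sequence, or by parity of the alternating design
when the sequence label is absent. Imputed bounded outcomes are truncated
to the declared scale range (untruncated draws could exit it), with
truncation logged. Observed cells are identical across the M datasets.

*Pooling.* Rubin's rules: pooled estimate = mean of the M estimates,
total variance `T = W + (1 + 1/M) B` (within-mean plus inflated
between-variance), interval from a t reference with the small-M degrees
of freedom `ν = (M−1)(1 + W/((1+1/M)B))²`; with B = 0 (including M = 1)
the normal reference is used. The rules are spelled out here because
"Rubin's rules" names a family of presentations.

## Decision summaries

For a bounded pain-type outcome, lower is better by default (the
direction is a per-outcome flag): improvement on a comparison means the
outcome difference is negative, clinically meaningful improvement means
it is below −MCID (default MCID 3 points), worsening means it is
positive. A participant is a *responder* on a comparison when
P(meaningful improvement) > 0.5 and P(worsening) < 0.1. Benefit/harm
tables report the posterior median difference, the central credible
interval, and P(difference < 0) per comparison. Posterior predictive
p values count ties as exceedance (`T_rep ≥ T_obs`), exactly the defining
inequality.

## Synthetic-data generator

The generator emulates a two-diet crossover study: 2 baseline weeks on
the reference, four 8-week experimental periods in ABAB or BABA order,
weekly measurements, AR(1) errors initialized from the stationary
distribution, bounded outcomes clipped to the scale (clipping logged;
recovery tests use wide bounds so truncation is negligible). Individual
parameters come from the second-level normal distributions, optionally
with the structured intercept-effect correlation. Completion strata
default to proportions 21/54, 9/54, 24/54 (full, early, withdrawal).
Withdrawals truncate at a uniform week inside the *first* experimental
period: the observed-data completion classifier cannot distinguish a
mid-second-period withdrawal from an early completer (both show data in
periods 1–2 only), so confining generated withdrawals to period 1 keeps
generated labels and classified labels identical. MNAR dropout tilts the
withdrawal probability by `exp(s · δ_i2)` so less-benefiting individuals
drop out more; the strength `s` is a free knob because no dropout model
is being estimated. Intermittent MAR gaps blank each scheduled
measurement with a configurable probability, keeping the row with a
missing marker.

What the generator does *not* emulate: early crossovers at participant-
chosen times, learning or cyclic trends, reporter switches mid-trial,
outcome floor/ceiling clustering, or any dependence of intermittent
missingness on the outcome. Passing recovery and coverage tests on this
generator therefore shows the estimator is correct *under the model*,
not that the model fits any particular real study.

## Problem sizes used in the checks

Recovery: 30 individuals × 30 weekly observations (d₂ = −3, σ_δ = 2,
ρ_e = 0.4, σ = 5), 20 replicate seeds, 2 chains × (300 warmup + 300
draws); the average posterior-median error of d₂ stays within 0.5 outcome
units. Coverage: 100 replicates of 12 individuals × 14 observations with
2 × (250+250) chains; the 95% interval for d₂ covers the truth 88–100% of
the time. These sizes were chosen to make the full suite convenient to
run repeatedly while keeping Monte-Carlo noise well below the tolerances
being checked.

## Known limitations

- No Hamiltonian/NUTS sampling; very high-dimensional random-effect
  structures mix more slowly than gradient-based samplers would.
- Discrete outcomes support only independent Bernoulli-logit and
  Poisson-log models — no latent-variable autocorrelation and no
  categorical (baseline-category or cumulative-logit) models.
- No network meta-analysis: all trials must share one treatment set.
- The multilevel assembly uses the contrast parameterization; arm-based
  multilevel models are not provided (single trials support both).
- MNAR handling is exactly the stratum-specific imputation described
  above — no selection or pattern-mixture machinery.
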