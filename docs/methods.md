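# Methods

## Model

The package implements a joint two-equation latent Gaussian model for an
unbalanced region × year health panel with nested region-in-country
structure.

**Outcome equation** (per region *i*, country *j*, year *t*):
log outcome on its own lag with a random coefficient, covariates, a region
intercept deviation, a Matérn spatial field on region centroids and an RW1
temporal trend; Gaussian noise σ_u on the log scale.  The lag coefficient
decomposes as β + υ_j + ν_t with iid Gaussian country deviations (variance
σ²_υ, sum-to-zero) and RW1 year deviations (independent Gaussian
increments, sum-to-zero).  The covariate coefficients on current log GDP
per capita and on log Gini (lags 0 and 1) can optionally carry the same
country + year random structure; they default to fixed, and the
`variance_test` operation decides whether a random version is warranted
(its sd credibly above 1% of the residual sd *and* a DIC improvement).

**Gini equation** (per country-year): log Gini on lagged country-mean log
outcome (lags 1–3), lagged country log GDP per capita (lags 1–3), the
lagged GDP growth rate, its own first lag, the period dummies, a country
Matérn field and a country-specific RW1 trend; noise σ_v.  Both equations
share one posterior, which is how the endogeneity of income inequality
(driven by lagged health) is handled; the Gini value entering the outcome
equation is the observed one (a two-stage plug-in latent-Gini variant is
available behind `ModelConfig.latent_gini`).

All five outcome choices (life expectancy; total, ischemic, cancer and
lung-cancer mortality) use the same Gaussian-on-log-scale observation
model; mortality rates are assumed already standardized per 100,000.

Assumptions worth stating: weak exogeneity of the lagged outcome (current
shocks affect only future values), iid errors *after* the spatio-temporal
adjustment (checked by `residual_diagnostics`), covariates other than Gini
treated as given, and complete-case masking per equation for missing cells
(rows are masked, never dropped; an unbalanced panel is the expected
input).

## Transformations

- Lags are calendar-year-indexed within region (outcome equation) or
  country (Gini equation): a gap year yields a missing lag, never a wrong
  join.  The outcome equation needs lags to 2 (GDP per capita), the Gini
  equation to 3, so the first 2 resp. 3 panel years are masked.
- Period dummies are 1 strictly after 2003, 2006 and 2007 (EU enlargements
  2004/2007 and the 2008 financial crisis).
- The external balance can be negative (observed range spans roughly −32 to
  +28 % of GDP) yet enters a log-log model; it uses the signed transform
  sign(b)·log(1+|b|), which preserves sign and order and is 0 at 0.
- The Gini index is kept on the 0–100 scale and logged there.
- The country-level outcome is the *unweighted* mean of region outcomes on
  the original scale, then logged; population weights are deliberately not
  required.

## Priors and identification

Fixed effects: Normal(0, 10²).  Every sd hyperparameter: half-Normal(0, 1).
Matérn field variances: half-Normal(0, 1) on the variance.  The Matérn
smoothness defaults to ν = 1 (the standard choice in two dimensions) and
the range to half the site bounding-box diagonal; both are configurable and
held fixed during sampling — only the field variance is sampled, keeping
the coefficient block exactly Gaussian.  `PriorConfig.precision_scale`
multiplies all prior precisions for sensitivity analysis
(`prior_sensitivity` refits per factor and reports max posterior-mean
shifts).

Deviation blocks (region intercepts, country deviations, RW1 effects,
spatial fields) are separated from the global intercept/global β by
sum-to-zero constraints, implemented as a soft constraint: a Gaussian
penalty with precision 1e8 on each block sum, added to the prior
precision.  RW1 blocks are otherwise rank-deficient (the level carries no
density); the penalty also fixes their level.

## Inference

Blocked Gibbs:

1. **Coefficient block** — all linear parameters of both equations stacked
   into one vector θ.  Given the variances, p(θ | …) is multivariate
   normal with precision Zᵀ W Z + P(hypers); the cross-products are
   precomputed once, so each iteration costs one dense Cholesky (p is a few
   hundred at desk scale).  With random effects off and σ fixed this step
   draws i.i.d. exact conjugate samples — the test suite verifies the
   sampled posterior means against the closed form to 0.5%.
2. **Hyperparameters** — each sd (or field variance) has a univariate
   conditional: Gaussian sum-of-squares of its block against the
   half-Normal prior.  These are not conjugate; each is updated by
   stepping-out slice sampling on the log scale (tuning-free,
   deterministic given the seed).

Defaults: 2 chains, draws after burn-in = half the iterations.  Convergence
is declared via split potential-scale-reduction ≤ 1.05 over all scalars; a
fit exceeding it is returned with a loud warning and `converged=False`,
never silently.  Everything is bit-reproducible given (config, seed): the
per-chain RNG is seeded as (seed, chain).

Fitted values are the posterior-mean linear predictor of the outcome
equation per unmasked row, exponentiated for the response scale.  DIC uses
the joint deviance: DIC = D̄ + p_eff, p_eff = D̄ − D(posterior mean).
CPO/leave-one-out quantities are out of scope.

Residual diagnostics on standardized residuals (log y − fitted)/σ̂_u:
per-region lag-1 autocorrelation, a per-year Moran-type spatial statistic
with row-normalized inverse-distance weights, and contemporaneous
correlations with every regressor including the lagged outcome; each flags
at |statistic| > 2/√n.  Regions with fewer than 3 residuals are skipped
with a note.

## Convergence analytics

- `coefficient_of_variation`: sample sd (n−1) over the mean; requires a
  positive mean.  The n−1 choice matters for years with few regions.
- `sigma_convergence`: per-year CV of fitted values across regions,
  response scale by default (log scale behind a flag) — dispersion of
  *health outcomes*, not of their logs, is the quantity of interest.
  Years with < 2 fitted regions are omitted with a note.
- `detect_break`: for each candidate year, jump = mean CV after − mean CV
  before; argmax wins, ties to the earliest year.  A jump is flagged
  significant when it exceeds 2× the sd of year-over-year CV changes — a
  step-versus-noise yardstick, deliberately not an asymptotic test.
- `assess_beta`: convergence iff β < 0 with the 95% interval excluding 0.
  A *negative* significant country deviation is labelled a below-average
  convergence rate, positive above-average; significant *positive* year
  deviations are divergence years.  Note an ambiguity in published tables
  of this model family: country rows are sometimes headed as intercept
  deviations (α_j) while the accompanying narrative reads them as
  convergence-rate (β) deviations; the package exposes both blocks
  (`alpha_<region>` and `beta_country_<country>`) and maps the verbal
  labels to the β deviations.
- Summary-mode significance (mean ± 1.96 sd) exists because published
  tables print only (mean, sd); posterior-quantile mode is authoritative
  for internal fits.  The two can disagree within ~3% of the 1.96
  boundary — one published country-deviation pair sits at 1.95 sds and is
  treated as borderline rather than forced to a label.

## Synthetic-data generator

The generator is the model run forward, not a separate approximation:

- Geometry: country centres uniform in the unit square, regions clustered
  within ±0.05 of their centre.
- Covariates: stationary AR(1) (coefficient 0.8) at the observed EU
  magnitudes — GDP per capita ≈ 19 474 PPS, Gini ≈ 29.65, public
  expenditure ≈ 46.5%, youth unemployment ≈ 18–20%, etc. — on the log
  scale except the external balance and growth rate, which can be
  negative.  GDP per capita, R&D, external balance, public expenditure and
  growth rate vary at country level; high-tech employment, university
  share and youth unemployment at region level.
- Gini evolves endogenously by the Gini equation; the outcome by the
  outcome equation, initialized at each region's stationary mean (an
  optional displacement `init_log_y_sd` starts regions off their steady
  state).  Three pre-sample years are simulated and discarded so
  within-panel lags start from settled dynamics.
- Intercepts are calibrated so the stationary levels hit the outcome and
  Gini targets given the covariate means.
- Generating values default to β = −0.5, Gini elasticity −0.2, Gini
  persistence 0.8, σ_u = σ_v = 0.02, with effect sds of a few percent —
  magnitudes consistent with published estimates for this model family.
- Missing cells are inserted completely at random at a configurable rate
  (default 5%).
- Stability guard: under the literal level form the AR root is β itself
  (under the growth form, 1 + β); simulation refuses |root| ≥ 1 including
  deviations.

**Scenarios.**  `convergent` is the default dynamics.
`divergent_after_break` (and `crisis_2010`, pinned at 2010) injects, from
the break year on, (a) a +0.4 year deviation in β — the magnitude of
published 2010 divergence-year deviations — together with a compensating
temporal-trend shift that keeps the stationary *level* fixed (without it
the level would jump, since the stationary mean is a/(1−β)), and (b) a 3×
multiplier on the region-shock sd.  Mechanism: writing the fitted value as
m_i + ν_t(m_i − m̄) + (β + ν_t)·dev_i, a positive ν_t widens the
cross-region spread of stationary levels by (1+ν_t) at the break year
itself, and the inflated shocks reinforce the widening from the following
year through the lag.

What the generator does *not* emulate: real EU geography and country
idiosyncrasies, covariate trends and cross-covariate correlation,
non-random missingness, measurement error in covariates.  Passing tests
therefore demonstrate internal consistency (the method recovers the truth
of its own generative class and detects the breaks it defines), not
external validity on real EUROSTAT panels.

## Problem sizes and numerical choices

The test suite runs fits at 4–10 countries × 3–5 regions × 10–12 years
with 200–2000 retained draws, and Monte-Carlo properties at up to 50 seeds
or ~5000 observations — sizes chosen so the full suite completes in a few
minutes while leaving the Monte-Carlo tolerances (5% relative on moment
checks, 0.5% on the conjugate comparison) statistically comfortable.
Covariance factorizations add a relative jitter of 1e−8 × variance to the
diagonal.  Coincident sites are allowed (perfect correlation) with a
warning.  A lag order exceeding the year span yields an all-missing column
with a warning.  A printed sd of exactly 0 in summary-mode significance is
treated as a degenerate interval (significant iff the mean is nonzero),
which published tables occasionally require.

## Known limitations

- The Gini equation with per-country RW1 trends is close to saturated on
  short panels; its own-lag coefficient mixes slowly and its posterior can
  be mildly optimistic (interval coverage near, not above, nominal in the
  recovery study).
- Split-R̂ on a few hundred scalars is conservative; fits routinely warn
  at modest draw counts even when the quantities of interest are stable.
- The dense-covariance spatial field scales to a few hundred sites; larger
  problems would need sparse (Markov) approximations, deliberately out of
  scope.
- Break detection reports the best candidate and a descriptive
  significance flag; it is not a formal structural-break test.
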