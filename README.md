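# healthconv

Bayesian spatio-temporal dynamic panel modelling of **regional
health-inequality convergence**, for health economists and epidemiologists
studying whether disparities in health outcomes (life expectancy, total and
cause-specific mortality) across regions shrink or widen over time — and in
particular whether a macroeconomic shock leaves a detectable dispersion
break.

## The model

For region *i* nested in country *j* and year *t*, the health outcome
follows a dynamic panel (conditional β-convergence) equation,

```
log y_ijt = a0 + α_i + (β + υ_j + ν_t) log y_ijt−1 + γ·x_ijt + S_i + τ_t + u_ijt
```

where `x_ijt` collects log GDP per capita (lags 0–2), log Gini (lags 0–1),
log high-tech employment, log university students, log youth male/female
unemployment, log R&D, a signed-log external balance, log public
expenditure, and three period dummies (1 from 2004, 2007 and 2008 on).
Coefficients are *random*: the lag coefficient β carries iid Gaussian
country deviations υ_j and first-order random-walk (RW1) year deviations
ν_t; α_i are region intercept deviations, S_i a Matérn-covariance Gaussian
spatial field on region centroids, τ_t an RW1 trend, u_ijt ~ N(0, σ_u²).

Because income inequality and health are plausibly bidirectionally causal,
the country-level Gini index is *endogenous* and gets its own equation,
estimated jointly with the first:

```
log Gini_jt = δ_0j + δ1..3·log y_jt−1..3 + δ4..6·log gdppc_jt−1..3
              + δ7·rate_jt−1 + δ8·log Gini_jt−1 + δ9..11·dummies + S'_j + τ'_jt + v_jt
```

**β-convergence** holds when β is negative with a 95% credible interval
excluding zero: regions below their steady state catch up.  Country/year
deviations localize the verdict (below/above-average convergence rate,
divergence years).  **σ-convergence** is measured as the per-year
cross-region coefficient of variation (CV) of the model's fitted outcome
values; a sustained CV rise after a candidate year is a dispersion break.

Inference is a blocked Gibbs sampler: all coefficients are drawn jointly
from their exact conjugate multivariate-normal conditional, and each
sd/variance hyperparameter by univariate slice sampling (half-Normal
priors).  Split-R̂ over ≥ 2 chains flags non-convergence loudly.

A synthetic-data generator (`healthconv.synthetic_data`) is a full
generative twin of the model — exogenous AR(1) covariates at realistic EU
magnitudes, endogenous Gini, spatially correlated region effects, an
optional post-break dispersion regime — so every stage is testable at desk
scale with known truth.

## Worked example

Simulate a 12-country × 5-region panel (1995–2011) with a crisis-type
dispersion break injected in 2010, fit the joint model and run the
convergence analytics:

```sh
healthconv all --out demo --seed 7 --outcome life_expectancy \
    --config demo.yaml
```

with `demo.yaml`:

```yaml
scenario: crisis_2010
simulate: {n_countries: 12, regions_per_country: 5,
           year_range: [1995, 2011], missingness: 0.02}
fit: {draws: 800, burn: 600, chains: 2}
```

This writes `panel.csv`, `geometry.csv`, `truth.json`, `fit.json`,
`fitted.csv`, `diagnostics.json`, `cv_series.csv`, `beta_report.json` and
`report.md`.  On this run the package prints/records:

- `beta_report.json`: `beta = -0.4748`, `convergence: true` — the global
  lag coefficient is negative and credibly nonzero (the generating value
  was −0.5), so the regions exhibit a catching-up process;
- `divergence_years: [2009, 2010, 2011]` — the RW1 year deviations of β
  turn significantly positive when the injected break relaxes the
  catching-up compression;
- `cv_series.csv`: the fitted-value CV is flat near 0.075 through 2008,
  then climbs 0.0788 → 0.0822 → 0.0855 → 0.0882 over 2008–2011;
- `break: {year: 2010, jump: 0.0106, significant: true}` — the
  largest pre/post CV jump among the candidate years is at 2010, the
  injected break year, and exceeds twice the inter-year CV-change sd;
- `fit.json`: `DIC = -3746.9`, `effective parameters = 111.4`.

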