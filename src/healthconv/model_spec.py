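"""Joint two-equation dynamic panel model: linear predictors, likelihood, priors.

Outcome equation (one row per region i, country j, year t):

    log y_ijt = a0 + alpha_i + (beta + ups_j + nu_t) log y_ijt-1
                + gamma . x_ijt + S_i + tau_t + u_ijt,   u ~ N(0, sigma_u^2)

with x the covariate vector (log GDP per capita at lags 0-2, log Gini at
lags 0-1, log high-tech employment, log university students, log youth
male/female unemployment, log R&D, signed-log external balance, log public
expenditure, three period dummies).  The Gini equation (one row per
country-year) models log Gini on lagged country-mean log outcome (lags
1-3), lagged country log GDP per capita (lags 1-3), the lagged GDP growth
rate, its own lag, the dummies, a country spatial field S'_j and a
country-specific RW1 trend tau'_jt, with noise sd sigma_v.  The two
equations share one posterior, which is how the endogeneity of the Gini
index (driven by lagged health outcomes) is handled.

A negative, significant beta is conditional beta-convergence: regions below
their steady state catch up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import halfnorm, norm

from .latent_fields import MaternField, RW1Effect, matern_logpdf, rw1_logpdf
from .panel_data import DesignTable, RegionGeometry

#: gamma coefficient names, aligned with DesignTable.EQ1_REGRESSORS[1:]
GAMMA_NAMES = [
    "log_gdppc", "log_gdppc_lag1", "log_gdppc_lag2", "log_gini",
    "log_gini_lag1", "log_empht", "log_univ", "log_umy", "log_ufy",
    "log_randd", "bpg_t", "log_pubexp", "d2004", "d2007", "d2008",
]
#: delta coefficient names, aligned with DesignTable.EQ2_REGRESSORS
DELTA_NAMES = [
    "log_yc_lag1", "log_yc_lag2", "log_yc_lag3",
    "log_gdppc_c_lag1", "log_gdppc_c_lag2", "log_gdppc_c_lag3",
    "rate_lag1", "log_gini_lag1", "d2004", "d2007", "d2008",
]
#: gammas that may carry country/year random deviations
RANDOM_GAMMA_CANDIDATES = ("log_gdppc", "log_gini", "log_gini_lag1")

#: every sd/variance hyperparameter a full model carries
HYPER_NAMES = (
    "sigma_u", "sigma_v", "sd_alpha", "sd_beta_country", "sd_beta_year",
    "sd_tau_year", "sd_delta0_country", "sd_tau_country",
    "matern_region_var", "matern_country_var",
)


@dataclass
class ModelConfig:
    """Structural switches of the joint model.

    random_effects toggles each latent block; gamma_random turns on
    country+year deviations for the candidate covariate coefficients
    (off by default; the variance test decides whether to keep them).
    """

    growth_form: bool = False      # LHS of eq.1 is dlog y instead of log y
    latent_gini: bool = False      # eq.1 uses fitted log Gini (two-stage plug-in)
    log_scale_cv: bool = False     # sigma-convergence CV on the log scale
    random_effects: dict = field(default_factory=lambda: {
        "alpha_region": True, "beta_country": True, "beta_year": True,
        "s_region": True, "tau_year": True,
        "delta0_country": True, "s_country": True, "tau_country": True,
    })
    gamma_random: dict = field(default_factory=lambda: {
        name: False for name in RANDOM_GAMMA_CANDIDATES
    })
    matern_smoothness: float = 1.0
    matern_range_region: float | None = None   # None: half the bbox diagonal
    matern_range_country: float | None = None

    def enabled(self, name: str) -> bool:
        return bool(self.random_effects.get(name, False))


def default_matern_range(coords: np.ndarray) -> float:
    """Half the bounding-box diagonal of the sites (falls back to 1)."""
    if len(coords) < 2:
        return 1.0
    span = coords.max(axis=0) - coords.min(axis=0)
    diag = float(np.hypot(*span))
    return 0.5 * diag if diag > 0 else 1.0


@dataclass
class ParameterSet:
    """One full point in parameter space, indexed by region/country/year lists.

    Deviation vectors (alpha_region, beta_country, ...) are centred
    deviations around the corresponding global quantity.
    """

    regions: list
    countries: list
    years: np.ndarray

    intercept: float = 0.0
    alpha_region: np.ndarray = None
    beta: float = 0.0
    beta_country: np.ndarray = None
    beta_year: np.ndarray = None
    gamma: np.ndarray = None                  # len 15, GAMMA_NAMES order
    gamma_country: dict = None                # name -> len-nJ array
    gamma_year: dict = None                   # name -> len-nT array
    s_region: np.ndarray = None
    tau_year: np.ndarray = None

    delta0: float = 0.0
    delta0_country: np.ndarray = None
    delta: np.ndarray = None                  # len 11, DELTA_NAMES order
    s_country: np.ndarray = None
    tau_country_year: np.ndarray = None       # (nJ, nT)

    sigma_u: float = 1.0
    sigma_v: float = 1.0
    hyper: dict = None

    def __post_init__(self) -> None:
        nR, nJ, nT = len(self.regions), len(self.countries), len(self.years)
        self.years = np.asarray(self.years, int)

        def zeros(cur, shape):
            return np.zeros(shape) if cur is None else np.asarray(cur, float)

        self.alpha_region = zeros(self.alpha_region, nR)
        self.beta_country = zeros(self.beta_country, nJ)
        self.beta_year = zeros(self.beta_year, nT)
        self.gamma = zeros(self.gamma, len(GAMMA_NAMES))
        self.s_region = zeros(self.s_region, nR)
        self.tau_year = zeros(self.tau_year, nT)
        self.delta0_country = zeros(self.delta0_country, nJ)
        self.delta = zeros(self.delta, len(DELTA_NAMES))
        self.s_country = zeros(self.s_country, nJ)
        self.tau_country_year = zeros(self.tau_country_year, (nJ, nT))
        self.gamma_country = self.gamma_country or {}
        self.gamma_year = self.gamma_year or {}
        self.hyper = self.hyper or {}
        # zero is allowed (deterministic generative twins); the likelihood
        # itself requires strictly positive sds
        if min(self.sigma_u, self.sigma_v) < 0:
            raise ValueError("observation sds must be non-negative")
        self._ridx = {r: k for k, r in enumerate(self.regions)}
        self._cidx = {c: k for k, c in enumerate(self.countries)}
        self._yidx = {int(y): k for k, y in enumerate(self.years)}

    # index helpers -------------------------------------------------------
    def region_index(self, region_ids) -> np.ndarray:
        return np.array([self._ridx[r] for r in region_ids])

    def country_index(self, country_ids) -> np.ndarray:
        return np.array([self._cidx[c] for c in country_ids])

    def year_index(self, years) -> np.ndarray:
        return np.array([self._yidx[int(y)] for y in years])

    def gamma_named(self, name: str) -> float:
        return float(self.gamma[GAMMA_NAMES.index(name)])


@dataclass
class PriorConfig:
    """Priors on fixed effects and hyperparameters.

    Weakly informative defaults: Normal(0, fixed_effect_sd^2) on fixed
    effects, half-Normal(0, scale) on every sd.  precision_scale > 1
    tightens all of them (sd divided by sqrt(factor)); used by the prior
    sensitivity analysis.
    """

    fixed_effect_sd: float = 10.0
    sd_scales: dict = field(default_factory=dict)   # hyper name -> half-normal scale
    default_sd_scale: float = 1.0
    precision_scale: float = 1.0
    #: soft sum-to-zero: precision put on the sum of each deviation block
    constraint_precision: float = 1e8

    def sd_scale(self, name: str) -> float:
        base = self.sd_scales.get(name, self.default_sd_scale)
        return base / np.sqrt(self.precision_scale)

    def fixed_sd(self) -> float:
        return self.fixed_effect_sd / np.sqrt(self.precision_scale)


# ---------------------------------------------------------------------------
# linear predictors
# ---------------------------------------------------------------------------

def eta_outcome(params: ParameterSet, design: DesignTable, rows=None) -> np.ndarray:
    """Outcome-equation linear predictor for the given eq1 rows (default: all).

    Pure function of (params, design); requires the addressed rows to have
    no missing regressors.
    """
    eq1 = design.eq1 if rows is None else design.eq1.loc[rows]
    X = eq1[DesignTable.EQ1_REGRESSORS].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("eta_outcome called on rows with missing regressors; mask first")
    ri = params.region_index(eq1["region_id"])
    ci = params.country_index(eq1["country_id"])
    yi = params.year_index(eq1["year"])

    beta_eff = params.beta + params.beta_country[ci] + params.beta_year[yi]
    eta = (
        params.intercept
        + params.alpha_region[ri]
        + beta_eff * X[:, 0]
        + X[:, 1:] @ params.gamma
        + params.s_region[ri]
        + params.tau_year[yi]
    )
    for name, dev in params.gamma_country.items():
        eta += np.asarray(dev)[ci] * eq1[name].to_numpy(float)
    for name, dev in params.gamma_year.items():
        eta += np.asarray(dev)[yi] * eq1[name].to_numpy(float)
    return eta


def eta_gini(params: ParameterSet, design: DesignTable, rows=None) -> np.ndarray:
    """Gini-equation linear predictor for the given eq2 rows (default: all)."""
    eq2 = design.eq2 if rows is None else design.eq2.loc[rows]
    X = eq2[DesignTable.EQ2_REGRESSORS].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("eta_gini called on rows with missing regressors; mask first")
    ci = params.country_index(eq2["country_id"])
    yi = params.year_index(eq2["year"])
    return (
        params.delta0
        + params.delta0_country[ci]
        + X @ params.delta
        + params.s_country[ci]
        + params.tau_country_year[ci, yi]
    )


def outcome_response(design: DesignTable, growth_form: bool = False) -> np.ndarray:
    """LHS of eq.1: log y, or its first difference under the growth form."""
    y = design.eq1["log_y"].to_numpy(float)
    if growth_form:
        y = y - design.eq1["log_y_lag1"].to_numpy(float)
    return y


def joint_loglik(
    params: ParameterSet, design: DesignTable, config: ModelConfig | None = None
) -> float:
    """Gaussian log-likelihood of both equations over their unmasked rows."""
    config = config or ModelConfig()
    m1, m2 = design.mask1, design.mask2
    if not m1.any() or not m2.any():
        raise ValueError("no complete rows in one of the equations")
    if min(params.sigma_u, params.sigma_v) <= 0:
        raise ValueError("likelihood needs strictly positive observation sds")
    y1 = outcome_response(design, config.growth_form)[m1]
    e1 = eta_outcome(params, design, rows=design.eq1.index[m1])
    y2 = design.eq2["log_gini"].to_numpy(float)[m2]
    e2 = eta_gini(params, design, rows=design.eq2.index[m2])
    ll1 = norm.logpdf(y1, e1, params.sigma_u).sum()
    ll2 = norm.logpdf(y2, e2, params.sigma_v).sum()
    return float(ll1 + ll2)


# ---------------------------------------------------------------------------
# prior
# ---------------------------------------------------------------------------

def _require(hyper: dict, name: str) -> float:
    if name not in hyper:
        raise KeyError(f"hyperparameter {name!r} not set on ParameterSet.hyper")
    return float(hyper[name])


def log_prior(
    params: ParameterSet,
    priors: PriorConfig,
    geometry: RegionGeometry,
    config: ModelConfig | None = None,
) -> float:
    """Sum of all prior log-densities at ``params``.

    iid Gaussian for country/region deviations, RW1 for year-indexed
    effects, exact Matérn Gaussian for the spatial fields, Normal(0, sd^2)
    for fixed effects and half-Normal for every sd hyperparameter.
    """
    config = config or ModelConfig()
    h = params.hyper
    lp = 0.0

    fixed = np.concatenate(
        [[params.intercept, params.beta, params.delta0], params.gamma, params.delta]
    )
    lp += norm.logpdf(fixed, 0.0, priors.fixed_sd()).sum()

    def iid_block(values, sd_name):
        sd = _require(h, sd_name)
        return norm.logpdf(values, 0.0, sd).sum() + halfnorm.logpdf(
            sd, scale=priors.sd_scale(sd_name)
        )

    if config.enabled("alpha_region"):
        lp += iid_block(params.alpha_region, "sd_alpha")
    if config.enabled("beta_country"):
        lp += iid_block(params.beta_country, "sd_beta_country")
    if config.enabled("delta0_country"):
        lp += iid_block(params.delta0_country, "sd_delta0_country")

    def rw1_block(values, sd_name):
        sd = _require(h, sd_name)
        eff = RW1Effect(values=np.asarray(values), increment_sd=sd)
        return rw1_logpdf(eff) + halfnorm.logpdf(sd, scale=priors.sd_scale(sd_name))

    if config.enabled("beta_year"):
        lp += rw1_block(params.beta_year, "sd_beta_year")
    if config.enabled("tau_year"):
        lp += rw1_block(params.tau_year, "sd_tau_year")
    if config.enabled("tau_country"):
        sd = _require(h, "sd_tau_country")
        for jrow in params.tau_country_year:
            lp += rw1_logpdf(RW1Effect(values=jrow, increment_sd=sd))
        lp += halfnorm.logpdf(sd, scale=priors.sd_scale("sd_tau_country"))

    if config.enabled("s_region"):
        var = _require(h, "matern_region_var")
        coords = geometry.coords(list(params.regions))
        rng = config.matern_range_region or default_matern_range(coords)
        lp += matern_logpdf(
            params.s_region,
            MaternField(var, rng, config.matern_smoothness, coords),
        ) + halfnorm.logpdf(var, scale=priors.sd_scale("matern_region_var"))
    if config.enabled("s_country"):
        var = _require(h, "matern_country_var")
        cc = geometry.country_centroids().set_index("country_id")
        coords = cc.loc[list(params.countries), ["x", "y"]].to_numpy(float)
        rng = config.matern_range_country or default_matern_range(coords)
        lp += matern_logpdf(
            params.s_country,
            MaternField(var, rng, config.matern_smoothness, coords),
        ) + halfnorm.logpdf(var, scale=priors.sd_scale("matern_country_var"))

    for name, on in (config.gamma_random or {}).items():
        if not on:
            continue
        lp += iid_block(params.gamma_country.get(name, np.zeros(len(params.countries))),
                        f"sd_gamma_{name}_country")
        lp += rw1_block(params.gamma_year.get(name, np.zeros(len(params.years))),
                        f"sd_gamma_{name}_year")

    lp += halfnorm.logpdf(params.sigma_u, scale=priors.sd_scale("sigma_u"))
    lp += halfnorm.logpdf(params.sigma_v, scale=priors.sd_scale("sigma_v"))
    return float(lp)
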