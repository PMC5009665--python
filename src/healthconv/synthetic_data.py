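"""Generative twin of the joint model for fully testable desk-scale panels.

Simulates region geometry, exogenous covariates (stationary AR(1) at
realistic EU magnitudes), a country-level Gini index that is endogenous
(driven by lagged country health outcomes and GDP through the Gini
equation), and the health outcome itself through the outcome equation,
all with a known ParameterSet.  Scenarios add a configurable post-break
dispersion regime (higher region-shock volatility and an attenuated
catching-up coefficient) emulating an austerity-type shock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .latent_fields import MaternField, sample_field
from .model_spec import (
    DELTA_NAMES, GAMMA_NAMES, ModelConfig, ParameterSet, default_matern_range,
)
from .panel_data import (
    PANEL_COLUMNS, PanelTable, RegionGeometry, assemble_design,
    bpg_transform, build_period_dummies,
)

logger = logging.getLogger(__name__)

#: descriptive target levels of the five outcomes (EU regional magnitudes:
#: life expectancy in years, mortality per 100,000)
OUTCOME_LEVELS = {
    "life_expectancy": 78.14,
    "total_mortality": 1003.85,
    "ischemic": 109.49,
    "cancer": 180.58,
    "lung_cancer": 40.21,
}
GINI_LEVEL = 29.65          # 0-100 scale
GDPPC_LEVEL = 19474.5       # purchasing-power standards


@dataclass
class CovariateProcess:
    """Stationary AR(1): x_t = mu + ar (x_{t-1} - mu) + e_t, with the
    innovation sd chosen so the stationary sd equals ``sd``.  Log-scale
    processes are simulated on log(x) and exponentiated."""

    mean: float
    sd: float
    ar: float = 0.8
    log_scale: bool = True

    def innovation_sd(self) -> float:
        return self.sd * np.sqrt(1.0 - self.ar**2)


def default_covariate_processes() -> dict[str, CovariateProcess]:
    """AR(1) settings at observed EU magnitudes (means from the descriptive
    statistics of the 1995-2011 EUROSTAT panel; dispersions on the log scale
    chosen to give realistic cross-sectional spread)."""
    return {
        # country level
        "gdppc": CovariateProcess(np.log(GDPPC_LEVEL), 0.35),
        "randd": CovariateProcess(np.log(1.24), 0.5),
        "bpg": CovariateProcess(-1.43, 6.83, log_scale=False),
        "pubexp": CovariateProcess(np.log(46.52), 0.10),
        "rate": CovariateProcess(2.0, 2.0, log_scale=False),
        # region level
        "empht": CovariateProcess(np.log(488.36), 0.40),
        "univ": CovariateProcess(np.log(22.10), 0.15),
        "umy": CovariateProcess(np.log(18.0), 0.40),
        "ufy": CovariateProcess(np.log(20.07), 0.40),
    }


COUNTRY_COVARIATES = ("gdppc", "randd", "bpg", "pubexp", "rate")
REGION_COVARIATES = ("empht", "univ", "umy", "ufy")

#: default gamma coefficients (GAMMA_NAMES order); small log-log elasticities
DEFAULT_GAMMA = {
    "log_gdppc": 0.01, "log_gdppc_lag1": 0.0, "log_gdppc_lag2": 0.0,
    "log_gini": -0.2, "log_gini_lag1": 0.05, "log_empht": 0.001,
    "log_univ": -0.002, "log_umy": 0.001, "log_ufy": 0.0, "log_randd": 0.005,
    "bpg_t": 0.002, "log_pubexp": 0.01, "d2004": 0.005, "d2007": 0.0,
    "d2008": 0.0,
}
DEFAULT_DELTA = {
    "log_yc_lag1": 0.1, "log_yc_lag2": 0.0, "log_yc_lag3": 0.0,
    "log_gdppc_c_lag1": -0.05, "log_gdppc_c_lag2": 0.0,
    "log_gdppc_c_lag3": 0.0, "rate_lag1": -0.002, "log_gini_lag1": 0.8,
    "d2004": 0.01, "d2007": 0.0, "d2008": 0.0,
}
DEFAULT_EFFECT_SDS = {
    "sd_alpha": 0.01, "sd_beta_country": 0.03, "sd_beta_year": 0.005,
    "sd_tau_year": 0.005, "sd_delta0_country": 0.02, "sd_tau_country": 0.005,
    "matern_region_var": 1e-4, "matern_country_var": 1e-4,
}

BURN_IN_YEARS = 3
SCENARIOS = ("convergent", "divergent_after_break", "crisis_2010")


@dataclass
class SimulationConfig:
    """Study-scale defaults: 27 countries x 10 regions, 1995-2011."""

    n_countries: int = 27
    regions_per_country: int = 10
    year_range: tuple[int, int] = (1995, 2011)
    outcome: str = "life_expectancy"
    beta: float = -0.5
    gamma: dict = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    delta: dict = field(default_factory=lambda: dict(DEFAULT_DELTA))
    sigma_u: float = 0.02
    sigma_v: float = 0.02
    effect_sds: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SDS))
    covariates: dict = field(default_factory=default_covariate_processes)
    missingness: float = 0.05
    init_log_y_sd: float = 0.0      # extra initial displacement from steady state
    break_year: int | None = None
    break_multiplier: float = 1.0   # region-shock sd multiplier from break on
    break_beta_shift: float = 0.0   # year deviation added to beta from break on
    growth_form: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 2 or self.regions_per_country < 2:
            raise ValueError("need >= 2 countries and >= 2 regions per country")
        y0, y1 = self.year_range
        if y1 - y0 + 1 < 6:
            raise ValueError("need >= 6 years (lags up to 3 must exist)")
        if self.break_year is not None and not (y0 <= self.break_year <= y1):
            raise ValueError("break year outside the panel year range")
        if self.outcome not in OUTCOME_LEVELS:
            raise ValueError(
                f"unknown outcome {self.outcome!r}; choose from {sorted(OUTCOME_LEVELS)}"
            )
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness rate must be in [0, 1)")


@dataclass
class SimulatedPanel:
    panel: PanelTable
    geometry: RegionGeometry
    params: ParameterSet
    config: SimulationConfig


def scenario(name: str, base: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """Named convergence scenarios.

    convergent: catching-up dynamics (beta < 0), no dispersion break.
    divergent_after_break: from ``break_year`` (default 2010) the region-shock
    sd is multiplied by ``break_multiplier`` (default 3) and the year
    deviation of beta shifts by +0.4 (the magnitude of reported 2010
    divergence-year deviations), emulating a sharp post-austerity rise in
    disparities: a positive year deviation relaxes the catching-up
    compression of cross-region levels, so dispersion widens from the break
    year on, reinforced one year later by the inflated shocks.
    crisis_2010: divergent_after_break pinned at 2010.
    """
    base = base or SimulationConfig()
    if name == "convergent":
        cfg = replace(base, break_year=None, break_multiplier=1.0,
                      break_beta_shift=0.0, **overrides)
    elif name == "divergent_after_break":
        opts = {"break_year": 2010, "break_multiplier": 3.0,
                "break_beta_shift": 0.4}
        opts.update(overrides)
        cfg = replace(base, **opts)
    elif name == "crisis_2010":
        opts = {"break_multiplier": 3.0, "break_beta_shift": 0.4}
        opts.update(overrides)
        cfg = replace(base, break_year=2010, **opts)
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return cfg


def _draw_centered(rng, sd, n):
    v = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    return v - v.mean()


def _rw1_values(rng, sd, T, constrained=True):
    inc = rng.normal(0.0, sd, T - 1) if sd > 0 else np.zeros(T - 1)
    v = np.concatenate([[0.0], np.cumsum(inc)])
    return v - v.mean() if constrained else v


def _draw_truth(cfg: SimulationConfig, geometry: RegionGeometry,
                regions, countries, years, rng) -> ParameterSet:
    nR, nJ, nT = len(regions), len(countries), len(years)
    sds = cfg.effect_sds
    coords_r = geometry.coords(regions)
    coords_c = geometry.country_centroids().set_index("country_id") \
        .loc[countries, ["x", "y"]].to_numpy(float)

    s_region = np.zeros(nR)
    if sds["matern_region_var"] > 0:
        fld = MaternField(sds["matern_region_var"], default_matern_range(coords_r),
                          1.0, coords_r)
        s_region = sample_field(fld, 1, int(rng.integers(2**31)))[0]
        s_region -= s_region.mean()
    s_country = np.zeros(nJ)
    if sds["matern_country_var"] > 0:
        fld = MaternField(sds["matern_country_var"], default_matern_range(coords_c),
                          1.0, coords_c)
        s_country = sample_field(fld, 1, int(rng.integers(2**31)))[0]
        s_country -= s_country.mean()

    beta_year = _rw1_values(rng, sds["sd_beta_year"], nT)
    tau_year = _rw1_values(rng, sds["sd_tau_year"], nT)
    if cfg.break_year is not None and cfg.break_beta_shift:
        post = years >= cfg.break_year
        # shift beta upward post-break; compensate the level through the
        # temporal trend so the stationary outcome level stays put
        beta_year = beta_year + cfg.break_beta_shift * post
        tau_year = tau_year - cfg.break_beta_shift * post * np.log(
            OUTCOME_LEVELS[cfg.outcome]
        )

    params = ParameterSet(
        regions=regions, countries=countries, years=years,
        intercept=0.0,  # calibrated below
        alpha_region=_draw_centered(rng, sds["sd_alpha"], nR),
        beta=cfg.beta,
        beta_country=_draw_centered(rng, sds["sd_beta_country"], nJ),
        beta_year=beta_year,
        gamma=np.array([cfg.gamma[g] for g in GAMMA_NAMES]),
        s_region=s_region,
        tau_year=tau_year,
        delta0=0.0,
        delta0_country=_draw_centered(rng, sds["sd_delta0_country"], nJ),
        delta=np.array([cfg.delta[d] for d in DELTA_NAMES]),
        s_country=s_country,
        tau_country_year=np.vstack(
            [_rw1_values(rng, sds["sd_tau_country"], nT) for _ in range(nJ)]
        ),
        sigma_u=cfg.sigma_u,
        sigma_v=cfg.sigma_v,
        hyper=dict(sds),
    )

    # intercept calibration: pin the stationary outcome and Gini levels at
    # their target magnitudes given the covariate means
    cov = cfg.covariates
    log_y_star = np.log(OUTCOME_LEVELS[cfg.outcome])
    log_gini_star = np.log(GINI_LEVEL)
    xbar = {
        "log_gdppc": cov["gdppc"].mean, "log_gdppc_lag1": cov["gdppc"].mean,
        "log_gdppc_lag2": cov["gdppc"].mean, "log_gini": log_gini_star,
        "log_gini_lag1": log_gini_star, "log_empht": cov["empht"].mean,
        "log_univ": cov["univ"].mean, "log_umy": cov["umy"].mean,
        "log_ufy": cov["ufy"].mean, "log_randd": cov["randd"].mean,
        "bpg_t": float(bpg_transform(cov["bpg"].mean)),
        "log_pubexp": cov["pubexp"].mean, "d2004": 0.0, "d2007": 0.0, "d2008": 0.0,
    }
    covar_sum = sum(cfg.gamma[g] * xbar[g] for g in GAMMA_NAMES)
    root = 1.0 + cfg.beta if cfg.growth_form else cfg.beta
    params.intercept = (1.0 - root) * log_y_star - covar_sum

    zbar = {
        "log_yc_lag1": log_y_star, "log_yc_lag2": log_y_star,
        "log_yc_lag3": log_y_star, "log_gdppc_c_lag1": cov["gdppc"].mean,
        "log_gdppc_c_lag2": cov["gdppc"].mean, "log_gdppc_c_lag3": cov["gdppc"].mean,
        "rate_lag1": cov["rate"].mean, "log_gini_lag1": log_gini_star,
        "d2004": 0.0, "d2007": 0.0, "d2008": 0.0,
    }
    dsum = sum(cfg.delta[d] * zbar[d] for d in DELTA_NAMES if d != "log_gini_lag1")
    params.delta0 = (1.0 - cfg.delta["log_gini_lag1"]) * log_gini_star - dsum
    return params


def _check_stability(cfg: SimulationConfig, params: ParameterSet) -> None:
    devs = params.beta + params.beta_country[:, None] + params.beta_year[None, :]
    roots = 1.0 + devs if cfg.growth_form else devs
    worst = np.abs(roots).max()
    if worst >= 1.0:
        raise ValueError(
            f"explosive outcome dynamics: max |AR root| = {worst:.3f} >= 1 "
            "(check beta and its deviations)"
        )


def simulate_panel(cfg: SimulationConfig) -> SimulatedPanel:
    """Simulate geometry, covariates, endogenous Gini and outcomes.

    Three pre-sample years are simulated and discarded as burn-in so that
    within-panel lags start from settled dynamics; the outcome is
    initialized at each region's stationary mean (plus an optional
    displacement ``init_log_y_sd``).
    """
    rng = np.random.default_rng(cfg.seed)
    y0, y1 = cfg.year_range
    years = np.arange(y0, y1 + 1)
    sim_years = np.arange(y0 - BURN_IN_YEARS, y1 + 1)
    countries = [f"C{j:02d}" for j in range(cfg.n_countries)]
    regions = [f"C{j:02d}R{i:02d}" for j in range(cfg.n_countries)
               for i in range(cfg.regions_per_country)]
    r2c = {r: r[:3] for r in regions}

    # geometry: country centres uniform in the unit square, regions clustered
    centres = rng.uniform(0.1, 0.9, size=(cfg.n_countries, 2))
    offsets = rng.uniform(-0.05, 0.05, size=(len(regions), 2))
    coords = np.repeat(centres, cfg.regions_per_country, axis=0) + offsets
    geometry = RegionGeometry(pd.DataFrame({
        "region_id": regions, "country_id": [r2c[r] for r in regions],
        "x": coords[:, 0], "y": coords[:, 1],
    }))

    params = _draw_truth(cfg, geometry, regions, countries, years, rng)
    _check_stability(cfg, params)

    cidx = {c: k for k, c in enumerate(countries)}
    ridx = {r: k for k, r in enumerate(regions)}
    yidx = {int(t): k for k, t in enumerate(years)}

    def year_k(t):  # pre-sample years borrow the first panel year's effects
        return yidx.get(int(t), 0)

    # covariate paths -------------------------------------------------------
    def ar_paths(proc: CovariateProcess, n_units: int) -> np.ndarray:
        x = np.empty((n_units, len(sim_years)))
        x[:, 0] = rng.normal(proc.mean, proc.sd, n_units)
        isd = proc.innovation_sd()
        for k in range(1, len(sim_years)):
            x[:, k] = proc.mean + proc.ar * (x[:, k - 1] - proc.mean) \
                + rng.normal(0.0, isd, n_units)
        return np.exp(x) if proc.log_scale else x

    cov_country = {v: ar_paths(cfg.covariates[v], cfg.n_countries)
                   for v in COUNTRY_COVARIATES}
    cov_region = {v: ar_paths(cfg.covariates[v], len(regions))
                  for v in REGION_COVARIATES}

    # dynamic recursion -----------------------------------------------------
    gamma = {g: params.gamma[k] for k, g in enumerate(GAMMA_NAMES)}
    delta = {d: params.delta[k] for k, d in enumerate(DELTA_NAMES)}
    log_y_star = np.log(OUTCOME_LEVELS[cfg.outcome])
    log_gini_star = np.log(GINI_LEVEL)

    nY = len(sim_years)
    log_y = np.empty((len(regions), nY))
    log_gini = np.empty((cfg.n_countries, nY))
    log_yc = np.empty((cfg.n_countries, nY))

    def hist(arr, j, k, fallback):
        return arr[j, k] if k >= 0 else fallback

    # region stationary means for initialization
    init_dev = rng.normal(0.0, cfg.init_log_y_sd, len(regions)) \
        if cfg.init_log_y_sd > 0 else np.zeros(len(regions))

    prev_log_y = None
    for k, t in enumerate(sim_years):
        tk = year_k(t)
        d2004, d2007, d2008 = build_period_dummies(int(t))

        # Gini equation (uses strictly lagged quantities)
        eta2 = np.full(cfg.n_countries, params.delta0)
        for j in range(cfg.n_countries):
            e = (params.delta0_country[j] + params.s_country[j]
                 + params.tau_country_year[j, tk])
            for lag, nm in ((1, "log_yc_lag1"), (2, "log_yc_lag2"), (3, "log_yc_lag3")):
                e += delta[nm] * hist(log_yc, j, k - lag, log_y_star)
            for lag, nm in ((1, "log_gdppc_c_lag1"), (2, "log_gdppc_c_lag2"),
                            (3, "log_gdppc_c_lag3")):
                gk = k - lag
                gv = cov_country["gdppc"][j, gk] if gk >= 0 else cov_country["gdppc"][j, 0]
                e += delta[nm] * np.log(gv)
            rk = k - 1
            rv = cov_country["rate"][j, rk] if rk >= 0 else cfg.covariates["rate"].mean
            e += delta["rate_lag1"] * rv
            e += delta["log_gini_lag1"] * hist(log_gini, j, k - 1, log_gini_star)
            e += delta["d2004"] * d2004 + delta["d2007"] * d2007 + delta["d2008"] * d2008
            eta2[j] += e
        log_gini[:, k] = eta2 + (rng.normal(0.0, cfg.sigma_v, cfg.n_countries)
                                 if cfg.sigma_v > 0 else 0.0)

        # outcome equation
        shock_sd = cfg.sigma_u
        if cfg.break_year is not None and t >= cfg.break_year:
            shock_sd = cfg.sigma_u * cfg.break_multiplier
        eta1 = np.empty(len(regions))
        for r in regions:
            i, j = ridx[r], cidx[r2c[r]]
            beta_eff = params.beta + params.beta_country[j] + params.beta_year[tk]
            x = {
                "log_gdppc": np.log(cov_country["gdppc"][j, k]),
                "log_gdppc_lag1": np.log(cov_country["gdppc"][j, max(k - 1, 0)]),
                "log_gdppc_lag2": np.log(cov_country["gdppc"][j, max(k - 2, 0)]),
                "log_gini": log_gini[j, k],
                "log_gini_lag1": hist(log_gini, j, k - 1, log_gini_star),
                "log_empht": np.log(cov_region["empht"][i, k]),
                "log_univ": np.log(cov_region["univ"][i, k]),
                "log_umy": np.log(cov_region["umy"][i, k]),
                "log_ufy": np.log(cov_region["ufy"][i, k]),
                "log_randd": np.log(cov_country["randd"][j, k]),
                "bpg_t": float(bpg_transform(cov_country["bpg"][j, k])),
                "log_pubexp": np.log(cov_country["pubexp"][j, k]),
                "d2004": d2004, "d2007": d2007, "d2008": d2008,
            }
            if prev_log_y is None:
                # stationary mean given this region's effects and first-year x
                fixed = (params.intercept + params.alpha_region[i]
                         + params.s_region[i] + params.tau_year[tk]
                         + sum(gamma[g] * x[g] for g in GAMMA_NAMES))
                root = 1.0 + beta_eff if cfg.growth_form else beta_eff
                ylag = fixed / (1.0 - root) + init_dev[i]
            else:
                ylag = prev_log_y[i]
            eta1[i] = (params.intercept + params.alpha_region[i]
                       + beta_eff * ylag + params.s_region[i] + params.tau_year[tk]
                       + sum(gamma[g] * x[g] for g in GAMMA_NAMES))
            if cfg.growth_form:
                eta1[i] += ylag
        noise = rng.normal(0.0, shock_sd, len(regions)) if shock_sd > 0 else 0.0
        log_y[:, k] = eta1 + noise
        prev_log_y = log_y[:, k]

        # country mean outcome on the original scale, then log
        yk = np.exp(log_y[:, k]).reshape(cfg.n_countries, cfg.regions_per_country)
        log_yc[:, k] = np.log(yk.mean(axis=1))

    # assemble the panel (burn-in years dropped) ---------------------------
    keep = [k for k, t in enumerate(sim_years) if t >= y0]
    rows = []
    for k in keep:
        t = int(sim_years[k])
        for r in regions:
            i, j = ridx[r], cidx[r2c[r]]
            rows.append({
                "region_id": r, "country_id": r2c[r], "year": t,
                "outcome": np.exp(log_y[i, k]),
                "gdppc": cov_country["gdppc"][j, k],
                "gini": np.exp(log_gini[j, k]),
                "empht": cov_region["empht"][i, k],
                "univ": cov_region["univ"][i, k],
                "umy": cov_region["umy"][i, k],
                "ufy": cov_region["ufy"][i, k],
                "randd": cov_country["randd"][j, k],
                "bpg": cov_country["bpg"][j, k],
                "pubexp": cov_country["pubexp"][j, k],
                "rate": cov_country["rate"][j, k],
            })
    df = pd.DataFrame(rows, columns=PANEL_COLUMNS)

    if cfg.missingness > 0:
        from .panel_data import VALUE_COLUMNS
        mask = rng.random((len(df), len(VALUE_COLUMNS))) < cfg.missingness
        vals = df[VALUE_COLUMNS].to_numpy()
        vals[mask] = np.nan
        df[VALUE_COLUMNS] = vals

    panel = PanelTable(df)
    logger.info("simulated panel: %s", panel.summary())
    return SimulatedPanel(panel=panel, geometry=geometry, params=params, config=cfg)


def noiseless_fitted(sim: SimulatedPanel) -> pd.DataFrame:
    """True-parameter fitted values (the outcome linear predictor evaluated
    at the generating ParameterSet) for every complete outcome-equation row.

    Returns columns region_id, country_id, year, fitted_log, fitted_response.
    """
    from .model_spec import eta_outcome

    design = assemble_design(sim.panel)
    rows = design.eq1.index[design.mask1]
    eta = eta_outcome(sim.params, design, rows=rows)
    if sim.config.growth_form:
        eta = eta + design.eq1.loc[rows, "log_y_lag1"].to_numpy(float)
    out = design.eq1.loc[rows, ["region_id", "country_id", "year"]].copy()
    out["fitted_log"] = eta
    out["fitted_response"] = np.exp(eta)
    return out.reset_index(drop=True)
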