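"""Posterior estimation for the joint model, summaries and diagnostics.

Sampler
-------
Given the variance hyperparameters, every coefficient of the two equations
(fixed effects, region/country intercept deviations, country and year
deviations of the lag coefficient, spatial fields, temporal trends) is
jointly Gaussian, so the sampler is a blocked Gibbs scheme:

1. draw the full coefficient vector from its exact multivariate-normal
   conditional (one Cholesky solve per iteration; the cross-product
   matrices are precomputed once);
2. draw each sd/variance hyperparameter from its univariate conditional by
   slice sampling on the log scale (half-Normal priors are not conjugate).

With all random effects disabled and the observation sds fixed, step 1
draws i.i.d. samples from the exact conjugate Gaussian linear-model
posterior, which is the reference the test suite checks the sampler
against.

Identification: deviation blocks (iid, RW1, spatial) carry a soft
sum-to-zero constraint, implemented as a high-precision Gaussian penalty
on the block sum added to the prior precision.

Convergence: split potential-scale-reduction over >= 2 chains; a fit with
max R-hat above 1.05 is returned with a loud warning flag, never silently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .latent_fields import JITTER_REL, matern_correlation, rw1_structure
from .model_spec import (
    DELTA_NAMES, GAMMA_NAMES, ModelConfig, PriorConfig, default_matern_range,
    outcome_response,
)
from .panel_data import DesignTable, RegionGeometry

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.05


# ---------------------------------------------------------------------------
# block layout
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    name: str
    kind: str                    # fixed | iid | rw1 | matern | rw1_multi
    labels: list
    hyper: str | None = None     # sd/variance hyperparameter name
    sum_zero: bool = False
    structure: np.ndarray | None = None   # DtD for rw1, Rinv for matern
    n_groups: int = 1            # rw1_multi: number of parallel walks
    offset: int = 0

    @property
    def size(self) -> int:
        return len(self.labels)

    @property
    def sl(self) -> slice:
        return slice(self.offset, self.offset + self.size)


def _indicator(codes: np.ndarray, n_levels: int, weight: np.ndarray | None = None):
    Z = np.zeros((len(codes), n_levels))
    Z[np.arange(len(codes)), codes] = 1.0 if weight is None else weight
    return Z


@dataclass
class ModelMatrices:
    """Dense stacked design for both equations plus the prior block layout."""

    blocks: list
    Z1: np.ndarray
    Z2: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    rows1: pd.DataFrame          # ids of complete eq1 rows
    config: ModelConfig
    p: int = 0

    def __post_init__(self) -> None:
        self.p = sum(b.size for b in self.blocks)
        self.labels = [lab for b in self.blocks for lab in b.labels]

    def block(self, name: str) -> _Block:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)


def build_matrices(
    design: DesignTable, geometry: RegionGeometry, config: ModelConfig
) -> ModelMatrices:
    eq1 = design.eq1[design.mask1]
    eq2 = design.eq2[design.mask2]
    if not len(eq1) or not len(eq2):
        raise ValueError("no complete rows in one of the equations")
    panel = design.panel
    regions, countries = panel.regions, panel.countries
    years = panel.years
    ridx = {r: k for k, r in enumerate(regions)}
    cidx = {c: k for k, c in enumerate(countries)}
    yidx = {int(y): k for k, y in enumerate(years)}
    nR, nJ, nT = len(regions), len(countries), len(years)

    r1 = np.array([ridx[r] for r in eq1["region_id"]])
    c1 = np.array([cidx[c] for c in eq1["country_id"]])
    t1 = np.array([yidx[int(y)] for y in eq1["year"]])
    c2 = np.array([cidx[c] for c in eq2["country_id"]])
    t2 = np.array([yidx[int(y)] for y in eq2["year"]])
    ylag = eq1["log_y_lag1"].to_numpy(float)

    blocks: list[_Block] = []
    cols1: list[np.ndarray] = []
    cols2: list[np.ndarray] = []

    def add(block: _Block, X1: np.ndarray | None, X2: np.ndarray | None):
        block.offset = sum(b.size for b in blocks)
        blocks.append(block)
        cols1.append(X1 if X1 is not None else np.zeros((len(eq1), block.size)))
        cols2.append(X2 if X2 is not None else np.zeros((len(eq2), block.size)))

    # eq1 fixed effects
    X1f = np.column_stack(
        [np.ones(len(eq1)), ylag, eq1[GAMMA_NAMES].to_numpy(float)]
    )
    add(_Block("fixed_eq1", "fixed",
               ["intercept", "beta"] + [f"gamma_{g}" for g in GAMMA_NAMES]),
        X1f, None)

    if config.enabled("alpha_region"):
        add(_Block("alpha_region", "iid", [f"alpha_{r}" for r in regions],
                   hyper="sd_alpha", sum_zero=True),
            _indicator(r1, nR), None)
    if config.enabled("beta_country"):
        add(_Block("beta_country", "iid", [f"beta_country_{c}" for c in countries],
                   hyper="sd_beta_country", sum_zero=True),
            _indicator(c1, nJ, weight=ylag), None)
    if config.enabled("beta_year"):
        add(_Block("beta_year", "rw1", [f"beta_year_{y}" for y in years],
                   hyper="sd_beta_year", sum_zero=True, structure=rw1_structure(nT)),
            _indicator(t1, nT, weight=ylag), None)
    if config.enabled("s_region"):
        coords = geometry.coords(regions)
        rng_ = config.matern_range_region or default_matern_range(coords)
        R = matern_correlation(
            np.hypot(*(coords[:, None, :] - coords[None, :, :]).transpose(2, 0, 1)),
            rng_, config.matern_smoothness,
        ) + JITTER_REL * np.eye(nR)
        add(_Block("s_region", "matern", [f"s_region_{r}" for r in regions],
                   hyper="matern_region_var", sum_zero=True,
                   structure=np.linalg.inv(R)),
            _indicator(r1, nR), None)
    if config.enabled("tau_year"):
        add(_Block("tau_year", "rw1", [f"tau_year_{y}" for y in years],
                   hyper="sd_tau_year", sum_zero=True, structure=rw1_structure(nT)),
            _indicator(t1, nT), None)
    for gname, on in (config.gamma_random or {}).items():
        if not on:
            continue
        xg = eq1[gname].to_numpy(float)
        add(_Block(f"gamma_{gname}_country", "iid",
                   [f"gamma_{gname}_country_{c}" for c in countries],
                   hyper=f"sd_gamma_{gname}_country", sum_zero=True),
            _indicator(c1, nJ, weight=xg), None)
        add(_Block(f"gamma_{gname}_year", "rw1",
                   [f"gamma_{gname}_year_{y}" for y in years],
                   hyper=f"sd_gamma_{gname}_year", sum_zero=True,
                   structure=rw1_structure(nT)),
            _indicator(t1, nT, weight=xg), None)

    # eq2 fixed effects
    X2f = np.column_stack(
        [np.ones(len(eq2)), eq2[DELTA_NAMES].to_numpy(float)]
    )
    add(_Block("fixed_eq2", "fixed",
               ["delta0"] + [f"delta_{d}" for d in DELTA_NAMES]),
        None, X2f)

    if config.enabled("delta0_country"):
        add(_Block("delta0_country", "iid",
                   [f"delta0_country_{c}" for c in countries],
                   hyper="sd_delta0_country", sum_zero=True),
            None, _indicator(c2, nJ))
    if config.enabled("s_country"):
        cc = geometry.country_centroids().set_index("country_id")
        coords = cc.loc[countries, ["x", "y"]].to_numpy(float)
        rng_ = config.matern_range_country or default_matern_range(coords)
        R = matern_correlation(
            np.hypot(*(coords[:, None, :] - coords[None, :, :]).transpose(2, 0, 1)),
            rng_, config.matern_smoothness,
        ) + JITTER_REL * np.eye(nJ)
        add(_Block("s_country", "matern", [f"s_country_{c}" for c in countries],
                   hyper="matern_country_var", sum_zero=True,
                   structure=np.linalg.inv(R)),
            None, _indicator(c2, nJ))
    if config.enabled("tau_country"):
        labels = [f"tau_{c}_{y}" for c in countries for y in years]
        Z = np.zeros((len(eq2), nJ * nT))
        Z[np.arange(len(eq2)), c2 * nT + t2] = 1.0
        add(_Block("tau_country", "rw1_multi", labels,
                   hyper="sd_tau_country", sum_zero=True,
                   structure=rw1_structure(nT), n_groups=nJ),
            None, Z)

    Z1 = np.hstack(cols1)
    Z2 = np.hstack(cols2)
    y1 = outcome_response(design, config.growth_form)[design.mask1]
    y2 = eq2["log_gini"].to_numpy(float)
    rows1 = eq1[["region_id", "country_id", "year", "log_y_lag1"]].reset_index(drop=True)
    return ModelMatrices(blocks=blocks, Z1=Z1, Z2=Z2, y1=y1, y2=y2,
                         rows1=rows1, config=config)


def _prior_precision(mm: ModelMatrices, hypers: dict, priors: PriorConfig) -> np.ndarray:
    P = np.zeros((mm.p, mm.p))
    c = priors.constraint_precision
    for b in mm.blocks:
        sl = b.sl
        if b.kind == "fixed":
            P[sl, sl] += np.eye(b.size) / priors.fixed_sd() ** 2
            continue
        if b.kind == "iid":
            P[sl, sl] += np.eye(b.size) / hypers[b.hyper] ** 2
        elif b.kind == "rw1":
            P[sl, sl] += b.structure / hypers[b.hyper] ** 2
        elif b.kind == "matern":
            P[sl, sl] += b.structure / hypers[b.hyper]
        elif b.kind == "rw1_multi":
            nT = b.size // b.n_groups
            Q = b.structure / hypers[b.hyper] ** 2 + c * np.ones((nT, nT)) / nT
            for g in range(b.n_groups):
                gsl = slice(b.offset + g * nT, b.offset + (g + 1) * nT)
                P[gsl, gsl] += Q
            continue
        if b.sum_zero:
            P[sl, sl] += c * np.ones((b.size, b.size)) / b.size
    return P


# ---------------------------------------------------------------------------
# slice sampler for hyperparameters
# ---------------------------------------------------------------------------

def _slice_sample(logf, x0: float, rng, w: float = 1.0, max_steps: int = 50) -> float:
    """Univariate stepping-out slice sampler (Neal 2003)."""
    f0 = logf(x0)
    logu = f0 + np.log(rng.random())
    left = x0 - w * rng.random()
    right = left + w
    for _ in range(max_steps):
        if logf(left) < logu:
            break
        left -= w
    for _ in range(max_steps):
        if logf(right) < logu:
            break
        right += w
    for _ in range(200):
        x = rng.uniform(left, right)
        if logf(x) >= logu:
            return x
        if x < x0:
            left = x
        else:
            right = x
    return x0  # pragma: no cover - degenerate shrinkage


def _sd_conditional(n_eff: float, ss: float, scale: float):
    """log conditional of log(sd) given a Gaussian block: N(0, sd^2) terms
    plus a half-Normal(scale) prior and the log-scale Jacobian."""

    def logf(x):
        s = np.exp(x)
        return -n_eff * x - ss / (2.0 * s * s) - s * s / (2.0 * scale * scale) + x

    return logf


def _var_conditional(n_eff: float, ss: float, scale: float):
    """Same for a variance parameter sampled on log(variance)."""

    def logf(x):
        v = np.exp(x)
        return -0.5 * n_eff * x - ss / (2.0 * v) - v * v / (2.0 * scale * scale) + x

    return logf


def _block_ss(b: _Block, theta: np.ndarray) -> tuple[float, float]:
    """(effective n, sum of squares) entering the sd conditional of a block."""
    v = theta[b.sl]
    if b.kind == "iid":
        return len(v), float(v @ v)
    if b.kind == "rw1":
        d = np.diff(v)
        return len(d), float(d @ d)
    if b.kind == "rw1_multi":
        nT = b.size // b.n_groups
        d = np.diff(v.reshape(b.n_groups, nT), axis=1)
        return d.size, float((d * d).sum())
    if b.kind == "matern":
        return len(v), float(v @ b.structure @ v)
    raise ValueError(b.kind)


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Posterior summaries, fitted values and sampler metadata."""

    summaries: pd.DataFrame      # index: parameter; mean, sd, q2.5, q97.5
    fitted: pd.DataFrame         # region_id, country_id, year, fitted_log, fitted_response
    dic: float
    p_eff: float
    deviance_draws: np.ndarray
    draws: dict                  # name -> (n_draws,) array for key scalars
    theta_draws: np.ndarray      # (n_draws, p) coefficient draws
    labels: list
    config: ModelConfig
    n_chains: int
    n_draws: int
    seed: int
    rhat_max: float
    converged: bool
    sigma_u_hat: float
    sigma_v_hat: float

    def param(self, name: str) -> pd.Series:
        return self.summaries.loc[name]

    def interval(self, name: str) -> tuple[float, float]:
        row = self.summaries.loc[name]
        return float(row["q2.5"]), float(row["q97.5"])


def _summarize(samples: np.ndarray) -> tuple[float, float, float, float]:
    return (
        float(np.mean(samples)), float(np.std(samples, ddof=1)),
        float(np.quantile(samples, 0.025)), float(np.quantile(samples, 0.975)),
    )


def _split_rhat(chains: np.ndarray) -> float:
    """Split potential scale reduction for one scalar; chains (m, n)."""
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return np.nan
    sub = chains[:, : 2 * half].reshape(2 * m, half)
    means = sub.mean(axis=1)
    W = sub.var(axis=1, ddof=1).mean()
    B = half * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def fit_joint_model(
    design: DesignTable,
    geometry: RegionGeometry,
    priors: PriorConfig | None = None,
    draws: int = 1000,
    seed: int = 0,
    config: ModelConfig | None = None,
    chains: int = 2,
    burn: int | None = None,
    fix_sigma: dict | None = None,
) -> FitResult:
    """Blocked-Gibbs posterior fit of the joint two-equation model.

    ``draws`` is the number of retained draws per chain after ``burn``
    (default: half of draws).  ``fix_sigma`` may pin ``sigma_u``/``sigma_v``
    at known values (used by the conjugate reference check).
    """
    priors = priors or PriorConfig()
    config = config or ModelConfig()
    if draws < 2:
        raise ValueError("need at least 2 draws")
    if draws < 500:
        logger.warning("draws=%d is below the recommended minimum of 500", draws)
    burn = draws // 2 if burn is None else burn
    fix_sigma = fix_sigma or {}

    if config.latent_gini:
        design = _plug_in_latent_gini(design, geometry, priors, seed, config)

    mm = build_matrices(design, geometry, config)
    n1, n2, p = len(mm.y1), len(mm.y2), mm.p
    ZtZ1 = mm.Z1.T @ mm.Z1
    ZtZ2 = mm.Z2.T @ mm.Z2
    Zty1 = mm.Z1.T @ mm.y1
    Zty2 = mm.Z2.T @ mm.y2

    hyper_names = sorted({b.hyper for b in mm.blocks if b.hyper})
    all_theta, all_hyper, all_dev = [], [], []

    for chain in range(chains):
        rng = np.random.default_rng([seed, chain])
        hypers = {h: (0.5 * priors.sd_scale(h)) ** (2 if "var" in h else 1)
                  for h in hyper_names}
        sigma_u = fix_sigma.get("sigma_u", 0.1)
        sigma_v = fix_sigma.get("sigma_v", 0.1)
        th_chain = np.empty((draws, p))
        hy_chain = {h: np.empty(draws) for h in hyper_names}
        su_chain = np.empty(draws)
        sv_chain = np.empty(draws)
        dev_chain = np.empty(draws)

        for it in range(burn + draws):
            A = ZtZ1 / sigma_u**2 + ZtZ2 / sigma_v**2 + _prior_precision(mm, hypers, priors)
            bvec = Zty1 / sigma_u**2 + Zty2 / sigma_v**2
            L = cholesky(A, lower=True)
            mean = cho_solve((L, True), bvec)
            z = rng.standard_normal(p)
            theta = mean + solve_triangular(L.T, z, lower=False)

            r1 = mm.y1 - mm.Z1 @ theta
            r2 = mm.y2 - mm.Z2 @ theta
            if "sigma_u" not in fix_sigma:
                logf = _sd_conditional(n1, float(r1 @ r1), priors.sd_scale("sigma_u"))
                sigma_u = float(np.exp(_slice_sample(logf, np.log(sigma_u), rng)))
            if "sigma_v" not in fix_sigma:
                logf = _sd_conditional(n2, float(r2 @ r2), priors.sd_scale("sigma_v"))
                sigma_v = float(np.exp(_slice_sample(logf, np.log(sigma_v), rng)))
            for b in mm.blocks:
                if b.hyper is None:
                    continue
                n_eff, ss = _block_ss(b, theta)
                if "var" in b.hyper:
                    logf = _var_conditional(n_eff, ss, priors.sd_scale(b.hyper))
                else:
                    logf = _sd_conditional(n_eff, ss, priors.sd_scale(b.hyper))
                hypers[b.hyper] = float(
                    np.exp(_slice_sample(logf, np.log(hypers[b.hyper]), rng))
                )

            if it >= burn:
                k = it - burn
                th_chain[k] = theta
                for h in hyper_names:
                    hy_chain[h][k] = hypers[h]
                su_chain[k] = sigma_u
                sv_chain[k] = sigma_v
                dev_chain[k] = -2.0 * (
                    _gauss_ll(r1, sigma_u) + _gauss_ll(r2, sigma_v)
                )

        all_theta.append(th_chain)
        all_hyper.append({**hy_chain, "sigma_u": su_chain, "sigma_v": sv_chain})
        all_dev.append(dev_chain)

    theta_draws = np.vstack(all_theta)
    dev_draws = np.concatenate(all_dev)
    hyper_draws = {
        h: np.concatenate([c[h] for c in all_hyper])
        for h in list(hyper_names) + ["sigma_u", "sigma_v"]
    }

    # convergence ----------------------------------------------------------
    rhat_max = 0.0
    if chains >= 2 and draws >= 4:
        for k in range(p):
            r = _split_rhat(np.stack([c[:, k] for c in all_theta]))
            if np.isfinite(r):
                rhat_max = max(rhat_max, r)
        for h in hyper_draws:
            if h in fix_sigma:
                continue
            r = _split_rhat(np.stack([c[h] for c in all_hyper]))
            if np.isfinite(r):
                rhat_max = max(rhat_max, r)
    converged = rhat_max <= RHAT_THRESHOLD or chains < 2
    if not converged:
        warnings.warn(
            f"sampler may not have converged: max split R-hat = {rhat_max:.3f} "
            f"> {RHAT_THRESHOLD}", stacklevel=2,
        )

    # summaries -------------------------------------------------------------
    rows = {}
    for k, lab in enumerate(mm.labels):
        rows[lab] = _summarize(theta_draws[:, k])
    for h, s in hyper_draws.items():
        rows[h] = _summarize(s)
    summaries = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean", "sd", "q2.5", "q97.5"]
    )

    theta_mean = theta_draws.mean(axis=0)
    su_hat = float(hyper_draws["sigma_u"].mean())
    sv_hat = float(hyper_draws["sigma_v"].mean())
    r1 = mm.y1 - mm.Z1 @ theta_mean
    r2 = mm.y2 - mm.Z2 @ theta_mean
    dev_hat = -2.0 * (_gauss_ll(r1, su_hat) + _gauss_ll(r2, sv_hat))
    dic, p_eff = compute_dic(dev_draws, dev_hat)

    fitted_log = mm.Z1 @ theta_mean
    if config.growth_form:
        fitted_log = fitted_log + mm.rows1["log_y_lag1"].to_numpy(float)
    fitted = mm.rows1[["region_id", "country_id", "year"]].copy()
    fitted["fitted_log"] = fitted_log
    fitted["fitted_response"] = np.exp(fitted_log)

    return FitResult(
        summaries=summaries, fitted=fitted, dic=dic, p_eff=p_eff,
        deviance_draws=dev_draws, draws=hyper_draws, theta_draws=theta_draws,
        labels=mm.labels, config=config, n_chains=chains, n_draws=draws,
        seed=seed, rhat_max=rhat_max, converged=converged,
        sigma_u_hat=su_hat, sigma_v_hat=sv_hat,
    )


def _gauss_ll(resid: np.ndarray, sd: float) -> float:
    n = len(resid)
    return float(-0.5 * n * np.log(2 * np.pi) - n * np.log(sd)
                 - (resid @ resid) / (2 * sd * sd))


def _plug_in_latent_gini(design, geometry, priors, seed, config) -> DesignTable:
    """Two-stage latent-Gini variant: replace eq.1's observed log-Gini
    regressors with posterior-mean fitted values from a Gini-equation-only
    preliminary fit."""
    pre_cfg = replace(
        config, latent_gini=False,
        random_effects={**config.random_effects, "alpha_region": False,
                        "beta_country": False, "beta_year": False,
                        "s_region": False, "tau_year": False},
    )
    pre = fit_joint_model(design, geometry, priors, draws=500, seed=seed,
                          config=pre_cfg, chains=1)
    mm = build_matrices(design, geometry, pre_cfg)
    theta = pre.theta_draws.mean(axis=0)
    eta2 = mm.Z2 @ theta
    eq2 = design.eq2[design.mask2]
    fit_map = {(c, int(y)): e for c, y, e in zip(eq2["country_id"], eq2["year"], eta2)}
    eq1 = design.eq1.copy()
    lg = np.array([fit_map.get((c, int(y)), np.nan)
                   for c, y in zip(eq1["country_id"], eq1["year"])])
    lg1 = np.array([fit_map.get((c, int(y) - 1), np.nan)
                    for c, y in zip(eq1["country_id"], eq1["year"])])
    keep = ~np.isnan(lg) & ~np.isnan(lg1)
    eq1.loc[keep, "log_gini"] = lg[keep]
    eq1.loc[keep, "log_gini_lag1"] = lg1[keep]
    mask1 = design.mask1 & keep
    return DesignTable(eq1=eq1, mask1=mask1, eq2=design.eq2,
                       mask2=design.mask2, panel=design.panel)


# ---------------------------------------------------------------------------
# summaries, DIC, diagnostics
# ---------------------------------------------------------------------------

def classify_significance(
    mean: float, sd: float | None = None,
    quantiles: tuple[float, float] | None = None,
) -> str:
    """'significant' iff the 95% interval excludes zero.

    Quantile mode (authoritative for internal fits) uses the posterior
    2.5/97.5 percentiles; summary mode uses the normal approximation
    mean +/- 1.96 sd, matching how published tables print mean (sd) pairs.
    A printed sd of exactly 0 (rounded) gives a degenerate interval:
    significant iff the mean is nonzero.
    """
    if quantiles is not None:
        lo, hi = quantiles
        if lo > hi:
            raise ValueError("quantiles must be ordered")
        return "significant" if (lo > 0 or hi < 0) else "not_significant"
    if sd is None:
        raise ValueError("provide sd or quantiles")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    return "significant" if (lo > 0 or hi < 0) else "not_significant"


def compute_dic(deviance_draws: np.ndarray, deviance_at_mean: float) -> tuple[float, float]:
    """DIC = Dbar + p_eff with p_eff = Dbar - D(posterior mean)."""
    d = np.asarray(deviance_draws, float)
    if len(d) < 2:
        raise ValueError("need >= 2 deviance draws")
    dbar = float(d.mean())
    p_eff = dbar - float(deviance_at_mean)
    return dbar + p_eff, p_eff


@dataclass
class DiagnosticsReport:
    """Residual checks mirroring the weak-exogeneity requirements: no
    temporal or spatial autocorrelation in standardized residuals, and no
    contemporary correlation between residuals and any regressor."""

    region_acf1: pd.DataFrame        # region_id, acf1, n, flag
    moran_by_year: pd.DataFrame      # year, moran_i, n, flag
    cross_correlation: pd.DataFrame  # regressor, r, n, flag
    skipped_regions: list = field(default_factory=list)

    def any_flag(self) -> bool:
        return bool(
            self.region_acf1["flag"].any()
            or self.moran_by_year["flag"].any()
            or self.cross_correlation["flag"].any()
        )


def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return 0.0
    return float((x[1:] @ x[:-1]) / denom)


def residual_diagnostics(
    fit: FitResult, design: DesignTable, geometry: RegionGeometry
) -> DiagnosticsReport:
    """Standardized-residual battery with |statistic| > 2/sqrt(n) flags."""
    eq1 = design.eq1[design.mask1].reset_index(drop=True)
    resid = (
        outcome_response(design, fit.config.growth_form)[design.mask1]
        - fit.fitted["fitted_log"].to_numpy(float)
    ) / fit.sigma_u_hat

    rows, skipped = [], []
    for rid, grp in pd.DataFrame(
        {"region_id": eq1["region_id"], "year": eq1["year"], "r": resid}
    ).groupby("region_id", sort=True):
        g = grp.sort_values("year")
        if len(g) < 3:
            skipped.append(rid)
            continue
        a = _lag1_autocorr(g["r"].to_numpy())
        rows.append({"region_id": rid, "acf1": a, "n": len(g),
                     "flag": abs(a) > 2 / np.sqrt(len(g))})
    region_acf1 = pd.DataFrame(rows, columns=["region_id", "acf1", "n", "flag"])

    myears = []
    for year, grp in pd.DataFrame(
        {"region_id": eq1["region_id"], "year": eq1["year"], "r": resid}
    ).groupby("year", sort=True):
        if len(grp) < 3:
            continue
        coords = geometry.coords(list(grp["region_id"]))
        d = np.hypot(*(coords[:, None, :] - coords[None, :, :]).transpose(2, 0, 1))
        with np.errstate(divide="ignore"):
            W = 1.0 / d
        np.fill_diagonal(W, 0.0)
        W[~np.isfinite(W)] = 0.0
        rs = W.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        W = W / rs
        r = grp["r"].to_numpy()
        r = r - r.mean()
        denom = float(r @ r)
        mi = float(r @ W @ r / denom) if denom > 0 else 0.0
        myears.append({"year": int(year), "moran_i": mi, "n": len(grp),
                       "flag": abs(mi) > 2 / np.sqrt(len(grp))})
    moran = pd.DataFrame(myears, columns=["year", "moran_i", "n", "flag"])

    xrows = []
    for col in DesignTable.EQ1_REGRESSORS:
        x = eq1[col].to_numpy(float)
        if np.std(x) == 0:
            continue
        r = float(np.corrcoef(x, resid)[0, 1])
        xrows.append({"regressor": col, "r": r, "n": len(x),
                      "flag": abs(r) > 2 / np.sqrt(len(x))})
    xcorr = pd.DataFrame(xrows, columns=["regressor", "r", "n", "flag"])

    return DiagnosticsReport(region_acf1=region_acf1, moran_by_year=moran,
                             cross_correlation=xcorr, skipped_regions=skipped)


#: map random-effect switch -> its sd/variance hyperparameter
EFFECT_HYPER = {
    "alpha_region": "sd_alpha", "beta_country": "sd_beta_country",
    "beta_year": "sd_beta_year", "s_region": "matern_region_var",
    "tau_year": "sd_tau_year", "delta0_country": "sd_delta0_country",
    "s_country": "matern_country_var", "tau_country": "sd_tau_country",
}


def variance_test(
    fit_full: FitResult, fit_reduced: FitResult, effect: str,
    negligibility: float = 0.01,
) -> str:
    """Keep a random effect only if its variance is credibly non-negligible.

    keep_random iff the 95% interval of the effect's sd excludes values
    below ``negligibility`` times the outcome residual sd AND the full
    model's DIC beats the reduced one; otherwise collapse_to_fixed.
    """
    cf, cr = fit_full.config.random_effects, fit_reduced.config.random_effects
    diff = {k for k in set(cf) | set(cr) if cf.get(k, False) != cr.get(k, False)}
    if diff != {effect}:
        raise ValueError(
            f"fits must differ only in {effect!r}; they differ in {sorted(diff) or 'nothing'}"
        )
    if not cf.get(effect, False):
        raise ValueError("fit_full must be the one including the effect")
    hyper = EFFECT_HYPER[effect]
    lo, hi = fit_full.interval(hyper)
    if "var" in hyper:  # variance parameter: compare on the sd scale
        lo = np.sqrt(max(lo, 0.0))
    threshold = negligibility * fit_full.sigma_u_hat
    if lo > threshold and fit_full.dic < fit_reduced.dic:
        return "keep_random"
    return "collapse_to_fixed"


def prior_sensitivity(
    design: DesignTable,
    geometry: RegionGeometry,
    priors: PriorConfig,
    scale_factors: list,
    **fit_kwargs,
) -> pd.DataFrame:
    """Refit under tightened priors; max posterior-mean shift per fixed effect.

    ``scale_factors`` multiply every prior precision; 1.0 must be included
    as the reference.
    """
    if 1.0 not in scale_factors:
        raise ValueError("scale_factors must include the reference factor 1.0")
    fits: dict[float, FitResult | Exception] = {}
    for f in scale_factors:
        pr = replace(priors, precision_scale=priors.precision_scale * f)
        try:
            fits[f] = fit_joint_model(design, geometry, pr, **fit_kwargs)
        except Exception as e:  # noqa: BLE001 - propagate per-factor, others continue
            logger.error("fit failed at precision factor %s: %s", f, e)
            fits[f] = e
    ref = fits[1.0]
    if isinstance(ref, Exception):
        raise ref
    fixed = [lab for lab in ref.labels
             if lab.startswith(("intercept", "beta", "gamma_", "delta"))
             and "country" not in lab and "year" not in lab]
    rows = []
    for lab in fixed:
        shifts = {}
        for f, fit in fits.items():
            if f == 1.0 or isinstance(fit, Exception):
                continue
            shifts[f] = abs(float(fit.summaries.loc[lab, "mean"])
                            - float(ref.summaries.loc[lab, "mean"]))
        rows.append({
            "parameter": lab,
            "max_abs_shift": max(shifts.values()) if shifts else np.nan,
            "reference_mean": float(ref.summaries.loc[lab, "mean"]),
        })
    return pd.DataFrame(rows)
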