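"""Latent Gaussian building blocks: iid effects, RW1 year effects, Matérn fields.

The spatial term is a Gaussian field with Matérn covariance evaluated
exactly on the region centroids (dense covariance).  At a few hundred sites
the dense factorization is cheap and is exactly the quantity that sparse
SPDE/GMRF constructions approximate, so no mesh machinery is needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.spatial.distance import cdist
from scipy.special import gammaln, kv
from scipy.stats import norm

from .panel_data import RegionGeometry

logger = logging.getLogger(__name__)

#: relative jitter added to covariance diagonals before factorization
JITTER_REL = 1e-8


@dataclass
class IIDEffect:
    """Exchangeable Gaussian deviations at a given grouping level."""

    level: str  # "country" or "region"
    values: np.ndarray
    sd: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.isfinite(self.values).all():
            raise ValueError("iid effect values must be finite")
        if self.sd <= 0:
            raise ValueError("iid effect sd must be positive")

    def logpdf(self) -> float:
        return float(norm.logpdf(self.values, 0.0, self.sd).sum())


@dataclass
class RW1Effect:
    """First-order random-walk effect over an ordered year index.

    The level is unidentified (the density depends only on increments); the
    sum-to-zero flag records whether the vector has been mean-centred.
    """

    values: np.ndarray
    increment_sd: float
    constrained: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if len(self.values) < 2:
            raise ValueError("RW1 effect needs at least 2 years")
        if self.increment_sd <= 0:
            raise ValueError("increment sd must be positive")
        if self.constrained and abs(self.values.sum()) > 1e-10:
            raise ValueError("constrained RW1 effect must sum to zero")


@dataclass
class MaternField:
    """Stationary Matérn Gaussian field on region (or country) centroids."""

    variance: float
    range_: float
    smoothness: float = 1.0
    sites: np.ndarray | RegionGeometry = field(default=None)

    def __post_init__(self) -> None:
        if min(self.variance, self.range_, self.smoothness) <= 0:
            raise ValueError("variance, range and smoothness must be positive")
        if isinstance(self.sites, RegionGeometry):
            self.sites = self.sites.coords(list(self.sites.df["region_id"]))
        self.sites = np.atleast_2d(np.asarray(self.sites, float))


def matern_correlation(d: np.ndarray, range_: float, smoothness: float) -> np.ndarray:
    """Matérn correlation rho(d) = 2^{1-nu}/Gamma(nu) (kappa d)^nu K_nu(kappa d)
    with kappa = sqrt(2 nu)/range; rho(0)=1.  For nu=1/2 this is exp(-d/range).
    """
    d = np.asarray(d, float)
    nu = smoothness
    kappa = np.sqrt(2.0 * nu) / range_
    x = kappa * d
    out = np.ones_like(x)
    pos = x > 0
    with np.errstate(over="ignore"):
        out[pos] = np.exp(
            (1.0 - nu) * np.log(2.0) - gammaln(nu) + nu * np.log(x[pos])
        ) * kv(nu, x[pos])
    # K_nu underflows to 0 at large distance; that is the correct limit
    return np.nan_to_num(out, nan=0.0)


def matern_covariance(fld: MaternField) -> np.ndarray:
    """Dense site-by-site Matérn covariance matrix; C(0) = variance."""
    d = cdist(fld.sites, fld.sites)
    n = len(fld.sites)
    if n > 1:
        off = d[~np.eye(n, dtype=bool)]
        if (off == 0).any():
            warnings.warn("coincident distinct sites: perfect correlation", stacklevel=2)
    C = fld.variance * matern_correlation(d, fld.range_, fld.smoothness)
    return 0.5 * (C + C.T)


def _chol_with_jitter(C: np.ndarray, variance: float) -> np.ndarray:
    jitter = JITTER_REL * variance
    try:
        return cholesky(C + jitter * np.eye(len(C)), lower=True)
    except np.linalg.LinAlgError as e:  # pragma: no cover - rare numerics
        raise np.linalg.LinAlgError(
            "covariance not positive definite after jitter; increase jitter "
            "or reduce the range/coincident sites"
        ) from e


def sample_field(fld: MaternField, n: int, seed: int) -> np.ndarray:
    """Draw n zero-mean realizations of the field; rows are draws."""
    C = matern_covariance(fld)
    L = _chol_with_jitter(C, fld.variance)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(C)))
    return z @ L.T


def matern_logpdf(values: np.ndarray, fld: MaternField) -> float:
    """Zero-mean Gaussian log-density of field values under the Matérn prior."""
    C = matern_covariance(fld)
    L = _chol_with_jitter(C, fld.variance)
    v = np.asarray(values, float)
    w = solve_triangular(L, v, lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    n = len(v)
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + w @ w))


def rw1_logpdf(effect: RW1Effect) -> float:
    """Log-density of the T-1 independent RW1 increments.

    Invariant to adding a constant to all values: the level is improper and
    carries no density (the sum-to-zero constraint, when used, only fixes
    the level).
    """
    inc = np.diff(effect.values)
    return float(norm.logpdf(inc, 0.0, effect.increment_sd).sum())


def sample_rw1(
    T: int, increment_sd: float, seed: int, constrained: bool = True
) -> RW1Effect:
    """Cumulative sum of iid Gaussian increments, optionally mean-centred."""
    if T < 2:
        raise ValueError("RW1 needs T >= 2")
    rng = np.random.default_rng(seed)
    inc = rng.normal(0.0, increment_sd, size=T - 1) if increment_sd > 0 else np.zeros(T - 1)
    values = np.concatenate([[0.0], np.cumsum(inc)])
    if constrained:
        values = values - values.mean()
    sd = increment_sd if increment_sd > 0 else np.finfo(float).tiny
    return RW1Effect(values=values, increment_sd=max(increment_sd, np.finfo(float).tiny),
                     constrained=constrained)


def rw1_structure(T: int) -> np.ndarray:
    """Unscaled RW1 structure matrix D'D (rank T-1), D the first-difference
    operator; the prior precision of an RW1 block is D'D / increment_sd^2."""
    D = np.diff(np.eye(T), axis=0)
    return D.T @ D
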