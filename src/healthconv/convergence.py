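"""Convergence analytics: beta-convergence classification and sigma-convergence.

beta-convergence: the outcome's dependence on its own lag is negative and
credibly nonzero, so regions behind their steady state catch up.  Country
and year deviations of the lag coefficient localize the statement: a
negative significant country deviation marks a below-average rate of
convergence, a positive significant year deviation marks a divergence
year.

sigma-convergence: the per-year cross-region coefficient of variation of
model fitted values (response scale by default).  A sustained rise of the
CV after a candidate year is a dispersion break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import FitResult, classify_significance

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# coefficient of variation
# ---------------------------------------------------------------------------

def coefficient_of_variation(values) -> float:
    """Sample sd (n-1 denominator) over the mean; requires a positive mean.

    Scale-invariant: cv(c x) = cv(x) for c > 0.
    """
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("CV needs at least 2 values")
    m = v.mean()
    if m <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / m)


@dataclass
class CVSeries:
    """Per-year cross-region CV of fitted values (the sigma-convergence object)."""

    series: pd.Series            # index: year, values: cv
    n_regions: pd.Series
    scale: str = "response"      # response | log
    omitted_years: list = field(default_factory=list)

    @property
    def years(self) -> np.ndarray:
        return self.series.index.to_numpy(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.series.index.astype(int),
            "cv": self.series.to_numpy(float),
            "n_regions": self.n_regions.to_numpy(int),
        })


def sigma_convergence(
    fit: FitResult | pd.DataFrame,
    panel=None,
    log_scale: bool = False,
) -> CVSeries:
    """CV across regions, per year, of the model's fitted outcome values.

    Accepts a FitResult or any fitted-value table with columns region_id,
    year, fitted_log (e.g. true-parameter fitted paths from the synthetic
    generator).  Response scale exponentiates the posterior-mean log fit;
    years with fewer than 2 fitted regions are omitted with a note.
    """
    fitted = fit.fitted if isinstance(fit, FitResult) else fit
    col = "fitted_log" if log_scale else "fitted_response"
    df = fitted.copy()
    if col == "fitted_response" and "fitted_response" not in df.columns:
        df["fitted_response"] = np.exp(df["fitted_log"])
    cvs, ns, omitted = {}, {}, []
    for year, grp in df.groupby("year", sort=True):
        if len(grp) < 2:
            omitted.append(int(year))
            continue
        cvs[int(year)] = coefficient_of_variation(grp[col].to_numpy(float))
        ns[int(year)] = len(grp)
    if omitted:
        logger.info("sigma_convergence: years omitted (<2 regions): %s", omitted)
    return CVSeries(
        series=pd.Series(cvs, dtype=float),
        n_regions=pd.Series(ns, dtype=int),
        scale="log" if log_scale else "response",
        omitted_years=omitted,
    )


# ---------------------------------------------------------------------------
# break detection
# ---------------------------------------------------------------------------

@dataclass
class BreakReport:
    year: int
    jump: float
    significant: bool
    threshold: float
    all_jumps: pd.Series = None
    skipped: list = field(default_factory=list)


def detect_break(cv: CVSeries, candidate_years, z: float = 2.0) -> BreakReport:
    """Best dispersion break among candidate years.

    For each candidate b the jump is mean CV(years >= b) - mean CV(years < b);
    the best candidate maximizes the jump, ties broken by the earliest year.
    The jump is 'significant' when it exceeds ``z`` times the standard
    deviation of the year-over-year CV changes (a plain step-versus-noise
    yardstick, not an asymptotic test).
    """
    years = cv.years
    if len(years) < 4:
        raise ValueError("break detection needs >= 4 years of CV values")
    vals = cv.series.to_numpy(float)
    jumps, skipped = {}, []
    for b in candidate_years:
        b = int(b)
        before, after = vals[years < b], vals[years >= b]
        if not len(before) or not len(after):
            skipped.append(b)
            continue
        jumps[b] = float(after.mean() - before.mean())
    if skipped:
        logger.info("detect_break: candidates outside year range skipped: %s", skipped)
    if not jumps:
        raise ValueError("no candidate year lies inside the CV year range")
    jump_s = pd.Series(jumps).sort_index()
    best_year = int(jump_s.idxmax())  # idxmax returns the first (earliest) max
    best = float(jump_s.loc[best_year])
    threshold = z * float(np.std(np.diff(vals), ddof=1)) if len(vals) > 2 else np.inf
    return BreakReport(year=best_year, jump=best,
                       significant=bool(best > threshold), threshold=threshold,
                       all_jumps=jump_s, skipped=skipped)


# ---------------------------------------------------------------------------
# beta-convergence
# ---------------------------------------------------------------------------

@dataclass
class BetaConvergenceReport:
    """Global catching-up verdict plus country/year localizations."""

    beta_mean: float
    beta_interval: tuple[float, float]
    beta_significant: bool
    convergence: bool
    countries: pd.DataFrame      # country, mean, label
    years: pd.DataFrame          # year, mean, divergence

    def country_label(self, country) -> str:
        row = self.countries[self.countries["country"] == country]
        return row["label"].iloc[0] if len(row) else "average"

    def divergence_years(self) -> list:
        return self.years.loc[self.years["divergence"], "year"].astype(int).tolist()


def _label_deviation(mean: float, significant: bool) -> str:
    if not significant:
        return "average"
    return "below_average" if mean < 0 else "above_average"


def assess_beta(fit: FitResult) -> BetaConvergenceReport:
    """Classify convergence from a fitted model (quantile mode).

    Convergence is declared iff the global lag coefficient is negative with
    a 95% interval excluding zero.  Country deviations with intervals
    excluding zero are labelled below/above average by sign; significant
    positive year deviations are flagged as divergence years.
    """
    s = fit.summaries
    beta = s.loc["beta"]
    beta_sig = classify_significance(
        beta["mean"], quantiles=(beta["q2.5"], beta["q97.5"])
    ) == "significant"
    crow, yrow = [], []
    for lab in fit.labels:
        if lab.startswith("beta_country_"):
            row = s.loc[lab]
            sig = classify_significance(
                row["mean"], quantiles=(row["q2.5"], row["q97.5"])
            ) == "significant"
            crow.append({"country": lab.removeprefix("beta_country_"),
                         "mean": float(row["mean"]),
                         "label": _label_deviation(row["mean"], sig)})
        elif lab.startswith("beta_year_"):
            row = s.loc[lab]
            sig = classify_significance(
                row["mean"], quantiles=(row["q2.5"], row["q97.5"])
            ) == "significant"
            yrow.append({"year": int(lab.removeprefix("beta_year_")),
                         "mean": float(row["mean"]),
                         "divergence": bool(sig and row["mean"] > 0)})
    return BetaConvergenceReport(
        beta_mean=float(beta["mean"]),
        beta_interval=(float(beta["q2.5"]), float(beta["q97.5"])),
        beta_significant=beta_sig,
        convergence=bool(beta_sig and beta["mean"] < 0),
        countries=pd.DataFrame(crow, columns=["country", "mean", "label"]),
        years=pd.DataFrame(yrow, columns=["year", "mean", "divergence"]),
    )


def assess_beta_from_summaries(
    beta: tuple[float, float],
    country_deviations: dict | None = None,
    year_deviations: dict | None = None,
) -> BetaConvergenceReport:
    """Summary-mode variant consuming printed (mean, sd) pairs.

    ``beta`` is the global (mean, sd); the deviation dicts map country name
    (or year) to (mean, sd).  Used to reproduce the verbal reading of
    published coefficient tables that print only means and sds.
    """
    bmean, bsd = beta
    bsig = classify_significance(bmean, sd=bsd) == "significant"
    crow = [
        {"country": c, "mean": m,
         "label": _label_deviation(m, classify_significance(m, sd=s) == "significant")}
        for c, (m, s) in (country_deviations or {}).items()
    ]
    yrow = [
        {"year": int(y), "mean": m,
         "divergence": bool(classify_significance(m, sd=s) == "significant" and m > 0)}
        for y, (m, s) in (year_deviations or {}).items()
    ]
    return BetaConvergenceReport(
        beta_mean=bmean,
        beta_interval=(bmean - 1.96 * bsd, bmean + 1.96 * bsd),
        beta_significant=bsig,
        convergence=bool(bsig and bmean < 0),
        countries=pd.DataFrame(crow, columns=["country", "mean", "label"]),
        years=pd.DataFrame(yrow, columns=["year", "mean", "divergence"]),
    )
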