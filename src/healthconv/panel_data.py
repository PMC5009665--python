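"""Panel data model, CSV I/O and deterministic design-matrix transformations.

A panel is a long-format table of region x year observations of a health
outcome (life expectancy in years, or a mortality rate per 100,000) together
with regional covariates (GDP per capita, high-tech employment, university
students, youth unemployment by sex) and country-level covariates (Gini
index on the 0-100 scale, R&D %GDP, external balance %GDP, public
expenditure %GDP, GDP growth rate).  The panel may be unbalanced: any
outcome or covariate cell may be missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of a panel file
PANEL_COLUMNS = [
    "region_id", "country_id", "year", "outcome", "gdppc", "gini",
    "empht", "univ", "umy", "ufy", "randd", "bpg", "pubexp", "rate",
]
ID_COLUMNS = ["region_id", "country_id", "year"]
VALUE_COLUMNS = [c for c in PANEL_COLUMNS if c not in ID_COLUMNS]

GEOMETRY_COLUMNS = ["region_id", "country_id", "x", "y"]

#: step years of the three period dummies (EU enlargements 2004/2007 and the
#: 2008 financial crisis: indicator is 1 strictly after the listed year)
DUMMY_THRESHOLDS = (2003, 2006, 2007)


class PanelValidationError(ValueError):
    """Raised when a panel violates a structural invariant."""


@dataclass
class PanelTable:
    """Validated long-format region x year panel.

    ``df`` keeps one row per (region_id, year); missing cells are NaN.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing_cols = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise PanelValidationError(f"panel missing columns: {missing_cols}")
        df = df[PANEL_COLUMNS].copy()
        df["year"] = df["year"].astype(int)
        df["region_id"] = df["region_id"].astype(str)
        df["country_id"] = df["country_id"].astype(str)
        for c in VALUE_COLUMNS:
            df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        dup = df.duplicated(subset=["region_id", "year"], keep=False)
        if dup.any():
            offenders = (
                df.loc[dup, ["region_id", "year"]]
                .drop_duplicates()
                .to_records(index=False)
                .tolist()
            )
            raise PanelValidationError(
                f"duplicate (region, year) pairs: {offenders[:10]}"
            )
        ncountry = df.groupby("region_id")["country_id"].nunique()
        bad = ncountry[ncountry > 1]
        if len(bad):
            raise PanelValidationError(
                f"regions mapped to multiple countries: {list(bad.index)}"
            )
        neg = df["outcome"].notna() & (df["outcome"] <= 0)
        if neg.any():
            rows = df.loc[neg, ["region_id", "year"]].to_records(index=False).tolist()
            raise PanelValidationError(
                f"non-positive outcome (log is taken) at rows: {rows[:10]}"
            )
        df = df.sort_values(["region_id", "year"], kind="mergesort").reset_index(drop=True)
        self.df = df

    # -- convenience views ------------------------------------------------
    @property
    def regions(self) -> list[str]:
        return sorted(self.df["region_id"].unique())

    @property
    def countries(self) -> list[str]:
        return sorted(self.df["country_id"].unique())

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.df["year"].min(), self.df["year"].max() + 1)

    @property
    def region_to_country(self) -> dict[str, str]:
        return dict(
            self.df.drop_duplicates("region_id")[["region_id", "country_id"]].values
        )

    def n_missing_cells(self) -> int:
        return int(self.df[VALUE_COLUMNS].isna().sum().sum())

    def summary(self) -> dict:
        return {
            "rows": len(self.df),
            "regions": len(self.regions),
            "countries": len(self.countries),
            "years": (int(self.df["year"].min()), int(self.df["year"].max())),
            "missing_cells": self.n_missing_cells(),
        }


@dataclass
class RegionGeometry:
    """Planar region centroids plus the region -> country nesting."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in GEOMETRY_COLUMNS if c not in df.columns]
        if missing:
            raise PanelValidationError(f"geometry missing columns: {missing}")
        df = df[GEOMETRY_COLUMNS].copy()
        df["region_id"] = df["region_id"].astype(str)
        df["country_id"] = df["country_id"].astype(str)
        for c in ("x", "y"):
            df[c] = df[c].astype(float)
        if not np.isfinite(df[["x", "y"]].to_numpy()).all():
            raise PanelValidationError("geometry coordinates must be finite")
        if df["region_id"].duplicated().any():
            raise PanelValidationError("duplicate region_id in geometry")
        if len(df[["x", "y"]].drop_duplicates()) < 2 and len(df) >= 2:
            logger.warning("all region centroids coincide")
        self.df = df.sort_values("region_id", kind="mergesort").reset_index(drop=True)

    def coords(self, region_ids: list[str]) -> np.ndarray:
        idx = self.df.set_index("region_id")
        try:
            return idx.loc[region_ids, ["x", "y"]].to_numpy(float)
        except KeyError as e:
            raise PanelValidationError(f"region without coordinates: {e}") from e

    def country_centroids(self) -> pd.DataFrame:
        """Unweighted mean of region centroids per country."""
        return self.df.groupby("country_id", sort=True)[["x", "y"]].mean().reset_index()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_panel(path, schema: dict[str, str] | None = None) -> PanelTable:
    """Read a panel CSV (UTF-8, one header row, "" for missing cells).

    ``schema`` optionally maps file column names to the canonical names in
    :data:`PANEL_COLUMNS`.
    """
    df = pd.read_csv(path, na_values=[""], keep_default_na=True)
    if schema:
        df = df.rename(columns=schema)
    table = PanelTable(df)
    logger.info("read panel %s: %s", path, table.summary())
    return table


def write_panel(table: PanelTable, path) -> None:
    table.df.to_csv(path, index=False, na_rep="")


def read_geometry(path) -> RegionGeometry:
    return RegionGeometry(pd.read_csv(path))


def write_geometry(geom: RegionGeometry, path) -> None:
    geom.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def build_lags(
    panel: PanelTable | pd.DataFrame,
    var: str,
    k: int,
    unit: str = "region",
) -> pd.Series:
    """Lag ``var`` by ``k`` calendar years within each unit.

    The lag is year-indexed, not position-indexed: the value at (unit, t) is
    the value at (unit, t-k), so a gap year yields a missing lag rather than
    a wrong join.  The first k years of each unit are missing.
    """
    if k < 1:
        raise ValueError("lag order k must be >= 1")
    df = panel.df if isinstance(panel, PanelTable) else panel
    unit_col = {"region": "region_id", "country": "country_id"}[unit]
    if unit_col not in df.columns or var not in df.columns:
        raise KeyError(f"missing column {unit_col!r} or {var!r}")
    span = df["year"].max() - df["year"].min() + 1
    if k >= span:
        logger.warning("lag order %d >= year span %d: all-missing column", k, span)
    shifted = df[[unit_col, "year", var]].copy()
    shifted["year"] = shifted["year"] + k
    merged = df[[unit_col, "year"]].merge(
        shifted, on=[unit_col, "year"], how="left", validate="many_to_one"
    )
    out = merged[var]
    out.index = df.index
    out.name = f"{var}_lag{k}"
    return out


def build_period_dummies(year: int) -> tuple[int, int, int]:
    """Period indicators: EU-2004 enlargement, EU-2007 enlargement, 2008 crisis.

    Each is 1 strictly after its threshold year (2003, 2006, 2007), so e.g.
    2007 -> (1, 1, 0).
    """
    return tuple(int(year > t) for t in DUMMY_THRESHOLDS)


def aggregate_to_country(panel: PanelTable | pd.DataFrame, var: str) -> pd.DataFrame:
    """Unweighted mean of ``var`` over non-missing regions per (country, year).

    Country-years where every region is missing yield NaN.
    """
    df = panel.df if isinstance(panel, PanelTable) else panel
    out = (
        df.groupby(["country_id", "year"], sort=True)[var]
        .mean()
        .reset_index()
        .rename(columns={var: f"{var}_country"})
    )
    return out


def bpg_transform(b: np.ndarray | float) -> np.ndarray | float:
    """Signed log transform for the external balance, defined on all reals.

    The external balance can be negative, so a plain log is undefined;
    sign(b)*log(1+|b|) preserves sign and order and is 0 at 0.
    """
    return np.sign(b) * np.log1p(np.abs(b))


@dataclass
class DesignTable:
    """Assembled regressors for the outcome equation (per observation) and
    the Gini equation (per country-year), with complete-case masks.

    ``eq1`` has one row per panel row (row count is never changed, rows with
    any missing required regressor are masked via ``mask1``).  ``eq2`` has
    one row per (country, year).
    """

    eq1: pd.DataFrame
    mask1: np.ndarray
    eq2: pd.DataFrame
    mask2: np.ndarray
    panel: PanelTable

    EQ1_REGRESSORS = [
        "log_y_lag1", "log_gdppc", "log_gdppc_lag1", "log_gdppc_lag2",
        "log_gini", "log_gini_lag1", "log_empht", "log_univ", "log_umy",
        "log_ufy", "log_randd", "bpg_t", "log_pubexp", "d2004", "d2007", "d2008",
    ]
    EQ2_REGRESSORS = [
        "log_yc_lag1", "log_yc_lag2", "log_yc_lag3",
        "log_gdppc_c_lag1", "log_gdppc_c_lag2", "log_gdppc_c_lag3",
        "rate_lag1", "log_gini_lag1", "d2004", "d2007", "d2008",
    ]

    def summary(self) -> dict:
        return {
            "eq1_rows": len(self.eq1),
            "eq1_complete": int(self.mask1.sum()),
            "eq2_rows": len(self.eq2),
            "eq2_complete": int(self.mask2.sum()),
        }


def _safe_log(s: pd.Series, name: str, rows: pd.DataFrame) -> pd.Series:
    bad = s.notna() & (s <= 0)
    if bad.any():
        where = rows.loc[bad, ["region_id", "year"]].head(5).to_records(index=False).tolist()
        raise PanelValidationError(
            f"non-positive value under log for {name!r} at rows {where}"
        )
    return np.log(s)


def assemble_design(panel: PanelTable) -> DesignTable:
    """Build the full regressor set for both equations.

    Outcome equation (per region-year): log outcome regressed on its own
    lag, log GDP per capita at lags 0-2, log Gini at lags 0-1, log regional
    covariates, signed-log external balance, log public expenditure and the
    three period dummies.  Gini equation (per country-year): log Gini on
    lagged country-mean log outcome (lags 1-3), lagged country log GDP per
    capita (lags 1-3), lagged GDP growth rate, its own lag and the dummies.
    """
    df = panel.df

    eq1 = df[ID_COLUMNS].copy()
    eq1["log_y"] = _safe_log(df["outcome"], "outcome", df)
    eq1["log_y_lag1"] = np.log(build_lags(panel, "outcome", 1, "region"))
    for k in (0, 1, 2):
        col = df["gdppc"] if k == 0 else build_lags(panel, "gdppc", k, "region")
        eq1[f"log_gdppc{'' if k == 0 else f'_lag{k}'}"] = _safe_log(
            col, "gdppc", df
        ) if k == 0 else np.log(col)
    eq1["log_gini"] = _safe_log(df["gini"], "gini", df)
    eq1["log_gini_lag1"] = np.log(build_lags(panel, "gini", 1, "region"))
    for v in ("empht", "univ", "umy", "ufy", "randd", "pubexp"):
        eq1[f"log_{v}"] = _safe_log(df[v], v, df)
    eq1["bpg_t"] = bpg_transform(df["bpg"])
    dummies = np.array([build_period_dummies(y) for y in df["year"]])
    eq1[["d2004", "d2007", "d2008"]] = dummies

    required1 = ["log_y"] + DesignTable.EQ1_REGRESSORS
    mask1 = eq1[required1].notna().all(axis=1).to_numpy()

    # country-level table for the Gini equation
    yc = aggregate_to_country(panel, "outcome")
    gc = aggregate_to_country(panel, "gdppc")
    country_vals = (
        df.groupby(["country_id", "year"], sort=True)[["gini", "rate"]]
        .mean()
        .reset_index()
    )
    eq2 = yc.merge(gc, on=["country_id", "year"]).merge(
        country_vals, on=["country_id", "year"]
    )
    eq2["log_gini"] = np.log(eq2["gini"].where(eq2["gini"] > 0))
    for k in (1, 2, 3):
        eq2[f"log_yc_lag{k}"] = np.log(
            build_lags(eq2.rename(columns={"outcome_country": "yc"}), "yc", k, "country")
        )
        eq2[f"log_gdppc_c_lag{k}"] = np.log(
            build_lags(
                eq2.rename(columns={"gdppc_country": "gc"}), "gc", k, "country"
            )
        )
    eq2["rate_lag1"] = build_lags(eq2, "rate", 1, "country")
    eq2["log_gini_lag1"] = np.log(
        build_lags(eq2.rename(columns={"gini": "gini_v"}), "gini_v", 1, "country")
    )
    dummies2 = np.array([build_period_dummies(y) for y in eq2["year"]])
    eq2[["d2004", "d2007", "d2008"]] = dummies2

    required2 = ["log_gini"] + DesignTable.EQ2_REGRESSORS
    mask2 = eq2[required2].notna().all(axis=1).to_numpy()

    design = DesignTable(eq1=eq1, mask1=mask1, eq2=eq2, mask2=mask2, panel=panel)
    logger.info("assembled design: %s", design.summary())
    return design
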