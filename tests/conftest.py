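import numpy as np
import pandas as pd
import pytest

from healthconv.panel_data import PANEL_COLUMNS, PanelTable, RegionGeometry
from healthconv.synthetic_data import SimulationConfig, simulate_panel


def make_panel(regions=("A1", "A2", "B1"), countries=("CA", "CA", "CB"),
               years=range(2000, 2006), seed=0):
    """Small hand-rolled balanced panel with plausible magnitudes."""
    rng = np.random.default_rng(seed)
    rows = []
    for r, c in zip(regions, countries):
        for y in years:
            rows.append({
                "region_id": r, "country_id": c, "year": y,
                "outcome": 75 + rng.normal(0, 2), "gdppc": 20000 + rng.normal(0, 500),
                "gini": 30 + rng.normal(0, 1), "empht": 400 + rng.normal(0, 20),
                "univ": 20 + rng.normal(0, 1), "umy": 15 + rng.normal(0, 1),
                "ufy": 18 + rng.normal(0, 1), "randd": 1.5 + rng.normal(0, 0.1),
                "bpg": rng.normal(0, 5), "pubexp": 45 + rng.normal(0, 2),
                "rate": rng.normal(2, 1),
            })
    return PanelTable(pd.DataFrame(rows, columns=PANEL_COLUMNS))


@pytest.fixture
def toy_panel():
    return make_panel()


@pytest.fixture
def toy_geometry(toy_panel):
    df = toy_panel.df.drop_duplicates("region_id")[["region_id", "country_id"]].copy()
    rng = np.random.default_rng(1)
    df["x"] = rng.uniform(0, 1, len(df))
    df["y"] = rng.uniform(0, 1, len(df))
    return RegionGeometry(df)


@pytest.fixture(scope="session")
def small_sim():
    """Session-wide simulated panel: 5 countries x 3 regions, 1995-2006."""
    cfg = SimulationConfig(n_countries=5, regions_per_country=3,
                           year_range=(1995, 2006), seed=42, missingness=0.05)
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Balanced (no missingness) simulated panel for exact-identity checks."""
    cfg = SimulationConfig(n_countries=4, regions_per_country=3,
                           year_range=(1995, 2006), seed=7, missingness=0.0)
    return simulate_panel(cfg)
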