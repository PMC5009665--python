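import dataclasses

import numpy as np
import pandas as pd
import pytest

from healthconv.inference import (
    FitResult, build_matrices, classify_significance, compute_dic,
    fit_joint_model, prior_sensitivity, residual_diagnostics, variance_test,
)
from healthconv.model_spec import ModelConfig, PriorConfig
from healthconv.panel_data import PanelTable, RegionGeometry, assemble_design
from healthconv.synthetic_data import SimulationConfig, simulate_panel

NO_EFFECTS = {k: False for k in ModelConfig().random_effects}


def fixed_effects_fit(sim, draws=800, seed=11, **kw):
    design = assemble_design(sim.panel)
    cfg = ModelConfig(random_effects=dict(NO_EFFECTS))
    return design, cfg, fit_joint_model(
        design, sim.geometry, PriorConfig(), draws=draws, seed=seed,
        config=cfg, chains=2, fix_sigma={"sigma_u": 0.02, "sigma_v": 0.02}, **kw
    )


class TestClassifySignificance:
    @pytest.mark.parametrize("mean,sd,expected", [
        (-0.5109, 0.0188, "significant"),      # strongly negative lag coefficient
        (0.0280, 0.0274, "not_significant"),   # interval straddles zero
        (0.0, 1.0, "not_significant"),
        (1.0406, 0.5213, "significant"),       # ratio just above 1.96
        (0.07, 0.0363, "not_significant"),     # ratio just below 1.96
        (0.001, 0.0, "significant"),           # printed sd rounded to zero
    ])
    def test_summary_mode(self, mean, sd, expected):
        assert classify_significance(mean, sd=sd) == expected

    def test_quantile_mode(self):
        assert classify_significance(-0.5, quantiles=(-0.6, -0.4)) == "significant"
        assert classify_significance(0.1, quantiles=(-0.05, 0.3)) == "not_significant"
        with pytest.raises(ValueError):
            classify_significance(0.0, quantiles=(0.5, -0.5))

    def test_requires_sd_or_quantiles(self):
        with pytest.raises(ValueError):
            classify_significance(1.0)


class TestDIC:
    def test_identical_draws_zero_peff(self):
        dic, p_eff = compute_dic(np.array([12.0, 12.0, 12.0]), 12.0)
        assert p_eff == 0.0
        assert dic == 12.0

    def test_two_draw_hand_arithmetic(self):
        # Dbar = 11, Dhat = 8 -> p_eff = 3, DIC = 14
        dic, p_eff = compute_dic(np.array([10.0, 12.0]), 8.0)
        assert p_eff == pytest.approx(3.0)
        assert dic == pytest.approx(14.0)

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            compute_dic(np.array([1.0]), 1.0)

    def test_peff_nonnegative_on_conjugate_fit(self, clean_sim):
        _, _, fit = fixed_effects_fit(clean_sim, draws=600)
        assert fit.p_eff >= 0


class TestFitJointModel:
    def test_conjugate_posterior_mean(self, clean_sim):
        """Fixed-effects-only fit with known sds reproduces the closed-form
        Gaussian linear-model posterior (within Monte-Carlo error)."""
        design, cfg, fit = fixed_effects_fit(clean_sim, draws=1500)
        mm = build_matrices(design, clean_sim.geometry, cfg)
        pr = PriorConfig()
        A = (mm.Z1.T @ mm.Z1 + mm.Z2.T @ mm.Z2) / 0.02**2 \
            + np.eye(mm.p) / pr.fixed_sd() ** 2
        exact = np.linalg.solve(A, (mm.Z1.T @ mm.y1 + mm.Z2.T @ mm.y2) / 0.02**2)
        cov = np.linalg.inv(A)
        got = fit.theta_draws.mean(axis=0)
        mc_se = np.sqrt(np.diag(cov) / len(fit.theta_draws))
        np.testing.assert_array_less(np.abs(got - exact), 5 * mc_se + 1e-12)

    def test_near_noiseless_recovers_fixed_effects(self):
        """With tiny observation noise and no random effects the fixed
        effects are recovered to three decimals."""
        cfg = SimulationConfig(
            n_countries=6, regions_per_country=4, year_range=(1995, 2006),
            seed=20, missingness=0.0, sigma_u=1e-6, sigma_v=1e-6,
            effect_sds={k: 0.0 for k in SimulationConfig().effect_sds},
        )
        sim = simulate_panel(cfg)
        design = assemble_design(sim.panel)
        mcfg = ModelConfig(random_effects=dict(NO_EFFECTS))
        fit = fit_joint_model(design, sim.geometry, PriorConfig(), draws=500,
                              seed=2, config=mcfg, chains=1,
                              fix_sigma={"sigma_u": 1e-6, "sigma_v": 1e-6})
        assert fit.summaries.loc["beta", "mean"] == pytest.approx(
            sim.params.beta, abs=1e-3
        )
        assert fit.summaries.loc["gamma_log_gini", "mean"] == pytest.approx(
            sim.params.gamma_named("log_gini"), abs=1e-3
        )
        assert fit.summaries.loc["delta_log_gini_lag1", "mean"] == pytest.approx(
            0.8, abs=1e-3
        )

    def test_seed_determinism(self, clean_sim):
        _, _, fit1 = fixed_effects_fit(clean_sim, draws=200, seed=5)
        _, _, fit2 = fixed_effects_fit(clean_sim, draws=200, seed=5)
        pd.testing.assert_frame_equal(fit1.summaries, fit2.summaries)

    def test_quantiles_ordered(self, clean_sim):
        _, _, fit = fixed_effects_fit(clean_sim, draws=300)
        assert (fit.summaries["q2.5"] <= fit.summaries["q97.5"]).all()

    def test_fitted_values_cover_unmasked_rows(self, clean_sim):
        design, _, fit = fixed_effects_fit(clean_sim, draws=200)
        assert len(fit.fitted) == int(design.mask1.sum())

    def test_nonconvergence_flag_is_loud(self, small_sim):
        design = assemble_design(small_sim.panel)
        with pytest.warns(UserWarning):
            fit = fit_joint_model(design, small_sim.geometry, PriorConfig(),
                                  draws=8, burn=0, seed=0, chains=2)
        assert fit.converged == (fit.rhat_max <= 1.05)


def _fake_fit(fitted, sigma_u_hat, config=None):
    return FitResult(
        summaries=pd.DataFrame(), fitted=fitted, dic=0.0, p_eff=0.0,
        deviance_draws=np.zeros(2), draws={}, theta_draws=np.zeros((2, 1)),
        labels=[], config=config or ModelConfig(), n_chains=1, n_draws=2,
        seed=0, rhat_max=1.0, converged=True, sigma_u_hat=sigma_u_hat,
        sigma_v_hat=1.0,
    )


def _long_null_panel(n_regions=10, n_years=400, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_regions):
        for t in range(n_years):
            rows.append({
                "region_id": f"R{i:02d}", "country_id": "C0",
                "year": 1600 + t,
                "outcome": float(np.exp(4.0 + 0.05 * rng.standard_normal())),
                "gdppc": float(20000 * np.exp(0.1 * rng.standard_normal())),
                "gini": 30.0, "empht": 400.0, "univ": 20.0,
                "umy": float(15 * np.exp(0.1 * rng.standard_normal())),
                "ufy": 18.0, "randd": 1.2, "bpg": 0.0, "pubexp": 45.0,
                "rate": 2.0,
            })
    return PanelTable(pd.DataFrame(rows))


class TestResidualDiagnostics:
    def _geometry(self, panel, seed=1):
        df = panel.df.drop_duplicates("region_id")[["region_id", "country_id"]].copy()
        rng = np.random.default_rng(seed)
        df["x"] = rng.uniform(0, 1, len(df))
        df["y"] = rng.uniform(0, 1, len(df))
        return RegionGeometry(df)

    def test_null_residuals_rarely_flag(self):
        """iid standard-normal residuals, hundreds per region: under 10% of
        the temporal/cross-correlation flags fire."""
        panel = _long_null_panel()
        geometry = self._geometry(panel)
        design = assemble_design(panel)
        rng = np.random.default_rng(7)
        eq1 = design.eq1[design.mask1]
        fitted = eq1[["region_id", "country_id", "year"]].copy()
        fitted["fitted_log"] = (eq1["log_y"].to_numpy(float)
                                - rng.standard_normal(len(eq1)))
        fitted["fitted_response"] = np.exp(fitted["fitted_log"])
        report = residual_diagnostics(_fake_fit(fitted, 1.0), design, geometry)
        flags = pd.concat([
            report.region_acf1["flag"], report.moran_by_year["flag"],
            report.cross_correlation["flag"],
        ])
        assert flags.mean() < 0.10

    def test_residual_equal_to_regressor_flags_cross_correlation(self, clean_sim):
        design = assemble_design(clean_sim.panel)
        eq1 = design.eq1[design.mask1]
        fitted = eq1[["region_id", "country_id", "year"]].copy()
        fitted["fitted_log"] = (eq1["log_y"].to_numpy(float)
                                - eq1["log_gdppc"].to_numpy(float))
        fitted["fitted_response"] = np.exp(fitted["fitted_log"])
        report = residual_diagnostics(
            _fake_fit(fitted, 1.0), design, self._geometry(clean_sim.panel)
        )
        row = report.cross_correlation.set_index("regressor").loc["log_gdppc"]
        assert row["r"] == pytest.approx(1.0)
        assert row["flag"]

    def test_alternating_residuals_flag_autocorrelation(self, clean_sim):
        design = assemble_design(clean_sim.panel)
        eq1 = design.eq1[design.mask1]
        fitted = eq1[["region_id", "country_id", "year"]].copy()
        sign = np.where(eq1["year"].to_numpy() % 2 == 0, 1.0, -1.0)
        fitted["fitted_log"] = eq1["log_y"].to_numpy(float) - sign
        fitted["fitted_response"] = np.exp(fitted["fitted_log"])
        report = residual_diagnostics(
            _fake_fit(fitted, 1.0), design, self._geometry(clean_sim.panel)
        )
        assert (report.region_acf1["acf1"] < -0.8).all()
        assert report.region_acf1["flag"].all()

    def test_short_regions_skipped_with_note(self, toy_panel, toy_geometry):
        df = toy_panel.df.copy()
        df = df[(df["region_id"] != "B1") | (df["year"] <= 2003)]
        panel = PanelTable(df)
        design = assemble_design(panel)
        eq1 = design.eq1[design.mask1]
        fitted = eq1[["region_id", "country_id", "year"]].copy()
        fitted["fitted_log"] = eq1["log_y"].to_numpy(float)
        fitted["fitted_response"] = np.exp(fitted["fitted_log"])
        report = residual_diagnostics(_fake_fit(fitted, 1.0), design, toy_geometry)
        assert "B1" in report.skipped_regions


class TestVarianceTest:
    @staticmethod
    def _pair_of_fits(sd_beta_country, seed):
        sds = dict(SimulationConfig().effect_sds)
        sds.update({"sd_beta_country": sd_beta_country, "sd_tau_country": 0.0,
                    "matern_region_var": 0.0, "matern_country_var": 0.0,
                    "sd_beta_year": 0.0, "sd_tau_year": 0.0})
        cfg = SimulationConfig(n_countries=8, regions_per_country=3,
                               year_range=(1995, 2005), seed=seed,
                               missingness=0.0, effect_sds=sds)
        sim = simulate_panel(cfg)
        design = assemble_design(sim.panel)
        re_full = {**NO_EFFECTS, "alpha_region": True, "beta_country": True,
                   "delta0_country": True}
        re_red = {**re_full, "beta_country": False}
        kw = dict(draws=400, burn=300, seed=seed, chains=1)
        full = fit_joint_model(design, sim.geometry, PriorConfig(),
                               config=ModelConfig(random_effects=re_full), **kw)
        red = fit_joint_model(design, sim.geometry, PriorConfig(),
                              config=ModelConfig(random_effects=re_red), **kw)
        return full, red

    def test_zero_variance_effect_collapses(self):
        verdicts = [
            variance_test(*self._pair_of_fits(0.0, seed), "beta_country")
            for seed in range(4)
        ]
        assert verdicts.count("collapse_to_fixed") >= 3

    def test_large_variance_effect_kept(self):
        verdicts = [
            variance_test(*self._pair_of_fits(0.10, seed), "beta_country")
            for seed in range(4)
        ]
        assert verdicts.count("keep_random") >= 3

    def test_identical_configs_rejected(self, clean_sim):
        _, _, fit = fixed_effects_fit(clean_sim, draws=200)
        with pytest.raises(ValueError, match="differ"):
            variance_test(fit, fit, "beta_country")


class TestPriorSensitivity:
    def test_reference_factor_required(self, clean_sim):
        design = assemble_design(clean_sim.panel)
        with pytest.raises(ValueError, match="1.0"):
            prior_sensitivity(design, clean_sim.geometry, PriorConfig(), [2.0, 4.0])

    def test_zero_shift_against_itself(self, clean_sim):
        design = assemble_design(clean_sim.panel)
        table = prior_sensitivity(
            design, clean_sim.geometry, PriorConfig(), [1.0],
            draws=200, seed=3, chains=1,
            config=ModelConfig(random_effects=dict(NO_EFFECTS)),
            fix_sigma={"sigma_u": 0.02, "sigma_v": 0.02},
        )
        assert table["max_abs_shift"].isna().all()

    def test_shifts_shrink_with_more_data(self):
        """Posterior concentration: tightening the prior moves the posterior
        less when the likelihood dominates."""
        shifts = {}
        for n_reg, label in ((2, "small"), (8, "large")):
            cfg = SimulationConfig(n_countries=5, regions_per_country=n_reg,
                                   year_range=(1995, 2006), seed=17,
                                   missingness=0.0,
                                   effect_sds={k: 0.0 for k in SimulationConfig().effect_sds})
            sim = simulate_panel(cfg)
            design = assemble_design(sim.panel)
            table = prior_sensitivity(
                design, sim.geometry, PriorConfig(), [1.0, 100.0],
                draws=1000, seed=3, chains=1,
                config=ModelConfig(random_effects=dict(NO_EFFECTS)),
                fix_sigma={"sigma_u": 0.02, "sigma_v": 0.02},
            )
            shifts[label] = table.set_index("parameter")["max_abs_shift"]
        assert shifts["large"].loc["beta"] < shifts["small"].loc["beta"]
        assert shifts["large"].median() < shifts["small"].median()
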