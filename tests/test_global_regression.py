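"""Global logistic regression: VIF, fits, DIC, odds ratios."""

import numpy as np
import pandas as pd
import pytest

from spatialenroll.global_regression import (
    FitConfig,
    build_design,
    compute_dic,
    compute_vif,
    fit_global,
    model_comparison_table,
    odds_ratio_table,
    percent_change,
)
from spatialenroll.posterior import PosteriorSummary


class TestVIF:
    def test_orthogonal_covariates_give_one(self, rng):
        n = 4000
        X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        out = compute_vif(X)
        assert np.allclose(out["vif"], 1.0, atol=0.02)
        assert not out["flagged"].any()

    def test_correlation_09_pair_matches_closed_form(self, rng):
        # VIF = 1 / (1 - rho^2) = 5.263 for rho = 0.9
        n = 10_000
        a = rng.standard_normal(n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        X = pd.DataFrame({"a": a, "b": b, "c": rng.standard_normal(n)})
        out = compute_vif(X).set_index("covariate")["vif"]
        assert out["a"] == pytest.approx(1 / (1 - 0.81), abs=0.35)

    def test_duplicate_column_flagged_infinite(self, rng):
        a = rng.standard_normal(500)
        X = pd.DataFrame({"a": a, "dup": a, "c": rng.standard_normal(500)})
        out = compute_vif(X).set_index("covariate")
        assert np.isinf(out.loc["a", "vif"]) and out.loc["a", "flagged"]


class TestComputeDic:
    def test_worked_example(self):
        out = compute_dic(np.array([10.0, 12.0, 14.0]), 11.0)
        assert out == {"DIC": 13.0, "pD": 1.0, "mean_deviance": 12.0}

    def test_degenerate_posterior_has_zero_pd(self):
        out = compute_dic(np.full(5, 7.0), 7.0)
        assert out["pD"] == 0.0 and out["DIC"] == 7.0

    def test_identity_holds_for_fit_reports(self, demo_dataset):
        design = build_design(demo_dataset.insurants, demo_dataset.covariates)
        f = fit_global(design, demo_dataset.graph, "iid", FitConfig(n_draws=300, seed=0))
        assert f.dic["DIC"] == pytest.approx(f.dic["mean_deviance"] + f.dic["pD"])
        assert f.dic["pD"] > 0


class TestFitGlobal:
    def test_none_effect_matches_ml_logistic(self, rng):
        # oracle: maximum-likelihood fit; diffuse priors at large n agree
        import statsmodels.api as sm

        from spatialenroll.synthetic_region import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_rows=10, n_cols=10, mean_insurants_per_area=1000,
            spatial_sd_structured=0, spatial_sd_unstructured=0, seed=31,
        )
        ds = simulate_dataset(cfg)
        design = build_design(ds.insurants, ds.covariates)
        fit = fit_global(design, None, "none", FitConfig(n_draws=400, seed=1))
        X = sm.add_constant(design.X.to_numpy())
        ml = sm.GLM(design.y, X, family=sm.families.Binomial()).fit()
        post = fit.posterior.summary().set_index("parameter")
        for j, name in enumerate(fit.posterior.names):
            assert abs(post.loc[name, "mean"] - ml.params[j]) < post.loc[name, "sd"] / 10 + 1e-6

    def test_effect_types_agree_without_spatial_signal(self, demo_dataset):
        design = build_design(demo_dataset.insurants, demo_dataset.covariates)
        fits = {
            e: fit_global(design, demo_dataset.graph, e, FitConfig(n_draws=300, seed=2))
            for e in ("none", "iid", "bym")
        }
        for name in ("male", "household_size"):
            means = [f.posterior.mean(name) for f in fits.values()]
            sds = [f.posterior.summary().set_index("parameter").loc[name, "sd"] for f in fits.values()]
            assert max(means) - min(means) < 2 * max(sds)
        table = model_comparison_table(list(fits.values()))
        assert table["DIC"].notna().all() and len(table) == 3

    def test_separation_warns_but_returns(self, rng):
        from spatialenroll.global_regression import RegressionDesign

        n = 400
        X = pd.DataFrame(
            {
                "male": rng.integers(0, 2, n),
                "age": rng.normal(55, 10, n),
                "foreign_citizenship": rng.integers(0, 2, n),
                "unemployed": rng.integers(0, 2, n),
                "deprivation": rng.uniform(1, 100, n),
                "household_size": rng.uniform(1, 4, n),
                "commuter_pct": rng.uniform(0, 60, n),
                "physician_density": rng.uniform(50, 400, n),
            }
        )
        y = (X["male"] == 1).to_numpy(float)  # perfectly separated by sex
        design = RegressionDesign(
            y=y, X=X, area_ids=["a"], area_index=np.zeros(n, dtype=int)
        )
        with pytest.warns(UserWarning, match="separat"):
            fit_global(design, None, "none", FitConfig(n_draws=200, seed=0))

    def test_unknown_effect_type_rejected(self, demo_dataset):
        design = build_design(demo_dataset.insurants, demo_dataset.covariates)
        with pytest.raises(ValueError):
            fit_global(design, demo_dataset.graph, "carar")


class TestOddsRatioTable:
    @staticmethod
    def _posterior(samples, names):
        return PosteriorSummary(
            names=names,
            samples=samples,
            deviance_samples=np.array([1.0, 2.0]),
            deviance_at_mean=1.0,
        )

    def test_zero_coefficient_gives_unit_or(self):
        p = self._posterior(np.zeros((200, 2)), ["intercept", "male"])
        t = odds_ratio_table(p).set_index("covariate")
        assert t.loc["male", "or_mean"] == 1.0
        assert t.loc["male", "ci_2.5"] == 1.0 and t.loc["male", "ci_97.5"] == 1.0

    def test_median_of_symmetric_samples(self):
        s = np.array([[-0.1], [0.0], [0.1]])
        t = odds_ratio_table(self._posterior(s, ["x"]))
        assert t["or_median"][0] == pytest.approx(1.0)

    def test_row_count_and_rank_preservation(self, rng):
        betas = np.array([0.3, -0.2, 0.0, 1.1])
        samples = betas + 0.01 * rng.standard_normal((500, 4))
        names = ["intercept", "a", "b", "c"]
        t = odds_ratio_table(self._posterior(samples, names))
        assert len(t) == 4
        assert (
            t.set_index("covariate")["or_mean"].rank().tolist()
            == pd.Series(betas, index=names).rank().tolist()
        )


class TestPercentChange:
    @pytest.mark.parametrize(
        "or_value,expected",
        [(0.938, -6.2), (1.100, 10.0), (1.0, 0.0), (0.997, -0.3), (0.801, -19.9),
         (1.058, 5.8), (0.996, -0.4)],
    )
    def test_published_conversions(self, or_value, expected):
        assert percent_change(or_value) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            percent_change(0.0)
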