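"""Tests for the individual fixed-effects engine and reporting conversions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crpbmd import (
    FitResult,
    ModelSpec,
    descriptive_stage_comparison,
    effect_per_sd,
    fit_ife,
    log2_fold_change,
    log2_geometric_mean,
    log2_percent_change,
    pairwise_stage_contrasts,
    stage_effects,
    wald_interaction_test,
    within_demean,
)
from tests.conftest import make_panel, make_random_small_panel


def crude_obs(woman, x, y):
    return pd.DataFrame(
        {"woman_id": woman, "log2_crp": x, "slope": y, "stage": 1, "alcohol": 0}
    )


class TestWithinDemean:
    def test_two_point_example(self):
        df = pd.DataFrame({"x": [1.0, 3.0]})
        out = within_demean(df, pd.Series([0, 0]))
        assert out["x"].tolist() == [-1.0, 1.0]

    def test_identical_rows_become_zero(self):
        df = pd.DataFrame({"x": [2.0, 2.0, 2.0]})
        assert (within_demean(df, pd.Series([0, 0, 0]))["x"] == 0).all()

    def test_time_fixed_column_annihilated(self):
        df = pd.DataFrame({"x": [5.0, 5.0, 7.0, 7.0]})
        out = within_demean(df, pd.Series([0, 0, 1, 1]))
        assert (out["x"] == 0).all()

    def test_singleton_group_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            within_demean(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), pd.Series([0, 0, 1]))


class TestFitIFE:
    def test_closed_form_two_woman_panel(self):
        """For two-observation panels the within estimator has the closed
        form sum(dx dy) / sum(dx^2); this design gives beta = -0.1 exactly."""
        obs = crude_obs([0, 0, 1, 1], [0.0, 1.0, 0.0, 2.0], [0.0, -0.1, 0.0, -0.2])
        fit = fit_ife(obs, ModelSpec(covariate_set="crude"))
        assert fit.beta == pytest.approx(-0.1, abs=1e-12)
        assert fit.n_obs == 4 and fit.n_women == 2

    def test_shift_invariance(self):
        """Adding any constant to any variable within a woman (or globally)
        leaves the within estimates unchanged."""
        rng = np.random.default_rng(1)
        obs = make_random_small_panel(rng)
        f0 = fit_ife(obs, ModelSpec(covariate_set="model1"))
        shifted = obs.copy()
        shifted["log2_crp"] = shifted["log2_crp"] + 100.0
        shifted["slope"] = shifted["slope"] - 7.0
        shifted["bmi"] = shifted["bmi"] + shifted["woman_id"] * 3.0  # per-woman shift
        f1 = fit_ife(shifted, ModelSpec(covariate_set="model1"))
        pd.testing.assert_series_equal(f0.params, f1.params, atol=1e-9, rtol=1e-9)
        pd.testing.assert_series_equal(f0.bse, f1.bse, atol=1e-9, rtol=1e-9)

    def test_time_fixed_covariate_dropped_others_unchanged(self):
        """Per-woman constant covariates are annihilated by demeaning: the
        model-1 fit collapses to the crude fit and reports them dropped."""
        rng = np.random.default_rng(2)
        obs = make_random_small_panel(rng)
        obs["stage"] = 1  # make every model-1 covariate time-fixed
        obs["smoking"] = 0
        obs["diabetes"] = 0
        obs["alcohol"] = 0
        obs["bmi"] = 20.0 + obs["woman_id"]  # constant within woman
        f0 = fit_ife(obs, ModelSpec(covariate_set="crude"))
        with pytest.warns(UserWarning, match="time-fixed"):
            f1 = fit_ife(obs, ModelSpec(covariate_set="model1"))
        assert "bmi" in f1.dropped
        assert f1.params["log2_crp"] == pytest.approx(f0.params["log2_crp"], rel=1e-10)
        assert f1.bse["log2_crp"] == pytest.approx(f0.bse["log2_crp"], rel=1e-10)

    def test_exposure_without_variation_errors(self):
        obs = crude_obs([0, 0, 1, 1], [1.0, 1.0, 2.0, 2.0], [0.0, 1.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="log2_crp"):
            with pytest.warns(UserWarning):
                fit_ife(obs, ModelSpec(covariate_set="crude"))

    def test_log4_reexpression_doubles_coefficient(self):
        """Per-doubling scale contract: expressing the exposure in log4
        units (per quadrupling) doubles the fitted coefficient."""
        rng = np.random.default_rng(3)
        obs = make_random_small_panel(rng)
        f2 = fit_ife(obs, ModelSpec(covariate_set="crude"))
        obs4 = obs.assign(log2_crp=obs["log2_crp"] / 2.0)  # log4(CRP)
        f4 = fit_ife(obs4, ModelSpec(covariate_set="crude"))
        assert f4.beta == pytest.approx(2.0 * f2.beta, rel=1e-10)

    def test_stratified_equals_fit_on_subset(self):
        rng = np.random.default_rng(4)
        obs = make_panel(rng, n_women=50, obs_per_stage=2)
        fs = fit_ife(obs, ModelSpec(covariate_set="crude", stratum=2))
        sub = obs[obs["stage"] == 2]
        fm = fit_ife(sub, ModelSpec(covariate_set="crude"))
        assert fs.beta == pytest.approx(fm.beta, rel=1e-12)
        assert fs.n_obs == len(sub)

    def test_ife_equals_lsdv_oracle(self):
        """Within estimates and CR1 cluster SEs equal statsmodels OLS with
        one indicator per woman (LSDV), the independent oracle."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        for _ in range(25):
            obs = make_random_small_panel(rng)
            fit = fit_ife(obs, ModelSpec(covariate_set="model1"))
            cols = list(fit.params.index)
            X = np.column_stack(
                [
                    obs[c].to_numpy(float)
                    if c in obs.columns
                    else (
                        (obs["stage"] == int(c[-1])).to_numpy(float)
                        if c.startswith("stage_")
                        else (obs["alcohol"] == int(c[-1])).to_numpy(float)
                    )
                    for c in cols
                ]
            )
            D = pd.get_dummies(obs["woman_id"]).to_numpy(float)
            res = sm.OLS(obs["slope"].to_numpy(), np.column_stack([X, D])).fit(
                cov_type="cluster", cov_kwds={"groups": obs["woman_id"].to_numpy()}
            )
            np.testing.assert_allclose(res.params[: len(cols)], fit.params, rtol=1e-8)
            np.testing.assert_allclose(res.bse[: len(cols)], fit.bse, rtol=1e-8)

    def test_t_reference_widens_intervals(self):
        obs = make_random_small_panel(np.random.default_rng(6))
        fz = fit_ife(obs, ModelSpec(covariate_set="crude"))
        ft = fit_ife(obs, ModelSpec(covariate_set="crude", ci_reference="t"))
        assert ft.ci_high["log2_crp"] - ft.ci_low["log2_crp"] > (
            fz.ci_high["log2_crp"] - fz.ci_low["log2_crp"]
        )

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            ModelSpec(covariate_set="model9")
        with pytest.raises(ValueError):
            ModelSpec(stratum=4)
        with pytest.raises(ValueError):
            ModelSpec(stratum=2, interaction_with_stage=True)


def synthetic_fit(params: dict, cov: np.ndarray) -> FitResult:
    """Hand-built FitResult for testing the contrast machinery in isolation."""
    idx = list(params)
    p = pd.Series(params)
    se = pd.Series(np.sqrt(np.diag(cov)), index=idx)
    return FitResult(
        params=p, bse=se, ci_low=p - 1.96 * se, ci_high=p + 1.96 * se,
        pvalues=pd.Series(1.0, index=idx), cov=pd.DataFrame(cov, index=idx, columns=idx),
        n_obs=10, n_women=5, df_model=len(idx), spec=ModelSpec(interaction_with_stage=True),
    )


class TestInteractionMachinery:
    def test_wald_zero_coefficients_identity_cov(self):
        fit = synthetic_fit(
            {"log2_crp": 0.0, "log2_crp_x_stage2": 0.0, "log2_crp_x_stage3": 0.0},
            np.eye(3),
        )
        res = wald_interaction_test(fit)
        assert res["statistic"] == pytest.approx(0.0)
        assert res["df"] == 2
        assert res["p"] == pytest.approx(1.0)

    def test_wald_missing_terms_errors(self):
        fit = synthetic_fit({"log2_crp": 0.0}, np.eye(1))
        with pytest.raises(ValueError, match="interaction"):
            wald_interaction_test(fit)

    def test_stage_effects_and_contrast_arithmetic(self):
        """Stage effects (-0.1, 0, -0.1) give contrasts 1v2 = -0.1,
        2v3 = +0.1, 1v3 = 0."""
        fit = synthetic_fit(
            {"log2_crp": -0.1, "log2_crp_x_stage2": 0.1, "log2_crp_x_stage3": 0.0},
            0.01 * np.eye(3),
        )
        eff = stage_effects(fit).set_index("stage")["beta"]
        assert eff.loc[1] == pytest.approx(-0.1)
        assert eff.loc[2] == pytest.approx(0.0)
        assert eff.loc[3] == pytest.approx(-0.1)
        con = pairwise_stage_contrasts(fit).set_index("contrast")["difference"]
        assert con.loc["1v2"] == pytest.approx(-0.1)
        assert con.loc["2v3"] == pytest.approx(0.1)
        assert con.loc["1v3"] == pytest.approx(0.0)

    def test_identical_stage_effects_give_zero_contrasts(self):
        fit = synthetic_fit(
            {"log2_crp": -0.2, "log2_crp_x_stage2": 0.0, "log2_crp_x_stage3": 0.0},
            0.01 * np.eye(3),
        )
        assert (pairwise_stage_contrasts(fit)["difference"] == 0).all()

    def test_interaction_fit_recovers_stage_slopes(self):
        rng = np.random.default_rng(7)
        obs = make_panel(rng, n_women=800, obs_per_stage=3, beta=(-0.1, 0.0, -0.25),
                         noise_sd=0.3)
        fit = fit_ife(obs, ModelSpec(covariate_set="crude", interaction_with_stage=True))
        eff = stage_effects(fit).set_index("stage")
        for s, b in ((1, -0.1), (2, 0.0), (3, -0.25)):
            assert eff.loc[s, "beta"] == pytest.approx(b, abs=4 * eff.loc[s, "robust_se"])
        assert wald_interaction_test(fit)["p"] < 1e-6


class TestDescriptiveComparison:
    def test_all_zero_deltas(self):
        deltas = pd.DataFrame(
            {
                "woman_id": [0, 0, 1, 1, 2, 2],
                "stage": [1, 2, 1, 2, 3, 3],
                "d_log2_crp": 0.0,
                "d_slope": 0.0,
            }
        )
        out = descriptive_stage_comparison(deltas)
        assert (out["means"]["mean"] == 0).all()
        assert (out["pairwise"]["difference"] == 0).all()

    def test_known_stage_means(self):
        rng = np.random.default_rng(8)
        n = 600
        woman = np.repeat(np.arange(n // 3), 3)
        stage = np.tile([1, 2, 3], n // 3)
        shift = np.array([0.0, -1.0, 0.5])[stage - 1]
        deltas = pd.DataFrame(
            {
                "woman_id": woman,
                "stage": stage,
                "d_log2_crp": rng.normal(0, 0.5, n),
                "d_slope": shift + rng.normal(0, 0.5, n),
            }
        )
        out = descriptive_stage_comparison(deltas)
        m = out["means"].query("variable == 'd_slope'").set_index("stage")["mean"]
        assert m.loc[2] < m.loc[1] < m.loc[3]
        p12 = out["pairwise"].query("variable == 'd_slope' and contrast == '1v2'")["p"].iloc[0]
        assert p12 < 1e-6

    def test_missing_stage_warns(self):
        deltas = pd.DataFrame(
            {
                "woman_id": [0, 0, 1, 1],
                "stage": [1, 1, 1, 1],
                "d_log2_crp": [0.1, 0.2, 0.0, 0.3],
                "d_slope": [0.0, 0.1, -0.1, 0.2],
            }
        )
        with pytest.warns(UserWarning, match="stage 2"):
            descriptive_stage_comparison(deltas)


class TestConversions:
    @pytest.mark.parametrize(
        "mean_log2, expected",
        [(0.53, 1.44), (0.85, 1.80), (0.73, 1.66), (0.61, 1.53), (0.51, 1.42), (0.0, 1.00)],
    )
    def test_geometric_mean(self, mean_log2, expected):
        assert log2_geometric_mean(mean_log2) == pytest.approx(expected)

    def test_percent_and_fold_change(self):
        assert log2_percent_change(0.10) == pytest.approx(7.2)
        assert log2_fold_change(1.31) == pytest.approx(2.5)

    def test_effect_per_sd(self):
        assert effect_per_sd(0.10, 1.31) == pytest.approx(0.13)
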