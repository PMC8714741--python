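"""OLS, hierarchical blocks, VIF, and effect sizes against oracles."""

import numpy as np
import pandas as pd
import pytest

from taskphenotype import reference
from taskphenotype.regression import (
    RegressionBlockSpec,
    delta_f_from_r2,
    effect_size_f2,
    encode_gender,
    fit_ols,
    hierarchical_fit,
    model_f,
    vif,
)


def _random_data(rng, n=120):
    df = pd.DataFrame(
        {
            "age": rng.normal(38, 11, n),
            "gender": rng.choice(["female", "male"], n),
            "m1": rng.normal(40, 50, n),
            "m2": rng.normal(32, 6, n),
            "m3": rng.normal(20, 38, n),
        }
    )
    df["phq9_total"] = (
        10
        - 0.1 * df["age"]
        + 0.03 * df["m1"]
        - 0.2 * df["m2"]
        + 0.05 * df["m3"]
        + rng.normal(0, 5, n)
    )
    return df


class TestFitOls:
    def test_matches_normal_equations_oracle(self, rng):
        n, k = 50, 3
        X = pd.DataFrame(rng.normal(size=(n, k)), columns=["a", "b", "c"])
        y = pd.Series(rng.normal(size=n), name="y")
        fit = fit_ols(X, y)

        Xc = np.column_stack([np.ones(n), X.to_numpy()])
        beta_hat = np.linalg.solve(Xc.T @ Xc, Xc.T @ y.to_numpy())
        resid = y.to_numpy() - Xc @ beta_hat
        sigma2 = resid @ resid / (n - k - 1)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(Xc.T @ Xc)))
        r2 = 1 - (resid @ resid) / np.sum((y - y.mean()) ** 2)

        np.testing.assert_allclose(fit.coef["B"].to_numpy(), beta_hat, atol=1e-10)
        np.testing.assert_allclose(fit.coef["se_B"].to_numpy(), se, atol=1e-10)
        assert fit.r2 == pytest.approx(r2, abs=1e-12)
        assert fit.ssr == pytest.approx(float(resid @ resid), abs=1e-8)

    def test_noiseless_line_recovered_exactly(self):
        x = pd.DataFrame({"x": np.arange(10.0)})
        y = pd.Series(1.0 + 2.0 * x["x"])
        fit = fit_ols(x, y)
        assert fit.coef.loc["(Intercept)", "B"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coef.loc["x", "B"] == pytest.approx(2.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_beta_is_standardized_coefficient(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"]) * [3.0, 0.5]
        y = pd.Series(X["a"] - X["b"] + rng.normal(size=60))
        fit = fit_ols(X, y)
        # refit on z-scored data: B there equals beta here
        Xz = (X - X.mean()) / X.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        zfit = fit_ols(Xz, yz)
        np.testing.assert_allclose(
            fit.coef.loc[["a", "b"], "beta"], zfit.coef.loc[["a", "b"], "B"], atol=1e-10
        )

    def test_listwise_deletion(self, rng):
        X = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, np.nan, 7, 8]})
        y = pd.Series([2.0, 4, 6, 8, 10, 12, np.nan, 16])
        assert fit_ols(X, y).n == 6

    def test_rank_deficiency_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10]})
        y = pd.Series([1.0, 2, 1, 2, 1])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols(X, y)

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2], "b": [3.0, 5]})
        with pytest.raises(ValueError, match="too small"):
            fit_ols(X, pd.Series([1.0, 2]))


class TestBlockComparison:
    def test_delta_f_matches_nested_rss_f(self, rng):
        """dF from R-squared equals the classic nested-model F computed
        from residual sums of squares."""
        data = _random_data(rng)
        spec = RegressionBlockSpec(block1=["m1", "m2", "m3"])
        report = hierarchical_fit(spec, data)
        m = 3
        rss_f = ((report.reduced.ssr - report.full.ssr) / m) / (
            report.full.ssr / report.full.df_resid
        )
        assert report.delta_f == pytest.approx(rss_f, abs=1e-8)
        assert report.delta_r2 == pytest.approx(report.full.r2 - report.reduced.r2)

    def test_published_statistics_recompute_from_printed_r2(self):
        f, _ = model_f(reference.NULL_MODEL_R2, k=2, n=reference.STUDY2_N)
        assert f == pytest.approx(reference.NULL_MODEL_F, abs=0.05)
        df_, _ = delta_f_from_r2(
            reference.NULL_MODEL_R2,
            reference.COMBINED_MODEL_R2,
            n=reference.STUDY2_N,
            m=3,
            k_full=5,
        )
        assert df_ == pytest.approx(reference.COMBINED_MODEL_DELTA_F, abs=0.05)
        f_full, _ = model_f(reference.COMBINED_MODEL_R2, k=5, n=reference.STUDY2_N)
        assert f_full == pytest.approx(reference.COMBINED_MODEL_F, abs=0.05)

    def test_r2_decrease_rejected(self):
        with pytest.raises(ValueError, match="cannot decrease"):
            delta_f_from_r2(0.3, 0.2, n=90, m=3, k_full=5)

    def test_gender_strings_are_coded_male_one(self, rng):
        data = _random_data(rng)
        spec = RegressionBlockSpec(block1=["m1"])
        report = hierarchical_fit(spec, data)
        coded = data.copy()
        coded["gender"] = encode_gender(coded["gender"])
        report2 = hierarchical_fit(spec, coded)
        pd.testing.assert_frame_equal(report.full.coef, report2.full.coef)

    def test_spec_rejects_repeated_and_outcome_predictors(self):
        with pytest.raises(ValueError, match="more than one block"):
            RegressionBlockSpec(block1=["age"])
        with pytest.raises(ValueError, match="outcome"):
            RegressionBlockSpec(block1=["phq9_total"])


class TestVif:
    def test_exact_closed_form_at_correlation_half(self):
        z1 = np.array([1.0, 1, -1, -1])
        z2 = np.array([1.0, -1, 1, -1])
        X = pd.DataFrame({"a": z1, "b": 0.5 * z1 + np.sqrt(0.75) * z2})
        out = vif(X)
        assert out["a"] == pytest.approx(1 / (1 - 0.25), abs=1e-10)
        assert out["b"] == pytest.approx(4 / 3, abs=1e-10)

    def test_orthogonal_predictors_give_one(self):
        X = pd.DataFrame({"a": [1.0, 1, -1, -1], "b": [1.0, -1, 1, -1]})
        np.testing.assert_allclose(vif(X), [1.0, 1.0], atol=1e-12)

    def test_collinear_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError):
            vif(X)

    def test_needs_two_predictors(self):
        with pytest.raises(ValueError, match="at least 2"):
            vif(pd.DataFrame({"a": [1.0, 2, 3]}))


class TestEffectSize:
    def test_published_block_effect_both_conventions(self):
        out = effect_size_f2(
            reference.COMBINED_MODEL_DELTA_R2, reference.COMBINED_MODEL_R2
        )
        assert out["cohen"] == pytest.approx(0.398, abs=0.001)
        assert out["variant"] == pytest.approx(0.353, abs=0.001)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            effect_size_f2(0.5, 0.4)
        with pytest.raises(ValueError):
            effect_size_f2(-0.1, 0.3)


class TestCoefficientRecovery:
    def test_null_model_age_coefficient_recovered(self):
        """Simulating from the published demographics-only model at
        n = 20,000 and refitting recovers the printed age coefficient
        within 3 Monte-Carlo standard errors."""
        from taskphenotype.simulate import simulate_from_fitted_model

        rng = np.random.default_rng(2024)
        df = simulate_from_fitted_model(
            reference.NULL_MODEL_COEF,
            {"age": (reference.STUDY2_AGE_MEAN, reference.STUDY2_AGE_SD)},
            residual_sd=reference.NULL_MODEL_RESIDUAL_SD,
            n=20_000,
            rng=rng,
        )
        fit = fit_ols(df[["age", "gender"]], df["phq9_total"])
        b = fit.coef.loc["age", "B"]
        se = fit.coef.loc["age", "se_B"]
        assert b == pytest.approx(reference.NULL_MODEL_COEF["age"], abs=3 * se)

    def test_noiseless_simulation_recovers_inputs_exactly(self):
        from taskphenotype.simulate import simulate_from_fitted_model

        rng = np.random.default_rng(7)
        coef = {"intercept": 5.0, "age": -0.2, "gender": 1.5}
        df = simulate_from_fitted_model(
            coef, {"age": (38.0, 11.0)}, residual_sd=0.0, n=500, rng=rng
        )
        fit = fit_ols(df[["age", "gender"]], df["phq9_total"])
        assert fit.coef.loc["(Intercept)", "B"] == pytest.approx(5.0, abs=1e-8)
        assert fit.coef.loc["age", "B"] == pytest.approx(-0.2, abs=1e-10)
        assert fit.coef.loc["gender", "B"] == pytest.approx(1.5, abs=1e-8)

    def test_negative_residual_sd_rejected(self):
        from taskphenotype.simulate import simulate_from_fitted_model

        with pytest.raises(ValueError, match="residual_sd"):
            simulate_from_fitted_model(
                {"intercept": 0.0}, {}, residual_sd=-1.0, n=10,
                rng=np.random.default_rng(0),
            )
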