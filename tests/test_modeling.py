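"""LM / gamma-GLM fitting, standardization, Nagelkerke R2, AIC ranking."""

import numpy as np
import pandas as pd
import pytest

from tgtacs.modeling import (
    ModelSpec,
    center_covariates,
    expand_formula,
    fit_gamma_glm,
    fit_lm,
    is_nested,
    nagelkerke_r2,
    optimize_model,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def _sim_lm(rng, n=300):
    df = pd.DataFrame({
        "gameplay": np.tile(np.arange(1, n // 2 + 1), 2),
        "group": ["sham"] * (n // 2) + ["active"] * (n // 2),
    })
    act = (df["group"] == "active").to_numpy()
    df["d_prime"] = (1.0 + 0.005 * df["gameplay"] - 1.5e-5 * df["gameplay"] ** 2
                     + 0.04 * act + 4e-4 * df["gameplay"] * act
                     + rng.normal(0, 0.1, n))
    return df


class TestFormulaDialect:
    def test_square_expansion(self):
        assert expand_formula("y ~ x + x^2") == "y ~ x + I(x**2)"

    def test_square_without_linear_term_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("y ~ x^2")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("y ~ x", family="poisson")


class TestCenterCovariates:
    def test_centering(self):
        t = pd.DataFrame({"age": [60.0, 70.0, 80.0], "moca": [20.0, 25.0, 30.0]})
        out = center_covariates(t)
        assert out["age_c"].tolist() == [-10.0, 0.0, 10.0]
        assert abs(out["age_c"].sum()) < 1e-9
        assert out.attrs["covariate_means"]["age"] == 70.0

    def test_idempotent(self):
        t = pd.DataFrame({"age": [60.0, 80.0], "moca": [20.0, 30.0]})
        once = center_covariates(t)
        twice = center_covariates(once.rename(columns={"age_c": "x"}),
                                  columns=("age",))
        assert np.allclose(once["age_c"], twice["age_c"])

    def test_all_missing_signalled(self):
        t = pd.DataFrame({"age": [np.nan, np.nan], "moca": [25.0, 26.0]})
        with pytest.raises(ValueError, match="age"):
            center_covariates(t)


class TestLM:
    def test_noiseless_recovery(self):
        df = pd.DataFrame({"g": np.arange(1, 50, dtype=float)})
        df["y"] = 1.0 + 2.0 * df["g"]
        fit = fit_lm(ModelSpec("y ~ g"), df, standardize=False)
        assert fit.terms.loc["g", "beta"] == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_pure_noise_slope_ci_covers_zero_at_nominal_rate(self):
        hits = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            df = pd.DataFrame({"x": r.normal(size=40), "y": r.normal(size=40)})
            fit = fit_lm(ModelSpec("y ~ x"), df, standardize=False)
            lo, hi = fit.terms.loc["x", ["ci_low", "ci_high"]]
            hits += lo <= 0 <= hi
        assert 0.90 <= hits / 200 <= 0.99

    def test_duplicate_predictor_rank_deficiency(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df["x2"] = df["x"]
        df["y"] = rng.normal(size=30)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_lm(ModelSpec("y ~ x + x2"), df)

    def test_row_order_invariance(self, rng):
        df = _sim_lm(rng)
        spec = ModelSpec("d_prime ~ gameplay * group + gameplay^2")
        a = fit_lm(spec, df, standardize=False)
        b = fit_lm(spec, df.sample(frac=1, random_state=1), standardize=False)
        pd.testing.assert_frame_equal(a.terms, b.terms, atol=1e-10, rtol=1e-8)

    def test_p_values_invariant_under_affine_covariate_recode(self, rng):
        df = _sim_lm(rng)
        df["age"] = rng.normal(70, 7, len(df))
        spec = ModelSpec("d_prime ~ gameplay + age")
        a = fit_lm(spec, df, standardize=False)
        df2 = df.assign(age=(df["age"] - 70.0) / 7.0)
        b = fit_lm(spec, df2, standardize=False)
        assert a.terms.loc["age", "p"] == pytest.approx(b.terms.loc["age", "p"])
        assert a.terms.loc["age", "beta"] == pytest.approx(
            b.terms.loc["age", "beta"] / 7.0)

    def test_aic_identity(self, rng):
        df = _sim_lm(rng)
        fit = fit_lm(ModelSpec("d_prime ~ gameplay * group"), df, standardize=False)
        assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.loglik)


class TestStandardizedBetas:
    def test_simple_lm_std_beta_is_pearson_r(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=200)})
        df["y"] = 1.5 * df["x"] + rng.normal(size=200)
        fit = fit_lm(ModelSpec("y ~ x"), df)
        r = np.corrcoef(df["x"], df["y"])[0, 1]
        assert fit.std_terms.loc["x", "std_beta"] == pytest.approx(r, abs=1e-10)

    def test_invariant_under_predictor_rescaling(self, rng):
        df = _sim_lm(rng)
        spec = ModelSpec("d_prime ~ gameplay")
        a = fit_lm(spec, df)
        b = fit_lm(spec, df.assign(gameplay=df["gameplay"] * 1000.0))
        assert a.std_terms.loc["gameplay", "std_beta"] == pytest.approx(
            b.std_terms.loc["gameplay", "std_beta"])

    def test_sign_agreement_with_raw_beta(self, rng):
        df = _sim_lm(rng)
        fit = fit_lm(ModelSpec("d_prime ~ gameplay * group + gameplay^2"), df)
        for term in ("gameplay", "I(gameplay ** 2)"):
            assert np.sign(fit.std_terms.loc[term, "std_beta"]) == np.sign(
                fit.terms.loc[term, "beta"])

    def test_zero_variance_predictor_signalled(self, rng):
        df = pd.DataFrame({"x": np.ones(20), "z": rng.normal(size=20)})
        df["y"] = rng.normal(size=20)
        with pytest.raises(ValueError):
            fit_lm(ModelSpec("y ~ x + z"), df)


class TestGammaGLM:
    def test_intercept_only_recovers_sample_mean(self, rng):
        df = pd.DataFrame({"rt": rng.gamma(20, 500 / 20, size=400)})
        fit = fit_gamma_glm(ModelSpec("rt ~ 1", "gamma_log"), df, standardize=False)
        assert np.exp(fit.terms.loc["Intercept", "beta"]) == pytest.approx(
            df["rt"].mean(), rel=1e-8)

    def test_recovers_generating_coefficients_within_3se(self, rng):
        n = 5000
        g = rng.uniform(1, 160, n)
        mu = np.exp(6.5 - 0.004 * g)
        df = pd.DataFrame({"g": g, "rt": rng.gamma(15.0, mu / 15.0)})
        fit = fit_gamma_glm(ModelSpec("rt ~ g", "gamma_log"), df, standardize=False)
        for term, truth in (("Intercept", 6.5), ("g", -0.004)):
            beta, se = fit.terms.loc[term, ["beta", "se"]]
            assert abs(beta - truth) < 3 * se

    def test_true_quadratic_term_lowers_aic(self):
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            g = r.uniform(1, 160, 5000)
            mu = np.exp(6.5 - 0.01 * g + 4e-5 * g**2)
            df = pd.DataFrame({"g": g, "rt": r.gamma(15.0, mu / 15.0)})
            lin = fit_gamma_glm(ModelSpec("rt ~ g", "gamma_log"), df,
                                standardize=False)
            quad = fit_gamma_glm(ModelSpec("rt ~ g + g^2", "gamma_log"), df,
                                 standardize=False)
            wins += quad.aic < lin.aic
        assert wins >= 19

    def test_nonpositive_response_signalled(self, rng):
        df = pd.DataFrame({"g": [1.0, 2.0, 3.0], "rt": [100.0, -5.0, 200.0]})
        with pytest.raises(ValueError):
            fit_gamma_glm(ModelSpec("rt ~ g", "gamma_log"), df)

    def test_converges_on_generator_scale_data(self, clean_tables, schedule):
        from tgtacs.preprocessing import run_filter_pipeline

        _, g = clean_tables
        filt, _ = run_filter_pipeline(g, "rt", schedule)
        mm = filt[filt["task"] == "mm_2back"].rename(
            columns={"gameplay_index": "gameplay"})
        fit = fit_gamma_glm(
            ModelSpec("mean_rt ~ gameplay * group + gameplay^2", "gamma_log"), mm,
            standardize=False)
        assert fit.nagelkerke_r_squared is not None
        assert fit.terms.loc["gameplay", "beta"] < 0


class TestNagelkerke:
    def test_null_fit_gives_zero(self, rng):
        df = pd.DataFrame({"rt": rng.gamma(10, 50, size=200)})
        fit = fit_gamma_glm(ModelSpec("rt ~ 1", "gamma_log"), df, standardize=False)
        assert fit.nagelkerke_r_squared == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_signal_strength(self):
        r2s = []
        for slope in (0.0, -0.002, -0.004, -0.008):
            r = np.random.default_rng(17)
            g = r.uniform(1, 160, 2000)
            df = pd.DataFrame({"g": g,
                               "rt": r.gamma(15.0, np.exp(6.5 + slope * g) / 15.0)})
            fit = fit_gamma_glm(ModelSpec("rt ~ g", "gamma_log"), df,
                                standardize=False)
            r2s.append(fit.nagelkerke_r_squared)
        assert all(a < b for a, b in zip(r2s, r2s[1:]))
        assert all(0.0 <= v <= 1.0 for v in r2s)


class TestTrialScaleRecovery:
    def test_interaction_sign_recovered_at_observed_effect_size(self):
        """At the trial's effect size (interaction std beta ~ 0.14, mean
        t ~ 1.6) the fitted interaction is positive in the large majority
        of replicates (P ~ Phi(1.6) ~ 0.94)."""
        from conftest import mm_dprime_aggregate

        spec = ModelSpec("d_prime ~ gameplay_index * group + gameplay_index^2")
        positive = 0
        for seed in range(100):
            terms = fit_lm(spec, mm_dprime_aggregate(40_000 + seed),
                           standardize=False).terms
            positive += terms.loc["gameplay_index:group[T.active]", "beta"] > 0
        assert positive >= 87


class TestOptimize:
    def test_duplicate_specs_tie_keeps_first(self, rng):
        df = _sim_lm(rng)
        s = ModelSpec("d_prime ~ gameplay")
        best, ledger = optimize_model([s, ModelSpec("d_prime ~ gameplay")], df)
        assert best is s

    def test_nesting_detection(self):
        a = ModelSpec("y ~ g + group")
        b = ModelSpec("y ~ g * group")
        c = ModelSpec("y ~ g * group + g^2")
        assert is_nested(a, b) and is_nested(b, c) and not is_nested(c, a)

    def test_ledger_ranks_by_aic_with_lr_p(self, rng):
        df = _sim_lm(rng)
        cands = [ModelSpec("d_prime ~ gameplay + group"),
                 ModelSpec("d_prime ~ gameplay * group"),
                 ModelSpec("d_prime ~ gameplay * group + gameplay^2")]
        best, ledger = optimize_model(cands, df)
        assert (ledger["aic"].diff().dropna() >= 0).all()
        assert ledger.loc[0, "best"]
        assert ledger.loc[1:, "lr_p_vs_best"].notna().any()

    def test_different_row_subsets_signalled(self, rng):
        df = _sim_lm(rng)
        df["extra"] = rng.normal(size=len(df))
        df.loc[df.index[:10], "extra"] = np.nan
        with pytest.raises(ValueError, match="row subsets"):
            optimize_model([ModelSpec("d_prime ~ gameplay"),
                            ModelSpec("d_prime ~ extra")], df)
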