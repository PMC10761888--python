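"""Model reduction, OLS fitting, fit statistics, and nested tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from neckfda import (
    BasisCurve,
    CollinearityError,
    ConformanceError,
    FormulaError,
    GeneratorConfig,
    ModelSpec,
    NotNestedError,
    build_design,
    coefficient_function,
    eval_basis,
    fit_formula,
    fit_sofr,
    make_basis,
    nested_f_test,
    parse_formula,
    predict,
)
from neckfda.simulate import generate_dataset

FINE = np.linspace(0.0, 1.0, 10_001)


def random_curves(rng, n, k=9, scale=1.0):
    basis = make_basis(k)
    return [
        BasisCurve(basis, rng.normal(0, scale, size=k), role="angular_velocity")
        for _ in range(n)
    ]


class TestFormula:
    @pytest.mark.parametrize(
        "formula, n_func, scalars",
        [
            ("ndi ~ RoM", 0, ("RoM",)),
            ("ndi ~ RoM + RoV + RoM:RoV", 0, ("RoM", "RoV", "RoM:RoV")),
            ("ndi ~ omega(t)", 1, ()),
            ("ndi ~ omega(t) + RoV + RoM", 1, ("RoV", "RoM")),
        ],
    )
    def test_parse_table_notation(self, formula, n_func, scalars):
        spec = parse_formula(formula)
        assert len(spec.functional_terms) == n_func
        assert spec.scalar_terms == scalars
        assert spec.label == formula

    def test_interaction_requires_main_effects(self):
        with pytest.raises(FormulaError):
            parse_formula("ndi ~ RoM:RoV")

    def test_malformed_formulas_rejected(self):
        for bad in ("ndi RoM", "~ RoM", "a ~ b ~ c"):
            with pytest.raises(FormulaError):
                parse_formula(bad)


class TestDesign:
    def test_zero_curves_give_zero_vscore_columns(self, rng):
        curves = {"omega": [BasisCurve(make_basis(9), np.zeros(9))] * 4}
        spec = ModelSpec("y", functional_terms=(("omega", 5),))
        d = build_design(curves, None, spec)
        assert d.X.shape == (4, 6)
        np.testing.assert_array_equal(d.X[:, 1:], 0.0)

    def test_identity_gram_makes_vscores_the_coefficients(self, rng):
        curves = {"omega": random_curves(rng, 6, k=9)}
        spec = ModelSpec("y", functional_terms=(("omega", 9),))
        d = build_design(curves, None, spec)
        C = np.stack([c.coefs for c in curves["omega"]])
        np.testing.assert_array_equal(d.X[:, 1:], C)

    def test_vscores_match_quadrature_inner_products(self, rng):
        """v_k equals the trapezoid integral of theta_k * x_i."""
        curves = {"omega": random_curves(rng, 3, k=9)}
        spec = ModelSpec("y", functional_terms=(("omega", 5),))
        d = build_design(curves, None, spec)
        theta = eval_basis(make_basis(5), FINE)
        x0 = curves["omega"][0](FINE)
        v_quad = np.trapezoid(theta * x0[:, None], FINE, axis=0)
        assert np.max(np.abs(d.X[0, 1:6] - v_quad)) < 1e-8


class TestFit:
    def test_exact_linear_response_fits_perfectly(self, rng):
        x = rng.normal(size=30)
        scalars = pd.DataFrame({"x": x, "y": 2.0 + 3.0 * x})
        spec = ModelSpec("y", scalar_terms=("x",))
        fit = fit_sofr(build_design({}, scalars, spec), scalars["y"].to_numpy())
        assert fit.stats.r2 == 1.0
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)

    def test_constant_response_gives_null_fit(self, rng):
        scalars = pd.DataFrame({"x": rng.normal(size=20), "y": 5.0})
        spec = ModelSpec("y", scalar_terms=("x",))
        fit = fit_sofr(build_design({}, scalars, spec), scalars["y"].to_numpy())
        assert fit.stats.r2 == 0.0
        assert fit.stats.F == 0.0
        assert fit.beta0 == pytest.approx(5.0)

    def test_six_point_f_statistic_by_hand(self):
        """F from the explicit RSS formula on a hand-checkable dataset."""
        x = np.arange(1.0, 7.0)
        y = 2 * x + np.array([0.1, -0.1, 0.2, -0.2, 0.1, -0.1])
        scalars = pd.DataFrame({"x": x, "y": y})
        spec = ModelSpec("y", scalar_terms=("x",))
        fit = fit_sofr(build_design({}, scalars, spec), y)
        # independent oracle: explicit RSS of the two models
        b, a = np.polyfit(x, y, 1)
        rss1 = np.sum((y - (a + b * x)) ** 2)
        rss0 = np.sum((y - y.mean()) ** 2)
        f_hand = ((rss0 - rss1) / 1) / (rss1 / 4)
        assert fit.stats.F == pytest.approx(f_hand, rel=1e-12)
        assert fit.stats.df1 == 1 and fit.stats.df2 == 4

    def test_agrees_with_statsmodels_ols(self, rng):
        """Cross-check coefficients and statistics against statsmodels."""
        curves = {"omega": random_curves(rng, 40, k=9)}
        scalars = pd.DataFrame(
            {"z": rng.normal(size=40), "y": rng.normal(10, 3, size=40)}
        )
        spec = ModelSpec("y", functional_terms=(("omega", 5),),
                         scalar_terms=("z",))
        design = build_design(curves, scalars, spec)
        fit = fit_sofr(design, scalars["y"].to_numpy())
        ref = sm.OLS(scalars["y"].to_numpy(), design.X).fit()
        np.testing.assert_allclose(fit.coefs, ref.params, atol=1e-10)
        assert fit.stats.r2 == pytest.approx(ref.rsquared, rel=1e-12)
        assert fit.stats.F == pytest.approx(ref.fvalue, rel=1e-10)
        assert fit.stats.p_value == pytest.approx(ref.f_pvalue, rel=1e-8)

    def test_duplicate_scalar_columns_fail_loudly(self, rng):
        x = rng.normal(size=20)
        scalars = pd.DataFrame({"a": x, "b": x * 2.0, "y": rng.normal(size=20)})
        spec = ModelSpec("y", scalar_terms=("a", "b"))
        with pytest.raises(CollinearityError):
            fit_sofr(build_design({}, scalars, spec), scalars["y"].to_numpy())

    def test_monotone_r2_when_adding_predictors(self, analytic_study):
        st = analytic_study
        r2 = [
            fit_formula(f, st.curves, st.scalars).stats.r2
            for f in ("ndi ~ RoV", "ndi ~ RoM + RoV",
                      "ndi ~ omega(t) + RoV + RoM")
        ]
        assert r2[0] <= r2[1] + 1e-12 <= r2[2] + 2e-12


class TestReductionEquivalence:
    def test_vscore_fit_equals_quadrature_functional_ols(self, rng):
        """The Gram-matrix reduction equals brute-force functional OLS."""
        for k_beta in (5, 9):
            cfg = GeneratorConfig(seed=int(rng.integers(2**31)), n_subjects=55,
                                  sessions_per_subject=1)
            st = generate_dataset(cfg, curves_only=True)
            y = st.scalars["ndi"].to_numpy(float)
            spec = ModelSpec("ndi", functional_terms=(("omega", k_beta),))
            design = build_design(st.curves, None, spec)
            fit = fit_sofr(design, y)
            # brute force: every inner product by fine quadrature
            theta = eval_basis(make_basis(k_beta), FINE)
            V = np.stack([
                np.trapezoid(theta * c(FINE)[:, None], FINE, axis=0)
                for c in st.curves["omega"]
            ])
            Xq = np.hstack([np.ones((len(y), 1)), V])
            keep = np.linalg.norm(Xq, axis=0) > 1e-10 * np.linalg.norm(
                Xq, axis=0).max()
            ref = np.zeros(Xq.shape[1])
            ref[keep], *_ = np.linalg.lstsq(Xq[:, keep], y, rcond=None)
            assert np.max(np.abs(fit.coefs - ref)) < 1e-8


class TestPredictAndCoefFunction:
    def test_zero_inputs_predict_the_intercept(self, rng):
        curves = {"omega": random_curves(rng, 12, k=9)}
        scalars = pd.DataFrame(
            {"z": rng.normal(size=12), "y": rng.normal(size=12)}
        )
        spec = ModelSpec("y", functional_terms=(("omega", 5),),
                         scalar_terms=("z",))
        fit = fit_sofr(build_design(curves, scalars, spec),
                       scalars["y"].to_numpy())
        zero = {"omega": [BasisCurve(make_basis(9), np.zeros(9))]}
        out = predict(fit, zero, pd.DataFrame({"z": [0.0]}))
        assert out[0] == pytest.approx(fit.beta0, abs=1e-12)

    def test_training_predictions_match_fitted(self, analytic_study):
        st = analytic_study
        fit = fit_formula("ndi ~ omega(t) + RoV", st.curves, st.scalars)
        out = predict(fit, st.curves, st.scalars)
        np.testing.assert_allclose(out, fit.fitted, atol=1e-12)

    def test_prediction_equals_quadrature_integral(self, analytic_study):
        st = analytic_study
        fit = fit_formula("ndi ~ omega(t)", st.curves, st.scalars)
        beta1 = coefficient_function(fit, "omega", FINE)
        for i in (0, 7):
            integral = np.trapezoid(beta1.values * st.curves["omega"][i](FINE),
                                    FINE)
            out = predict(fit, {"omega": [st.curves["omega"][i]]})
            assert abs(out[0] - (fit.beta0 + integral)) < 1e-8

    def test_unknown_term_lookup_fails(self, analytic_study):
        fit = fit_formula("ndi ~ omega(t)", analytic_study.curves,
                          analytic_study.scalars)
        with pytest.raises(KeyError):
            coefficient_function(fit, "nope", FINE)

    def test_noiseless_coefficient_function_recovered(self):
        cfg = GeneratorConfig(seed=1234, n_subjects=60, sessions_per_subject=1,
                              response_noise_sd=0.0)
        st = generate_dataset(cfg, curves_only=True, round_scores=False)
        fit = fit_formula("ndi ~ omega(t)", st.curves, st.scalars)
        est = coefficient_function(fit, "omega", FINE).values
        truth = eval_basis(make_basis(9), FINE) @ st.ground_truth.true_b
        assert np.max(np.abs(est - truth)) < 1e-6

    def test_conformance_error_on_missing_term(self, analytic_study):
        fit = fit_formula("ndi ~ omega(t)", analytic_study.curves,
                          analytic_study.scalars)
        with pytest.raises(ConformanceError):
            predict(fit, {}, None)


class TestNested:
    def test_intercept_only_vs_full_reproduces_overall_f(self, analytic_study):
        st = analytic_study
        null_fit = fit_formula("ndi ~ 1", st.curves, st.scalars)
        full = fit_formula("ndi ~ omega(t)", st.curves, st.scalars)
        res = nested_f_test(null_fit, full)
        assert res.F == pytest.approx(full.stats.F, rel=1e-12)
        assert res.p_value == pytest.approx(full.stats.p_value, rel=1e-12)
        assert (res.df1, res.df2) == (full.stats.df1, full.stats.df2)

    def test_not_nested_rejected(self, analytic_study):
        st = analytic_study
        a = fit_formula("ndi ~ RoM", st.curves, st.scalars)
        b = fit_formula("ndi ~ omega(t)", st.curves, st.scalars)
        with pytest.raises(NotNestedError):
            nested_f_test(a, b)

    def test_null_extra_column_f_has_mean_one(self, rng):
        """Adding orthogonalized noise gives F with mean ~ df2/(df2-2)."""
        n = 40
        fs = []
        for _ in range(500):
            x = rng.normal(size=n)
            y = 1.0 + 0.5 * x + rng.normal(size=n)
            z = rng.normal(size=n)
            X0 = np.column_stack([np.ones(n), x])
            z = z - X0 @ np.linalg.lstsq(X0, z, rcond=None)[0]
            scalars = pd.DataFrame({"x": x, "z": z, "y": y})
            f0 = fit_sofr(build_design({}, scalars,
                                       ModelSpec("y", scalar_terms=("x",))), y)
            f1 = fit_sofr(build_design({}, scalars,
                                       ModelSpec("y", scalar_terms=("x", "z"))), y)
            fs.append(nested_f_test(f0, f1).F)
        expected = (n - 3) / (n - 5)  # mean of F(1, n-3)
        assert abs(np.mean(fs) - expected) < 0.1


class TestAIC:
    def test_nested_aic_difference_identity(self, analytic_study):
        """AIC_0 - AIC_1 = n log(RSS_0/RSS_1) - 2 (p_1 - p_0)."""
        st = analytic_study
        f0 = fit_formula("ndi ~ RoM + RoV", st.curves, st.scalars)
        f1 = fit_formula("ndi ~ omega(t) + RoV + RoM", st.curves, st.scalars)
        n = f0.stats.n
        dparams = f1.stats.n_params - f0.stats.n_params
        expected = n * np.log(f0.rss / f1.rss) - 2 * dparams
        assert f0.stats.aic - f1.stats.aic == pytest.approx(expected, rel=1e-12)

    def test_aic_definition_minus_two_loglik_plus_two_params(self, analytic_study):
        st = analytic_study
        fit = fit_formula("ndi ~ RoV", st.curves, st.scalars)
        n, rss = fit.stats.n, fit.rss
        loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
        assert fit.stats.aic == pytest.approx(
            -2 * loglik + 2 * (fit.stats.n_params + 1), rel=1e-12
        )


class TestNoiselessIdentifiability:
    def test_sigma_zero_refit_has_unit_correlation(self):
        cfg = GeneratorConfig(seed=77, n_subjects=55, sessions_per_subject=1,
                              response_noise_sd=0.0)
        st = generate_dataset(cfg, curves_only=True, round_scores=False)
        fit = fit_formula("ndi ~ omega(t)", st.curves, st.scalars)
        assert fit.stats.r == 1.0
        np.testing.assert_allclose(fit.b("omega"), st.ground_truth.true_b,
                                   atol=1e-6)
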