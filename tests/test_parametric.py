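"""Parametric AFT/PH engine: closed forms, invariances, nesting, recovery."""

import numpy as np
import pandas as pd
import pytest

from survstc import (
    IPDDataset,
    ValidationError,
    aft_hazard,
    aft_survival,
    fit_parametric,
    generate_ipd,
    linear_predictor,
    predict_median,
)
from survstc.parametric import FittedSurvivalModel


def make_model(family, mu=0.0, beta=None, ancillary=None, centering=None):
    return FittedSurvivalModel(
        family=family,
        mu=mu,
        covariate_coefs=beta or {},
        ancillary=ancillary or {},
        centering=centering or {},
        loglik=0.0,
        n_params=1,
        converged=True,
    )


class TestLinearPredictor:
    def test_no_covariates_returns_intercept(self):
        m = make_model("exponential", mu=1.7)
        assert linear_predictor(m, {"anything": 99}) == 1.7

    def test_log2_coefficient_doubles_theta(self):
        m = make_model("exponential", mu=0.0, beta={"x": np.log(2)})
        assert linear_predictor(m, {"x": 1}) == pytest.approx(np.log(2))

    def test_opposite_coefficients_cancel(self):
        m = make_model("exponential", mu=0.5, beta={"a": 1.0, "b": -1.0})
        assert linear_predictor(m, {"a": 2, "b": 2}) == pytest.approx(0.5)

    def test_missing_covariate_named_in_error(self):
        m = make_model("exponential", beta={"age": 0.1})
        with pytest.raises(ValidationError, match="age"):
            linear_predictor(m, {"sex": 1})


class TestAFTCurves:
    def test_survival_is_one_at_time_zero(self):
        for family, anc in [
            ("exponential", {}),
            ("weibull", {"shape": 2.0}),
            ("gamma", {"shape": 1.5}),
            ("loglogistic", {"shape": 2.0}),
            ("lognormal", {"sigma": 0.7}),
            ("genf", {"sigma": 0.8, "Q": 0.3, "P": 0.5}),
            ("gompertz", {"shape": 0.1}),
        ]:
            m = make_model(family, ancillary=anc)
            assert aft_survival(m, {}, 0.0) == 1.0

    def test_exponential_closed_form_with_acceleration(self):
        # rate 0.5 baseline, theta=2: S(1) = exp(-0.5*2*1)
        m = make_model("exponential", mu=np.log(0.5) + np.log(2))
        assert aft_survival(m, {}, 1.0) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_theta_one_reproduces_baseline_curve(self):
        m0 = make_model("weibull", mu=-1.0, ancillary={"shape": 1.4})
        m1 = make_model(
            "weibull", mu=-1.0, beta={"x": 0.8}, ancillary={"shape": 1.4}
        )
        t = np.linspace(0.1, 20, 50)
        np.testing.assert_allclose(
            aft_survival(m1, {"x": 0.0}, t), aft_survival(m0, {}, t), rtol=1e-12
        )

    def test_weibull_hazard_hand_value(self):
        # unit scale, shape 2, theta=1: h(1) = shape * t^(shape-1) = 2
        m = make_model("weibull", ancillary={"shape": 2.0})
        assert aft_hazard(m, {}, 1.0) == pytest.approx(2.0, abs=1e-12)

    def test_exponential_hazard_constant_theta_lambda(self):
        m = make_model("exponential", mu=np.log(0.3) + 0.7)
        t = np.array([0.5, 2.0, 9.0])
        np.testing.assert_allclose(aft_hazard(m, {}, t), 0.3 * np.exp(0.7), rtol=1e-12)

    def test_hazard_nonpositive_time_rejected(self):
        m = make_model("exponential")
        with pytest.raises(ValidationError):
            aft_hazard(m, {}, 0.0)

    @pytest.mark.parametrize(
        "family,anc",
        [
            ("weibull", {"shape": 1.7}),
            ("gamma", {"shape": 2.2}),
            ("loglogistic", {"shape": 1.9}),
            ("lognormal", {"sigma": 0.6}),
            ("genf", {"sigma": 0.9, "Q": 0.4, "P": 0.6}),
            ("gompertz", {"shape": 0.15}),
        ],
    )
    def test_hazard_matches_numerical_log_survival_derivative(self, family, anc):
        m = make_model(family, mu=-0.4, beta={"x": 0.3}, ancillary=anc)
        X = {"x": 1.0}
        t = np.linspace(0.5, 8.0, 13)
        eps = 1e-5
        s_hi = aft_survival(m, X, t + eps)
        s_lo = aft_survival(m, X, t - eps)
        h_num = -(np.log(s_hi) - np.log(s_lo)) / (2 * eps)
        np.testing.assert_allclose(aft_hazard(m, X, t), h_num, rtol=1e-5, atol=1e-8)

    def test_aft_consistency_s_of_t_theta(self):
        # S(t|X) equals S0(t * exp(lp(X))) for every AFT family
        for family, anc in [
            ("weibull", {"shape": 1.3}),
            ("gamma", {"shape": 0.8}),
            ("loglogistic", {"shape": 2.5}),
            ("lognormal", {"sigma": 1.1}),
            ("genf", {"sigma": 0.7, "Q": -0.2, "P": 0.4}),
        ]:
            m = make_model(family, mu=0.3, beta={"x": 0.5}, ancillary=anc)
            m0 = make_model(family, mu=0.0, ancillary=anc)
            t = np.linspace(0.2, 15, 40)
            theta = np.exp(0.3 + 0.5 * 2.0)
            np.testing.assert_allclose(
                aft_survival(m, {"x": 2.0}, t),
                aft_survival(m0, {}, t * theta),
                rtol=1e-12,
                atol=1e-15,
            )

    def test_genf_limits_to_loglogistic_and_lognormal(self):
        t = np.linspace(0.1, 10, 80)
        sigma = 0.8
        # Q=0, P=1 corner: log-logistic with shape sqrt(2)/sigma, unit scale
        genf_ll = make_model("genf", ancillary={"sigma": sigma, "Q": 0.0, "P": 1.0})
        loglog = make_model("loglogistic", ancillary={"shape": np.sqrt(2.0) / sigma})
        np.testing.assert_allclose(
            aft_survival(genf_ll, {}, t), aft_survival(loglog, {}, t), atol=1e-4
        )
        # Q=0, P->0 limit: log-normal with the same sigma
        genf_ln = make_model("genf", ancillary={"sigma": sigma, "Q": 0.0, "P": 1e-7})
        lognorm = make_model("lognormal", ancillary={"sigma": sigma})
        np.testing.assert_allclose(
            aft_survival(genf_ln, {}, t), aft_survival(lognorm, {}, t), atol=1e-4
        )


class TestFitParametric:
    def test_exponential_mle_closed_form(self, tiny_ipd):
        fit = fit_parametric(tiny_ipd, "exponential")
        assert np.exp(fit.mu) == pytest.approx(0.4, abs=1e-9)
        assert fit.loglik == pytest.approx(4 * np.log(0.4) - 4, abs=1e-9)
        assert fit.converged

    def test_aic_identity(self, weibull_binary_data):
        fit = fit_parametric(weibull_binary_data, "weibull", ["x"])
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params, abs=1e-12)
        assert fit.n_params == 3

    def test_all_censored_rejected(self):
        data = IPDDataset(
            time=np.array([1.0, 2.0]),
            event=np.array([0, 0]),
            covariates=pd.DataFrame(index=range(2)),
        )
        with pytest.raises(ValidationError):
            fit_parametric(data, "weibull")

    def test_refit_is_bit_identical(self, weibull_binary_data):
        f1 = fit_parametric(weibull_binary_data, "gamma", ["x"])
        f2 = fit_parametric(weibull_binary_data, "gamma", ["x"])
        assert f1.mu == f2.mu
        assert f1.loglik == f2.loglik
        assert f1.covariate_coefs == f2.covariate_coefs

    def test_weibull_nests_exponential(self, weibull_binary_data):
        fe = fit_parametric(weibull_binary_data, "exponential", ["x"])
        fw = fit_parametric(weibull_binary_data, "weibull", ["x"])
        assert fw.loglik >= fe.loglik - 1e-6

    def test_centering_is_likelihood_neutral(self):
        # continuous covariate: centering shifts mu by beta*c, nothing else
        data = generate_ipd(
            family="weibull",
            params={"mu": -3.5, "shape": 1.2},
            beta={"age": 0.02},
            covariate_model={"age": ("normal", 60.0, 9.0)},
            n=400,
            censoring=(40.0, 0.01),
            seed=9,
        )
        fit = fit_parametric(data, "weibull", ["age"])
        c = fit.centering["age"]
        assert c == pytest.approx(data.covariates["age"].mean())
        shifted = IPDDataset(
            time=data.time,
            event=data.event,
            covariates=data.covariates - c,
        )
        fit0 = fit_parametric(shifted, "weibull", ["age"])
        assert fit0.centering["age"] == pytest.approx(0.0, abs=1e-9)
        assert fit.loglik == pytest.approx(fit0.loglik, abs=1e-6)
        assert fit.covariate_coefs["age"] == pytest.approx(
            fit0.covariate_coefs["age"], abs=1e-4
        )
        # both parameterisations give the same survival prediction
        t = np.linspace(1, 30, 10)
        np.testing.assert_allclose(
            aft_survival(fit, {"age": 65.0}, t),
            aft_survival(fit0, {"age": 65.0 - c}, t),
            atol=2e-4,
        )

    def test_beta_log2_halves_predicted_median(self):
        # doubling a covariate with coefficient log 2 halves expected survival
        m = make_model(
            "weibull", mu=-2.0, beta={"x": np.log(2)}, ancillary={"shape": 1.3}
        )
        med1 = predict_median(m, {"x": 1.0})
        med2 = predict_median(m, {"x": 2.0})
        assert med2 == pytest.approx(med1 / 2.0, rel=1e-9)

    def test_gompertz_reduces_to_exponential_at_zero_shape(self, weibull_binary_data):
        fg = fit_parametric(weibull_binary_data, "gompertz", ["x"])
        # fitted curve must be a valid survival function
        t = np.linspace(0.1, 30, 100)
        s = aft_survival(fg, {"x": 1.0}, t)
        assert np.all(np.diff(s) <= 1e-12) and s[0] <= 1.0

    def test_model_json_round_trip(self, weibull_binary_data):
        fit = fit_parametric(weibull_binary_data, "weibull", ["x"])
        back = FittedSurvivalModel.from_json(fit.to_json())
        assert back.family == fit.family
        assert back.mu == fit.mu
        assert back.covariate_coefs == fit.covariate_coefs
        assert back.aic == pytest.approx(fit.aic)
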