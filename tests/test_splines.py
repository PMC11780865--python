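"""Royston-Parmar splines: basis algebra, links, nesting identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survstc import (
    ValidationError,
    fit_parametric,
    fit_spline,
    generate_ipd,
    place_knots,
    spline_hazard,
    spline_survival,
)
from survstc.parametric import FittedSurvivalModel
from survstc.splines import SplineBasis, _spline_eval, basis_values


def make_spline_model(knots, gamma, link, beta=None, centering=None):
    return FittedSurvivalModel(
        family="spline",
        link=link,
        knots=tuple(knots),
        mu=gamma[0],
        spline_coefs=tuple(gamma),
        covariate_coefs=beta or {},
        centering=centering or {},
        loglik=0.0,
        n_params=len(gamma),
        converged=True,
    )


class TestKnotPlacement:
    def test_median_knot_for_m_equal_one(self):
        # event times e^0, e^1, e^2 -> boundary 0/2, internal at median 1
        data = generate_ipd(
            family="exponential", params={"mu": 0.0}, n=3, censoring=(np.inf, 0.0), seed=0
        )
        data = data.__class__(
            time=np.exp([0.0, 1.0, 2.0]),
            event=np.array([1, 1, 1]),
            covariates=data.covariates.iloc[:3],
        )
        basis = place_knots(data, 1)
        assert basis.k_min == pytest.approx(0.0)
        assert basis.k_max == pytest.approx(2.0)
        assert basis.internal[0] == pytest.approx(1.0)

    def test_m_zero_boundary_only(self, weibull_binary_data):
        basis = place_knots(weibull_binary_data, 0)
        assert basis.m == 0
        ev = np.log(weibull_binary_data.time[weibull_binary_data.event == 1])
        assert basis.k_min == pytest.approx(ev.min())
        assert basis.k_max == pytest.approx(ev.max())

    def test_quantile_internal_knots(self, weibull_binary_data):
        basis = place_knots(weibull_binary_data, 3)
        ev = np.log(weibull_binary_data.time[weibull_binary_data.event == 1])
        np.testing.assert_allclose(basis.internal, np.quantile(ev, [0.25, 0.5, 0.75]))

    def test_degenerate_identical_event_times_rejected(self):
        from survstc import IPDDataset
        import pandas as pd

        data = IPDDataset(
            time=np.array([2.0, 2.0, 2.0, 5.0]),
            event=np.array([1, 1, 1, 0]),
            covariates=pd.DataFrame(index=range(4)),
        )
        with pytest.raises(ValidationError):
            place_knots(data, 1)


class TestBasis:
    def test_zero_below_first_knot(self):
        basis = SplineBasis(k_min=0.0, k_max=2.0, internal=(1.0,))
        v = basis_values(basis, np.array([-3.0, -0.1, 0.0]))
        np.testing.assert_array_equal(v, 0.0)

    def test_hand_evaluated_value(self):
        # k_min=0, k_max=1, k_j=0.5 at u=1: theta=0.5, v = .125 - .5*1 - 0
        basis = SplineBasis(k_min=0.0, k_max=1.0, internal=(0.5,))
        v = basis_values(basis, 1.0)
        assert v[-1] == pytest.approx(-0.375, abs=1e-15)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        ks=st.lists(
            st.floats(-2.0, 3.0), min_size=3, max_size=5, unique=True
        ).filter(lambda v: min(np.diff(sorted(v))) > 0.1),
        gammas=st.lists(st.floats(-2.0, 2.0), min_size=5, max_size=5),
    )
    def test_curvature_continuous_and_linear_in_tails(self, ks, gammas):
        ks = sorted(ks)
        basis = SplineBasis(k_min=ks[0], k_max=ks[-1], internal=tuple(ks[1:-1]))
        gamma = np.array(gammas[: basis.m + 2])
        # the spline is piecewise cubic, so a central second difference is
        # exact (up to roundoff) whenever the stencil stays within one piece
        h = 0.01

        def second(u):
            u = np.asarray(u)
            sp, _ = _spline_eval(basis, gamma, u + h)
            sm, _ = _spline_eval(basis, gamma, u - h)
            s0, _ = _spline_eval(basis, gamma, u)
            return (sp - 2 * s0 + sm) / h**2

        # linear beyond the boundary knots: curvature numerically zero
        outside = np.array([ks[0] - 1.0, ks[0] - 0.2, ks[-1] + 0.2, ks[-1] + 1.0])
        assert np.all(np.abs(second(outside)) < 1e-8)
        # second derivative continuous across each knot: the jump seen over
        # a +-eps window is bounded by the third-derivative slope, far below
        # the O(6*gamma) jump an unrestricted cubic would show
        eps = 0.03
        slope_bound = 6.0 * np.sum(np.abs(gamma)) * 2 * (eps + h) + 1e-8
        for k in ks:
            jump = abs(float(second(k + eps) - second(k - eps)))
            assert jump <= slope_bound


class TestSplineCurves:
    def test_m0_hazard_link_is_unit_exponential(self):
        m = make_spline_model([0.0, 1.0], [0.0, 1.0], "hazard")
        t = np.linspace(0.1, 5, 30)
        np.testing.assert_allclose(spline_survival(m, {}, t), np.exp(-t), rtol=1e-12)
        np.testing.assert_allclose(spline_hazard(m, {}, t), 1.0, rtol=1e-10)

    def test_m0_odds_link_is_standard_loglogistic(self):
        m = make_spline_model([0.0, 1.0], [0.0, 1.0], "odds")
        t = np.linspace(0.1, 5, 30)
        np.testing.assert_allclose(spline_survival(m, {}, t), 1 / (1 + t), rtol=1e-12)
        assert spline_survival(m, {}, 1.0) == pytest.approx(0.5)
        # h(t) = f/S = 1/(1+t)
        np.testing.assert_allclose(spline_hazard(m, {}, t), 1 / (1 + t), rtol=1e-10)

    def test_survival_is_one_at_zero(self):
        m = make_spline_model([0.0, 1.0], [0.3, 1.2], "normal")
        assert spline_survival(m, {}, 0.0) == 1.0

    def test_zero_covariate_shift_matches_baseline(self):
        base = make_spline_model([-1.0, 2.0], [0.1, 0.9], "hazard")
        cov = make_spline_model([-1.0, 2.0], [0.1, 0.9], "hazard", beta={"x": 0.5})
        t = np.linspace(0.2, 8, 20)
        np.testing.assert_allclose(
            spline_survival(cov, {"x": 0.0}, t), spline_survival(base, {}, t), rtol=1e-12
        )

    @pytest.mark.parametrize("link", ["hazard", "odds", "normal"])
    def test_hazard_matches_numerical_derivative(self, link):
        basis = [np.log(0.8), np.log(4.0), np.log(20.0)]
        gamma = [0.2, 1.1, 0.15]
        m = make_spline_model(basis, gamma, link, beta={"x": 0.4})
        X = {"x": 1.0}
        t = np.linspace(1.0, 18.0, 15)
        eps = 1e-5
        h_num = -(
            np.log(spline_survival(m, X, t + eps)) - np.log(spline_survival(m, X, t - eps))
        ) / (2 * eps)
        np.testing.assert_allclose(spline_hazard(m, X, t), h_num, rtol=1e-5)


class TestFitSpline:
    @pytest.mark.parametrize(
        "link,family", [("hazard", "weibull"), ("odds", "loglogistic"), ("normal", "lognormal")]
    )
    def test_m0_nesting_identity(self, weibull_binary_data, link, family):
        fs = fit_spline(weibull_binary_data, 0, link, ["x"])
        fp = fit_parametric(weibull_binary_data, family, ["x"])
        assert fs.loglik == pytest.approx(fp.loglik, abs=1e-4)
        assert fs.n_params == fp.n_params

    def test_adding_a_knot_never_worsens_loglik(self, weibull_binary_data):
        lls = [
            fit_spline(weibull_binary_data, m, "hazard", ["x"]).loglik for m in (0, 1, 2)
        ]
        assert lls[1] >= lls[0] - 1e-3
        assert lls[2] >= lls[1] - 1e-3

    def test_fitted_survival_monotone_on_grid(self, weibull_binary_data):
        fit = fit_spline(weibull_binary_data, 2, "odds", ["x"])
        assert fit.converged
        t = np.linspace(0.05, weibull_binary_data.horizon, 1000)
        s = spline_survival(fit, {"x": 1.0}, t)
        assert np.all(np.diff(s) <= 1e-12)

    def test_knots_stored_with_model(self, weibull_binary_data):
        fit = fit_spline(weibull_binary_data, 1, "normal", [])
        assert len(fit.knots) == 3
        basis = place_knots(weibull_binary_data, 1)
        np.testing.assert_allclose(fit.knots, basis.all_knots)

    def test_one_knot_odds_truth_beats_weibull(self):
        # data simulated from a 1-knot odds spline should out-rank Weibull by AIC
        basis = SplineBasis(k_min=np.log(2.0), k_max=np.log(60.0), internal=(np.log(12.0),))
        gamma = np.array([-3.2, 1.6, 0.18])
        wins = 0
        n_trials = 10
        for seed in range(n_trials):
            data = generate_ipd(
                family="spline",
                spline_spec=(basis, gamma, "odds"),
                n=2000,
                censoring=(70.0, 0.005),
                seed=seed,
            )
            f_spline = fit_spline(data, 1, "odds", [])
            f_weib = fit_parametric(data, "weibull", [])
            if f_spline.converged and f_spline.aic < f_weib.aic:
                wins += 1
        assert wins >= 0.8 * n_trials
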