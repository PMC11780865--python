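"""Maximum-likelihood fitting of covariate-adjusted parametric survival models.

The model for subject j is an accelerated failure time (AFT) model

    S(t | X_j) = S0(t * theta_j),   h(t | X_j) = theta_j * h0(t * theta_j),
    log(theta_j) = mu + sum_k beta_k * (X_jk - c_k),

with right-censored log-likelihood sum_j [ d_j log h(t_j|X_j) + log S(t_j|X_j) ].
The acceleration factor theta multiplies time, so a covariate with
coefficient log(2) halves expected survival when it increases by one unit.
Gompertz is fitted as a proportional-hazards model instead: exp(lp)
multiplies the baseline hazard exp(b t).

Continuous covariates are centered at the sample mean (``centering``); this
is likelihood-neutral (beta unchanged, mu shifted by sum beta_k c_k) and is
there purely for optimizer conditioning.  Exponential fits are delegated to
a Poisson GLM with log-exposure offset — the identical likelihood up to the
constant sum(d log t), which is removed when the log-likelihood is reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from .data_io import IPDDataset, ValidationError
from .families import Family, get_family

__all__ = [
    "FittedSurvivalModel",
    "linear_predictor",
    "aft_survival",
    "aft_hazard",
    "fit_parametric",
]

GRAD_TOL = 1e-3  # sup-norm of the finite-difference gradient at the optimum


def _grad_ok(gnorm: float, fun: float) -> bool:
    """Convergence by gradient sup-norm, scaled to the likelihood magnitude
    (a gradient of 1e-3 on a log-likelihood of 5000 is numerical noise)."""
    return gnorm < max(GRAD_TOL, 1e-5 * abs(fun))
_AFT_FAMILIES = ("exponential", "weibull", "gamma", "loglogistic", "lognormal", "genf")


@dataclass(frozen=True)
class FittedSurvivalModel:
    """A fitted survival model: family/link, coefficients, fit diagnostics.

    For spline models ``knots`` holds (k_min, internal..., k_max) on the
    log-time axis and ``spline_coefs`` the full gamma vector (gamma_0 is
    duplicated in ``mu`` so the linear predictor contract is uniform); for
    parametric families both are empty and ``ancillary`` carries the shape
    parameters.
    """

    family: str
    link: str = "n/a"  # hazard / odds / normal for splines
    knots: tuple[float, ...] = ()
    mu: float = 0.0
    spline_coefs: tuple[float, ...] = ()
    covariate_coefs: Mapping[str, float] = field(default_factory=dict)
    ancillary: Mapping[str, float] = field(default_factory=dict)
    loglik: float = np.nan
    n_params: int = 0
    vcov: np.ndarray | None = None
    converged: bool = False
    centering: Mapping[str, float] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def is_spline(self) -> bool:
        return self.family == "spline"

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariate_coefs)

    def covariate_se(self, name: str) -> float:
        """Wald standard error of one covariate coefficient (diagnostic only;
        interval estimation for estimands is by bootstrap)."""
        if self.vcov is None:
            raise ValidationError("no covariance matrix available (fit not converged?)")
        names = list(self.covariate_coefs)
        if name not in names:
            raise ValidationError(f"no coefficient for covariate '{name}'")
        if self.is_spline:
            offset = len(self.spline_coefs)
        else:
            from .families import get_family

            offset = 1 + get_family(self.family).n_ancillary
        j = offset + names.index(name)
        return float(np.sqrt(self.vcov[j, j]))

    # -- evaluation helpers (dispatch to the right curve machinery) --------
    def survival(self, X: Mapping[str, float], t) -> np.ndarray:
        if self.is_spline:
            from .splines import spline_survival

            return spline_survival(self, X, t)
        return aft_survival(self, X, t)

    def hazard(self, X: Mapping[str, float], t) -> np.ndarray:
        if self.is_spline:
            from .splines import spline_hazard

            return spline_hazard(self, X, t)
        return aft_hazard(self, X, t)

    def to_json(self) -> str:
        payload = {
            "family": self.family,
            "link": self.link,
            "knots": list(self.knots),
            "mu": self.mu,
            "spline_coefs": list(self.spline_coefs),
            "covariate_coefs": dict(self.covariate_coefs),
            "ancillary": dict(self.ancillary),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "centering": dict(self.centering),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FittedSurvivalModel":
        d = json.loads(text)
        return cls(
            family=d["family"],
            link=d["link"],
            knots=tuple(d["knots"]),
            mu=d["mu"],
            spline_coefs=tuple(d["spline_coefs"]),
            covariate_coefs=d["covariate_coefs"],
            ancillary=d["ancillary"],
            loglik=d["loglik"],
            n_params=d["n_params"],
            converged=d["converged"],
            centering=d["centering"],
        )


# ---------------------------------------------------------------------------
# evaluation


def linear_predictor(model: FittedSurvivalModel, X: Mapping[str, float]) -> float:
    """mu + sum_k beta_k (X_k - c_k): log theta for AFT families, the log
    hazard multiplier for Gompertz, and the covariate shift on gamma_0 for
    splines."""
    lp = model.mu
    for name, beta in model.covariate_coefs.items():
        if name not in X:
            raise ValidationError(f"covariate '{name}' missing from X")
        lp += beta * (float(X[name]) - model.centering.get(name, 0.0))
    return float(lp)


def _lp_centered(model: FittedSurvivalModel, X: Mapping[str, float]) -> float:
    """Covariate part only: sum_k beta_k (X_k - c_k)."""
    return linear_predictor(model, X) - model.mu


def aft_survival(model: FittedSurvivalModel, X: Mapping[str, float], t) -> np.ndarray:
    """S0(t * theta) for AFT families; Gompertz PH survival for gompertz."""
    t = np.asarray(t, dtype=float)
    if model.is_spline:
        raise ValidationError("spline model routed to aft_survival; use spline_survival")
    fam = get_family(model.family)
    anc = _anc_vector(fam, model.ancillary)
    lp = linear_predictor(model, X)
    if model.family == "gompertz":
        out = np.exp(-np.exp(lp) * fam.cum_hazard0(t, anc))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(t > 0, np.exp(fam.log_s0(np.maximum(t, 1e-300) * np.exp(lp), anc)), 1.0)
    return out if out.ndim else float(out)


def aft_hazard(model: FittedSurvivalModel, X: Mapping[str, float], t) -> np.ndarray:
    """theta * h0(t * theta) (AFT) or exp(lp) * h0(t) (Gompertz)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValidationError("hazard requires t > 0")
    fam = get_family(model.family)
    anc = _anc_vector(fam, model.ancillary)
    lp = linear_predictor(model, X)
    if model.family == "gompertz":
        out = np.exp(lp + fam.log_h0(t, anc))
    else:
        theta = np.exp(lp)
        out = theta * np.exp(fam.log_h0(t * theta, anc))
    return out if out.ndim else float(out)


def predict_median(model: FittedSurvivalModel, X: Mapping[str, float]) -> float:
    """Median survival time under the fitted model at covariates X."""
    fam = get_family(model.family)
    anc = _anc_vector(fam, model.ancillary)
    lp = linear_predictor(model, X)
    if model.family == "gompertz":
        u = fam.s0_inverse(np.array(0.5) ** np.exp(-lp), anc)  # exp(-e^lp H0)=1/2
        return float(u)
    return float(fam.s0_inverse(np.asarray(0.5), anc) / np.exp(lp))


def _anc_vector(fam: Family, ancillary: Mapping[str, float]) -> np.ndarray:
    return np.array([float(ancillary[n]) for n in fam.ancillary_names])


# ---------------------------------------------------------------------------
# fitting


def _center(data: IPDDataset, covariates: Sequence[str]) -> tuple[np.ndarray, dict]:
    """Center continuous covariates at the sample mean; binary stay raw."""
    X = data.covariate_matrix(covariates)
    centering = {}
    for j, name in enumerate(covariates):
        col = X[:, j]
        is_binary = np.isin(col, [0.0, 1.0]).all()
        c = 0.0 if is_binary else float(col.mean())
        centering[name] = c
        X[:, j] = col - c
    return X, centering


def _negloglik_aft(params, fam: Family, t, d, Xc, ev):
    k = fam.n_ancillary
    mu = params[0]
    anc = fam.untransform(np.asarray(params[1 : 1 + k]))
    if not fam.valid(anc):
        return 1e12
    beta = np.asarray(params[1 + k :])
    lp = np.full(t.shape, mu)
    if beta.size:
        lp = lp + Xc @ beta
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        if fam.name == "gompertz":
            elp = np.exp(lp)
            ll = np.sum(lp[ev] + fam.log_h0(t[ev], anc)) - np.sum(
                elp * fam.cum_hazard0(t, anc)
            )
        else:
            # events contribute log f, censored observations log S
            u = t * np.exp(lp)
            ll = np.sum(lp[ev] + fam.log_f0(u[ev], anc)) + np.sum(
                fam.log_s0(u[~ev], anc)
            )
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _fit_exponential_glm(t, d, Xc):
    """Exponential AFT by Newton-Raphson on its concave log-likelihood.

    ll = sum d*lp - t*exp(lp) is a Poisson log-linear model with exposure t,
    so the score is X'(d - t e^lp) and the information X' diag(t e^lp) X;
    a handful of damped Newton steps from the events/exposure start solves
    it to machine precision, deterministically.
    """
    design = np.ones((t.size, 1))
    if Xc.size:
        design = np.column_stack([design, Xc])
    params = np.zeros(design.shape[1])
    params[0] = np.log(d.sum() / t.sum())
    ok = False
    for _ in range(50):
        lp = design @ params
        w = t * np.exp(lp)
        score = design.T @ (d - w)
        info = design.T @ (design * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # damp: halve until the likelihood does not decrease
        ll_old = float(d @ lp - w.sum())
        scale = 1.0
        for _half in range(30):
            new = params + scale * step
            lp_n = design @ new
            ll_new = float(d @ lp_n - np.sum(t * np.exp(lp_n)))
            if ll_new >= ll_old - 1e-12:
                break
            scale *= 0.5
        params = params + scale * step
        if np.max(np.abs(score)) < 1e-9:
            ok = True
            break
    lp = design @ params
    w = t * np.exp(lp)
    ll = float(d @ lp - w.sum())
    info = design.T @ (design * w[:, None])
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = None
        ok = False
    return params, ll, vcov, ok


def _optimize_ll(negloglik, start, args):
    """BFGS with a Nelder-Mead polish fallback; returns (fun, x, ok, gnorm)."""
    res = optimize.minimize(
        negloglik, start, args=args, method="BFGS",
        options={"gtol": 1e-6, "maxiter": 300},
    )
    grad = approx_fprime(res.x, negloglik, args=args, centered=True)
    gnorm = float(np.max(np.abs(grad)))
    ok = np.isfinite(res.fun) and res.fun < 1e11 and (_grad_ok(gnorm, res.fun) or res.success)
    if not ok and np.isfinite(res.fun):
        # flat curvature (e.g. generalized F) trips BFGS line searches;
        # a simplex polish followed by one more BFGS usually lands it
        pol = optimize.minimize(
            negloglik, res.x, args=args, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 1500},
        )
        res2 = optimize.minimize(
            negloglik, pol.x, args=args, method="BFGS",
            options={"gtol": 1e-6, "maxiter": 300},
        )
        if res2.fun <= res.fun:
            grad = approx_fprime(res2.x, negloglik, args=args, centered=True)
            gnorm = float(np.max(np.abs(grad)))
            ok = np.isfinite(res2.fun) and res2.fun < 1e11 and (_grad_ok(gnorm, res2.fun) or res2.success)
            res = res2
    return float(res.fun), res.x, bool(ok), gnorm


def fit_parametric(
    data: IPDDataset,
    family: str,
    covariates: Sequence[str] = (),
    max_restarts: int = 5,
) -> FittedSurvivalModel:
    """Fit one covariate-adjusted parametric survival model by ML.

    Optimization is quasi-Newton (BFGS) on transformed parameters, started
    from method-of-moments values, with up to ``max_restarts`` deterministic
    jittered restarts; an optimizer failure after all restarts returns the
    best point found with ``converged=False`` (the model-selection stage
    excludes such fits).  Refitting the same data is bit-identical.
    """
    fam = get_family(family)
    covariates = list(covariates)
    if data.n_events < 1:
        raise ValidationError("cannot fit a survival model with zero events")
    t = data.time
    d = data.event.astype(float)
    Xc, centering = _center(data, covariates)
    log_t_unc = np.log(t[d == 1])

    if family == "exponential":
        params, ll, vcov, ok = _fit_exponential_glm(t, d, Xc)
        mu = float(params[0])
        beta = params[1:]
        n_params = 1 + len(covariates)
        return FittedSurvivalModel(
            family=family,
            mu=mu,
            covariate_coefs=dict(zip(covariates, beta.tolist())),
            ancillary={},
            loglik=ll,
            n_params=n_params,
            vcov=vcov,
            converged=ok,
            centering=centering,
        )

    anc0 = fam.init_ancillary(log_t_unc)
    x0 = np.concatenate(
        [[fam.init_mu(log_t_unc)], fam.transform(anc0) if anc0.size else anc0, np.zeros(len(covariates))]
    )
    args = (fam, t, d, Xc, d == 1)
    rng = np.random.default_rng(202401)  # deterministic restart jitter

    best = None
    for attempt in range(max_restarts):
        start = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.3, size=x0.size)
        fun, x, ok, gnorm = _optimize_ll(_negloglik_aft, start, args)
        cand = (fun, x, ok, gnorm)
        stuck = best is not None and abs(fun - best[0]) < 1e-6
        if best is None or cand[0] < best[0]:
            best = cand
        if ok and fun <= best[0] + 1e-9:
            best = cand
            break
        if stuck and attempt >= 1:
            break  # restarts keep landing on the same flat optimum

    fun, x, ok, _ = best
    k = fam.n_ancillary
    mu = float(x[0])
    anc = fam.untransform(x[1 : 1 + k]) if k else np.empty(0)
    beta = x[1 + k :]
    n_params = 1 + k + len(covariates)
    vcov = None
    if ok:
        try:
            H = approx_hess(x, _negloglik_aft, args=args)
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = None
    return FittedSurvivalModel(
        family=family,
        mu=mu,
        covariate_coefs=dict(zip(covariates, np.asarray(beta).tolist())),
        ancillary=dict(zip(fam.ancillary_names, np.asarray(anc).tolist())),
        loglik=-float(fun),
        n_params=n_params,
        vcov=vcov,
        converged=bool(ok),
        centering=centering,
    )
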