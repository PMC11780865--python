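"""Baseline survival distributions for the AFT / proportional-hazards engine.

Every accelerated-failure-time family is expressed with a *unit-scale*
baseline: S(t | X) = S0(t * theta) with theta = exp(mu + X.beta).  The
intercept mu absorbs the family's scale/rate parameter (theta multiplies
time, so exp(mu) is the reciprocal time scale), and the ``ancillary``
parameters carry shape only.  This removes the usual intercept/scale
aliasing and keeps the linear predictor exactly the log time-acceleration
factor: adding log(2) to it halves every survival quantile.

Gompertz is the one proportional-hazards family: h(t | X) = exp(lp) *
exp(b t), i.e. the linear predictor is a log hazard multiplier, not a log
time ratio.

Ancillary parameters are optimized on transformed (unconstrained) scales:
log for positive shapes, identity for sign-free ones.

Generalized F uses the stabilized (sigma, Q, P) parameterisation: with
delta = sqrt(Q^2 + 2P), s1 = 2/(Q^2 + 2P + Q*delta), s2 = 2/(Q^2 + 2P -
Q*delta) and w = delta * log(u) / sigma, the baseline survival is the
F(2*s1, 2*s2) survival function evaluated at e^w.  Its limits (Q=0, P=1:
log-logistic; Q=0, P->0: log-normal) are exercised in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = ["FAMILIES", "get_family", "Family"]

_EPS = 1e-300


def _logsf_f(x: np.ndarray, d1: float, d2: float) -> np.ndarray:
    """log survival of the F(d1, d2) distribution, via the beta function."""
    # sf_F(x) = I_{d2/(d2 + d1 x)}(d2/2, d1/2)
    z = d2 / (d2 + d1 * x)
    return np.log(np.maximum(special.betainc(d2 / 2.0, d1 / 2.0, z), _EPS))


class Family:
    """One baseline distribution: log-survival, log-hazard, inverse survival.

    Subclasses work on the *accelerated* time u = t * theta and a vector of
    ancillary parameters on their natural scale.
    """

    name: str = ""
    n_ancillary: int = 0
    ancillary_names: tuple[str, ...] = ()
    is_aft: bool = True

    # natural <-> transformed (unconstrained optimizer scale)
    def transform(self, anc: np.ndarray) -> np.ndarray:
        return np.log(anc)

    def untransform(self, x: np.ndarray) -> np.ndarray:
        return np.exp(x)

    def log_s0(self, u: np.ndarray, anc: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def log_h0(self, u: np.ndarray, anc: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def log_f0(self, u: np.ndarray, anc: np.ndarray) -> np.ndarray:
        """Log baseline density; overridden where a direct form is cheaper."""
        return self.log_h0(u, anc) + self.log_s0(u, anc)

    def valid(self, anc: np.ndarray) -> bool:
        """Reject absurd shape regions before evaluating the likelihood."""
        return bool(np.all(np.isfinite(anc)))

    def s0_inverse(self, p: np.ndarray, anc: np.ndarray) -> np.ndarray:
        """u such that S0(u) = p; used by the synthetic-data generator."""
        raise NotImplementedError

    def init_ancillary(self, log_times: np.ndarray) -> np.ndarray:
        """Method-of-moments starting values from uncensored log times."""
        raise NotImplementedError

    def init_mu(self, log_times: np.ndarray) -> float:
        # theta ~ 1/median(t) puts the baseline median near the data median
        return -float(np.median(log_times))


class Exponential(Family):
    name = "exponential"
    n_ancillary = 0

    def log_s0(self, u, anc):
        return -u

    def log_h0(self, u, anc):
        return np.zeros_like(u)

    def s0_inverse(self, p, anc):
        return -np.log(p)

    def init_ancillary(self, log_times):
        return np.empty(0)


class Weibull(Family):
    name = "weibull"
    n_ancillary = 1
    ancillary_names = ("shape",)

    def log_s0(self, u, anc):
        a = anc[0]
        return -(u ** a)

    def log_h0(self, u, anc):
        a = anc[0]
        return np.log(a) + (a - 1.0) * np.log(u)

    def s0_inverse(self, p, anc):
        a = anc[0]
        return (-np.log(p)) ** (1.0 / a)

    def init_ancillary(self, log_times):
        s = max(float(np.std(log_times)), 0.05)
        return np.array([min(np.pi / (np.sqrt(6.0) * s), 20.0)])


class Gamma(Family):
    """Gamma AFT: unit-rate baseline, shape free; acceleration acts on time."""

    name = "gamma"
    n_ancillary = 1
    ancillary_names = ("shape",)

    def log_s0(self, u, anc):
        a = anc[0]
        return np.log(np.maximum(special.gammaincc(a, u), _EPS))

    def log_f0(self, u, anc):
        a = anc[0]
        return (a - 1.0) * np.log(u) - u - special.gammaln(a)

    def log_h0(self, u, anc):
        return self.log_f0(u, anc) - self.log_s0(u, anc)

    def s0_inverse(self, p, anc):
        a = anc[0]
        return special.gammainccinv(a, p)

    def init_ancillary(self, log_times):
        return np.array([1.0])


class LogLogistic(Family):
    name = "loglogistic"
    n_ancillary = 1
    ancillary_names = ("shape",)

    def log_s0(self, u, anc):
        a = anc[0]
        return -np.log1p(u ** a)

    def log_h0(self, u, anc):
        a = anc[0]
        return np.log(a) + (a - 1.0) * np.log(u) - np.log1p(u ** a)

    def s0_inverse(self, p, anc):
        a = anc[0]
        return (1.0 / p - 1.0) ** (1.0 / a)

    def init_ancillary(self, log_times):
        s = max(float(np.std(log_times)), 0.05)
        return np.array([min(np.pi / (np.sqrt(3.0) * s), 20.0)])


class LogNormal(Family):
    name = "lognormal"
    n_ancillary = 1
    ancillary_names = ("sigma",)

    def log_s0(self, u, anc):
        sigma = anc[0]
        return stats.norm.logsf(np.log(u) / sigma)

    def log_h0(self, u, anc):
        sigma = anc[0]
        z = np.log(u) / sigma
        return stats.norm.logpdf(z) - np.log(sigma * u) - stats.norm.logsf(z)

    def s0_inverse(self, p, anc):
        sigma = anc[0]
        return np.exp(sigma * stats.norm.isf(p))

    def init_ancillary(self, log_times):
        return np.array([max(float(np.std(log_times)), 0.05)])


class GenF(Family):
    """Generalized F in the stabilized (sigma, Q, P) parameterisation."""

    name = "genf"
    n_ancillary = 3
    ancillary_names = ("sigma", "Q", "P")

    def transform(self, anc):
        return np.array([np.log(anc[0]), anc[1], np.log(anc[2])])

    def untransform(self, x):
        return np.array([np.exp(x[0]), x[1], np.exp(x[2])])

    @staticmethod
    def _shape(anc):
        sigma, Q, P = anc
        delta = np.sqrt(Q * Q + 2.0 * P)
        s1 = 2.0 / (Q * Q + 2.0 * P + Q * delta)
        s2 = 2.0 / (Q * Q + 2.0 * P - Q * delta)
        return sigma, delta, s1, s2

    def log_s0(self, u, anc):
        sigma, delta, s1, s2 = self._shape(anc)
        ew = np.exp(delta * np.log(u) / sigma)
        return _logsf_f(ew, 2.0 * s1, 2.0 * s2)

    def log_f0(self, u, anc):
        sigma, delta, s1, s2 = self._shape(anc)
        w = delta * np.log(u) / sigma
        return (
            np.log(delta)
            + s1 * (np.log(s1) - np.log(s2))
            + s1 * w
            - np.log(sigma)
            - np.log(u)
            - (s1 + s2) * np.log1p(s1 * np.exp(w) / s2)
            - special.betaln(s1, s2)
        )

    def log_h0(self, u, anc):
        return self.log_f0(u, anc) - self.log_s0(u, anc)

    def valid(self, anc):
        if not np.all(np.isfinite(anc)):
            return False
        _, _, s1, s2 = self._shape(anc)
        # the incomplete beta becomes pathologically slow (and the model
        # indistinguishable from its limits) once either df explodes
        return bool(np.isfinite(s1) and np.isfinite(s2) and max(s1, s2) < 1e4)

    def s0_inverse(self, p, anc):
        sigma, delta, s1, s2 = self._shape(anc)
        y = stats.f.isf(p, 2.0 * s1, 2.0 * s2)
        return np.exp(sigma * np.log(y) / delta)

    def init_ancillary(self, log_times):
        s = max(float(np.std(log_times)), 0.05)
        # start at the log-logistic corner (Q=0, P=1): sigma = sqrt(2)/shape
        return np.array([s * np.sqrt(3.0) / np.pi * np.sqrt(2.0), 0.0, 1.0])


class Gompertz(Family):
    """Gompertz proportional hazards: h(t|X) = exp(lp) * exp(b t), b free."""

    name = "gompertz"
    n_ancillary = 1
    ancillary_names = ("shape",)
    is_aft = False

    def transform(self, anc):
        return np.asarray(anc, dtype=float)

    def untransform(self, x):
        return np.asarray(x, dtype=float)

    def cum_hazard0(self, t, anc):
        b = anc[0]
        t = np.asarray(t, dtype=float)
        if abs(b) < 1e-12:
            return t
        return np.expm1(b * t) / b

    def log_h0(self, t, anc):
        b = anc[0]
        return b * np.asarray(t, dtype=float)

    def log_s0(self, t, anc):
        # baseline (lp = 0) survival; the PH engine scales the cumulative hazard
        return -self.cum_hazard0(t, anc)

    def s0_inverse(self, p, anc):
        """t with exp(-H0(t)) = p; may be +inf for b < 0 (defective)."""
        b = anc[0]
        y = -np.log(p)
        if abs(b) < 1e-12:
            return y
        arg = 1.0 + b * y
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(arg > 0, np.log(np.maximum(arg, _EPS)) / b, np.inf)
        return out

    def init_ancillary(self, log_times):
        return np.array([0.01])


FAMILIES: dict[str, Family] = {
    f.name: f
    for f in (
        Exponential(),
        Weibull(),
        Gamma(),
        LogLogistic(),
        LogNormal(),
        GenF(),
        Gompertz(),
    )
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None
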