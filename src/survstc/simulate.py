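"""Synthetic two-population survival data for exercising every STC stage.

The generator emulates the structure of a first-line renal-cell-carcinoma
comparison: one index arm with subject-level data (binary risk/lesion
covariates plus continuous age, covariate-driven event times, mixed
administrative and random censoring), and "published" comparator arms
rendered the way a paper would report them — digitized KM coordinates, a
numbers-at-risk table every few months, a total event count, and an
aggregate baseline row of proportions and a median age.  Because the truth
behind each rendering is known, reconstruction error and estimand bias are
measurable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import AggregateBaseline, DigitizedCurve, IPDDataset, RiskTable, ValidationError
from .families import get_family
from .km import km_estimate
from .splines import SplineBasis, _spline_eval

__all__ = [
    "generate_ipd",
    "render_comparator",
    "make_paper_like_scenario",
    "ComparatorBundle",
    "Scenario",
]


def _draw_covariates(
    covariate_model: Mapping[str, tuple], n: int, rng: np.random.Generator
) -> pd.DataFrame:
    cols = {}
    for name, spec in covariate_model.items():
        kind = spec[0]
        if kind == "bernoulli":
            cols[name] = rng.binomial(1, spec[1], size=n).astype(float)
        elif kind == "normal":
            cols[name] = rng.normal(spec[1], spec[2], size=n)
        else:
            raise ValidationError(f"unknown covariate model {kind!r} for '{name}'")
    return pd.DataFrame(cols, index=range(n))


def _spline_event_times(
    basis: SplineBasis, gamma: np.ndarray, link: str, lp: np.ndarray, U: np.ndarray
) -> np.ndarray:
    """Invert g(S) = s(log t) + lpc at S = U by bisection in log time."""
    from scipy import optimize, stats

    if link == "hazard":
        target = np.log(-np.log(U))
    elif link == "odds":
        target = np.log(1.0 / U - 1.0)
    elif link == "normal":
        target = -stats.norm.ppf(U)
    else:
        raise ValidationError(f"unknown link {link!r}")
    target = target - lp
    s_lo, ds_lo = _spline_eval(basis, gamma, np.asarray(basis.k_min))
    s_hi, ds_hi = _spline_eval(basis, gamma, np.asarray(basis.k_max))
    if ds_lo <= 0 or ds_hi <= 0:
        raise ValidationError("spline_spec must be increasing in log time")
    out = np.empty(U.size)
    for i, y in enumerate(target):
        if y <= s_lo:
            # linear tail below the first knot: invert in closed form
            out[i] = basis.k_min + (y - s_lo) / ds_lo
        elif y >= s_hi:
            out[i] = basis.k_max + (y - s_hi) / ds_hi
        else:
            def f(u):
                s, _ = _spline_eval(basis, gamma, np.asarray(u))
                return float(s) - y
            out[i] = optimize.brentq(f, basis.k_min, basis.k_max, xtol=1e-10)
    with np.errstate(over="ignore"):
        return np.exp(out)


def generate_ipd(
    family: str = "weibull",
    params: Mapping[str, float] | None = None,
    beta: Mapping[str, float] | None = None,
    covariate_model: Mapping[str, tuple] | None = None,
    n: int = 300,
    censoring: tuple[float, float] = (np.inf, 0.0),
    seed: int = 0,
    arm_label: str = "index",
    spline_spec: tuple | None = None,
) -> IPDDataset:
    """Draw subject-level data from a known covariate-adjusted model.

    Event times come from inverse-transform sampling of S0(t * theta_i)
    with theta_i = exp(mu + X_i . beta) (for Gompertz, exp(lp) scales the
    hazard instead).  Observed time is the minimum of the event time, the
    administrative horizon ``censoring[0]`` and an exponential random
    censor with rate ``censoring[1]``; the event flag records which won.

    For spline truth pass ``family="spline"`` and ``spline_spec = (basis,
    gamma, link)``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    params = dict(params or {})
    beta = dict(beta or {})
    covariate_model = dict(covariate_model or {})
    rng = np.random.default_rng(seed)
    X = _draw_covariates(covariate_model, n, rng)
    for name in beta:
        if name not in X.columns:
            raise ValidationError(f"beta refers to unknown covariate '{name}'")
    mu = float(params.get("mu", 0.0))
    lp = mu + sum(beta[c] * X[c].to_numpy() for c in beta) if beta else np.full(n, mu)
    lp = np.asarray(lp, dtype=float)
    U = rng.uniform(size=n)

    if family == "spline":
        if spline_spec is None:
            raise ValidationError("spline generation needs spline_spec=(basis, gamma, link)")
        basis, gamma, link = spline_spec
        event_t = _spline_event_times(basis, np.asarray(gamma, float), link, lp, U)
    else:
        fam = get_family(family)
        anc = np.array([float(params[k]) for k in fam.ancillary_names])
        if family == "gompertz":
            # S(t) = exp(-e^lp H0(t)) = U  =>  H0(t) = -log U / e^lp
            event_t = np.array(
                [fam.s0_inverse(np.asarray(u) ** np.exp(-l), anc) for u, l in zip(U, lp)],
                dtype=float,
            )
        else:
            event_t = fam.s0_inverse(U, anc) / np.exp(lp)

    admin, rate = censoring
    censor_t = np.full(n, float(admin))
    if rate > 0:
        censor_t = np.minimum(censor_t, rng.exponential(1.0 / rate, size=n))
    obs = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    obs = np.maximum(obs, 1e-8)
    if not np.all(np.isfinite(obs)):
        # defective distributions (Gompertz b<0) need a finite admin horizon
        raise ValidationError("infinite observed time; set an administrative censoring horizon")
    return IPDDataset(time=obs, event=event, covariates=X, arm_label=arm_label)


def render_comparator(
    data: IPDDataset,
    curve_points: int = 120,
    risk_interval: float = 6.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[DigitizedCurve, RiskTable, AggregateBaseline]:
    """Render an arm the way a publication reports it.

    The KM curve is sampled at ``curve_points`` evenly spaced times
    (optional uniform digitization jitter bounded by 0.005, then
    re-monotonized), numbers at risk are tabulated at multiples of
    ``risk_interval``, and covariates are summarized into an aggregate
    baseline (proportion for 0/1 columns, median otherwise) with the arm's
    horizon as follow-up.
    """
    if curve_points < 10:
        raise ValidationError("need at least 10 digitized points")
    if jitter > 0.005:
        raise ValidationError("digitization jitter is bounded at 0.005")
    km = km_estimate(data)
    horizon = data.horizon
    # a digitizer clicks at visible step corners, so points concentrate
    # where the curve drops: pick the event times closest to equally
    # spaced survival levels (plus 0 and the horizon)
    s_min = float(km.survival.min())
    levels = np.linspace(1.0, s_min, curve_points)
    idx = np.unique(np.searchsorted(-km.survival, -levels, side="left").clip(0, km.times.size - 1))
    t_grid = np.unique(np.concatenate([[0.0], km.times[idx], [horizon]]))
    s_grid = km.at(t_grid)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        s_grid = s_grid + rng.uniform(-jitter, jitter, size=s_grid.size)
        s_grid[0] = 1.0
    curve = DigitizedCurve.from_points(t_grid, s_grid)

    risk_times = np.arange(0.0, horizon + 1e-9, risk_interval)
    n_at_risk = np.array([(data.time >= s).sum() for s in risk_times])
    risk = RiskTable(
        interval_times=risk_times,
        n_at_risk=n_at_risk,
        total_events=int(data.event.sum()),
    )

    values = {}
    binaries = []
    for name in data.covariate_names:
        col = data.covariates[name].to_numpy(dtype=float)
        if np.isin(col, [0.0, 1.0]).all():
            values[name] = float(col.mean())
            binaries.append(name)
        else:
            values[name] = float(np.median(col))
    baseline = AggregateBaseline(
        values=values,
        trial_label=data.arm_label,
        follow_up=float(horizon),
        binary_covariates=tuple(binaries),
    )
    return curve, risk, baseline


# ---------------------------------------------------------------------------
# full scenario


@dataclass(frozen=True)
class ComparatorBundle:
    """Everything a published comparator trial supplies, plus hidden truth."""

    label: str
    curve: DigitizedCurve
    risk: RiskTable
    baseline: AggregateBaseline
    truth_ipd: IPDDataset  # hidden: for oracle checks only


@dataclass(frozen=True)
class Scenario:
    index: IPDDataset
    comparators: tuple[ComparatorBundle, ...]
    true_beta: Mapping[str, float]
    true_params: Mapping[str, float]
    family: str


#: index-arm covariate distribution of the emulated trial population
_COVARIATE_MODEL = {
    "AGE": ("normal", 62.0, 10.0),
    "FEMALE": ("bernoulli", 0.28),
    "IMDC_FAVOURABLE": ("bernoulli", 0.31),
    "MSKCC_FAVOURABLE": ("bernoulli", 0.29),
    "PDL1_LT1": ("bernoulli", 0.315),
    "METS_GE2": ("bernoulli", 0.715),
    "BONE_LESIONS": ("bernoulli", 0.22),
    "LYMPH_LESIONS": ("bernoulli", 0.45),
    "LIVER_LESIONS": ("bernoulli", 0.18),
    "LUNG_LESIONS": ("bernoulli", 0.71),
}

#: prognostic truth: favourable risk protective, tumour burden harmful,
#: age mildly harmful; remaining covariates pure noise
_TRUE_BETA = {
    "AGE": 0.01,
    "IMDC_FAVOURABLE": -0.45,
    "MSKCC_FAVOURABLE": -0.2,
    "METS_GE2": 0.3,
    "LIVER_LESIONS": 0.25,
}

_TRUE_PARAMS = {"mu": -4.35, "shape": 1.2}

#: which covariates each emulated comparator publication reports, echoing
#: how reporting subsets differ across real trials
_COMPARATOR_REPORTING = {
    "trial_A": [
        "AGE", "FEMALE", "IMDC_FAVOURABLE", "PDL1_LT1", "METS_GE2",
        "BONE_LESIONS", "LYMPH_LESIONS", "LIVER_LESIONS", "LUNG_LESIONS",
    ],
    "trial_J": ["AGE", "FEMALE", "IMDC_FAVOURABLE", "MSKCC_FAVOURABLE", "METS_GE2"],
    "trial_K": [
        "AGE", "FEMALE", "IMDC_FAVOURABLE", "PDL1_LT1", "METS_GE2",
        "BONE_LESIONS", "LYMPH_LESIONS", "LIVER_LESIONS", "LUNG_LESIONS",
    ],
    "trial_C": ["AGE", "FEMALE", "IMDC_FAVOURABLE", "MSKCC_FAVOURABLE", "PDL1_LT1", "METS_GE2"],
}

_COMPARATOR_FOLLOW_UP = {"trial_A": 74.0, "trial_J": 46.0, "trial_K": 73.0, "trial_C": 53.0}

#: log time-acceleration disadvantage of each comparator treatment
_COMPARATOR_EFFECT = {"trial_A": 0.20, "trial_J": 0.25, "trial_K": 0.18, "trial_C": 0.35}


def make_paper_like_scenario(
    seed: int = 0,
    n_index: int = 350,
    n_comparator: int = 400,
    null: bool = False,
) -> Scenario:
    """One index arm plus four rendered comparator bundles.

    Weibull AFT truth with the covariate vocabulary above; each comparator
    population has mildly shifted covariate mixes, its own follow-up
    horizon and (unless ``null``) a survival disadvantage, and reports only
    a subset of covariates — so covariate alignment and per-comparator
    refitting are exercised downstream.
    """
    rng = np.random.default_rng(seed)
    index = generate_ipd(
        family="weibull",
        params=_TRUE_PARAMS,
        beta=_TRUE_BETA,
        covariate_model=_COVARIATE_MODEL,
        n=n_index,
        censoring=(66.0, 0.004),
        seed=int(rng.integers(2**31)),
        arm_label="index",
    )
    bundles = []
    for label, reported in _COMPARATOR_REPORTING.items():
        shift = rng.uniform(-0.05, 0.05)
        cov_model = {}
        for name, spec in _COVARIATE_MODEL.items():
            if spec[0] == "bernoulli":
                cov_model[name] = ("bernoulli", float(np.clip(spec[1] + shift, 0.02, 0.98)))
            else:
                cov_model[name] = (spec[0], spec[1] + 40.0 * shift, spec[2])
        effect = 0.0 if null else _COMPARATOR_EFFECT[label]
        comp = generate_ipd(
            family="weibull",
            params={**_TRUE_PARAMS, "mu": _TRUE_PARAMS["mu"] + effect},
            beta=_TRUE_BETA,
            covariate_model=cov_model,
            n=n_comparator,
            censoring=(_COMPARATOR_FOLLOW_UP[label], 0.004),
            seed=int(rng.integers(2**31)),
            arm_label=label,
        )
        curve, risk, baseline_full = render_comparator(
            comp, curve_points=120, risk_interval=6.0
        )
        baseline = AggregateBaseline(
            values={k: baseline_full.values[k] for k in reported},
            trial_label=label,
            follow_up=baseline_full.follow_up,
            binary_covariates=tuple(
                k for k in baseline_full.binary_covariates if k in reported
            ),
        )
        bundles.append(
            ComparatorBundle(
                label=label, curve=curve, risk=risk, baseline=baseline, truth_ipd=comp
            )
        )
    return Scenario(
        index=index,
        comparators=tuple(bundles),
        true_beta=dict(_TRUE_BETA),
        true_params=dict(_TRUE_PARAMS),
        family="weibull",
    )
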