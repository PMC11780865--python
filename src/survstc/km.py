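"""Kaplan-Meier estimation, RMST, Guyot pseudo-IPD reconstruction, and
kernel-smoothed hazards from KM data.

The comparator side of an unanchored STC never has subject-level data:
only a published KM figure (digitized into coordinates), a numbers-at-risk
table, and sometimes a total event count.  This module turns those back
into pseudo-IPD (Guyot's iterative algorithm), summarizes survival
nonparametrically, and estimates a smooth hazard for landmark hazard
ratios.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .data_io import DigitizedCurve, IPDDataset, RiskTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "StepSurvival",
    "KernelHazard",
    "km_estimate",
    "km_rmst",
    "guyot_reconstruct",
    "kernel_hazard",
]


@dataclass(frozen=True)
class StepSurvival:
    """Right-continuous product-limit survival step function.

    ``times`` are the distinct event times; ``survival`` the estimate just
    after each; ``n_risk``/``n_event`` the risk-set size and event count at
    each.  ``max_follow`` is the largest observed time (event or censor) —
    the curve is known only up to there.
    """

    times: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    max_follow: float
    greenwood_var: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if np.any(np.diff(s) > 1e-12) or (s.size and s[0] > 1.0 + 1e-12):
            raise ValidationError("survival must be non-increasing and start <= 1")

    def at(self, t) -> np.ndarray:
        """S(t) with the right-continuous step convention; S(t)=1 before the
        first event."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        s = np.concatenate([[1.0], self.survival])
        return s[np.clip(idx, -1, self.times.size - 1) + 1]


@dataclass(frozen=True)
class KernelHazard:
    """Kernel-smoothed hazard on a time grid."""

    grid: np.ndarray
    hazard: np.ndarray
    bandwidth: float
    kernel_name: str = "epanechnikov"

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.hazard) < 0):
            raise ValidationError("kernel hazard must be nonnegative")

    def at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.grid, self.hazard)


def km_estimate(data: IPDDataset) -> StepSurvival:
    """Product-limit estimator; ties handled events-before-censorings."""
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, data.event)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    n_risk = ev["at_risk"].to_numpy(dtype=float)
    n_event = ev["observed"].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    # Greenwood: Var(S(t)) = S(t)^2 * cumsum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = n_event / (n_risk * (n_risk - n_event))
    inc[~np.isfinite(inc)] = 0.0
    var = surv ** 2 * np.cumsum(inc)
    return StepSurvival(
        times=times,
        survival=surv,
        n_risk=n_risk,
        n_event=n_event,
        max_follow=float(data.time.max()),
        greenwood_var=var,
    )


def km_rmst(curve: StepSurvival, tau: float) -> float:
    """Area under the step survival curve from 0 to tau (months).

    Beyond the last observed time the curve is extended flat at its last
    value, with a warning — the estimand truncation rule is supposed to
    prevent this path.
    """
    if not tau > 0:
        raise ValidationError("tau must be positive")
    if tau > curve.max_follow + 1e-9:
        warnings.warn(
            f"RMST horizon {tau} exceeds last observed time {curve.max_follow}; "
            "extending the curve flat",
            stacklevel=2,
        )
    knots = np.concatenate([[0.0], curve.times, [np.inf]])
    values = np.concatenate([[1.0], curve.survival])  # value on [knots[i], knots[i+1])
    area = 0.0
    for i in range(values.size):
        left = knots[i]
        right = min(knots[i + 1], tau)
        if right <= left:
            break
        area += values[i] * (right - left)
    return float(area)


# ---------------------------------------------------------------------------
# Guyot reconstruction


def guyot_reconstruct(curve: DigitizedCurve, risk: RiskTable) -> IPDDataset:
    """Reconstruct pseudo-IPD from a digitized KM curve and risk table.

    Implements the iterative interval algorithm: within each risk-table
    interval the number of censorings is solved so that the number at risk
    implied by the digitized survival drops matches the published number at
    the start of the next interval, with censoring times spread uniformly
    within the interval.  In the final interval (no next published number)
    no within-interval censoring is assumed and subjects still at risk are
    censored at the last digitized time.  If ``risk.total_events`` is given,
    a final pass relabels the latest censor/event times so the reconstructed
    total matches it exactly.

    The output has the same CSV schema as any other subject-level dataset
    (empty covariate set), so every downstream stage applies unchanged.
    """
    t_s = curve.times
    s = curve.survival
    if risk.interval_times[0] > t_s[0] or risk.interval_times[-1] > t_s[-1] + 1e-9:
        # risk times may not extend beyond the digitized range
        raise ValidationError("risk-table intervals must span the digitized curve range")
    trisk = np.asarray(risk.interval_times, dtype=float)
    nrisk = np.asarray(risk.n_at_risk, dtype=int)
    n_int = trisk.size
    K = t_s.size

    # click index ranges per interval: [lower[i], upper[i]] inclusive
    lower = np.searchsorted(t_s, trisk, side="left")
    upper = np.empty(n_int, dtype=int)
    upper[:-1] = np.searchsorted(t_s, trisk[1:], side="left") - 1
    upper[-1] = K - 1

    n_hat = np.zeros(K + 1)
    km_hat = np.ones(K)
    n_event = np.zeros(K, dtype=int)
    cen_times_all: list[float] = []
    n_hat[lower[0]] = nrisk[0]
    last_event = 0

    for i in range(n_int):
        lo, up = lower[i], upper[i]
        if lo > up:
            if i + 1 < n_int:
                n_hat[lower[i + 1]] = n_hat[lo]
            continue
        last_interval = i == n_int - 1
        if not last_interval:
            s_lo = s[lo]
            s_next = s[lower[i + 1]] if lower[i + 1] < K else s[-1]
            guess = n_hat[lo] * (s_next / s_lo if s_lo > 0 else 0.0) - nrisk[i + 1]
            n_cen = int(round(guess))
            n_cen = max(0, min(n_cen, int(n_hat[lo])))
        else:
            n_cen = 0
        t_lo = t_s[lo]
        t_hi = t_s[lower[i + 1]] if not last_interval else t_s[-1]

        for _iteration in range(40):
            # spread censor times uniformly within the interval
            if n_cen > 0:
                cen_t = t_lo + (np.arange(1, n_cen + 1)) * (t_hi - t_lo) / (n_cen + 1)
            else:
                cen_t = np.empty(0)
            # walk the digitized clicks, allocating events and censorings
            le = last_event
            nh = n_hat[lo]
            km_prev = km_hat[le]
            local_events = np.zeros(up - lo + 1, dtype=int)
            local_nhat = np.zeros(up - lo + 2)
            local_nhat[0] = nh
            local_km = np.zeros(up - lo + 1)
            for k in range(lo, up + 1):
                j = k - lo
                if km_prev > 0 and local_nhat[j] > 0:
                    d_k = int(round(local_nhat[j] * (1.0 - s[k] / km_prev)))
                    d_k = max(0, min(d_k, int(local_nhat[j])))
                else:
                    d_k = 0
                local_events[j] = d_k
                km_k = km_prev * (1.0 - d_k / local_nhat[j]) if local_nhat[j] > 0 else 0.0
                if d_k > 0:
                    km_prev = km_k
                local_km[j] = km_k if d_k > 0 else km_prev
                # censorings between this click and the next
                next_t = t_s[k + 1] if k + 1 < K else np.inf
                c_k = int(np.sum((cen_t >= t_s[k]) & (cen_t < next_t)))
                local_nhat[j + 1] = local_nhat[j] - d_k - c_k
            if last_interval:
                break
            implied_next = local_nhat[-1]
            diff = int(round(implied_next - nrisk[i + 1]))
            if diff == 0:
                break
            new_cen = n_cen + diff
            if new_cen < 0 or new_cen > int(n_hat[lo]):
                break
            if new_cen == n_cen:
                break
            n_cen = new_cen

        # commit interval results
        for k in range(lo, up + 1):
            j = k - lo
            n_event[k] = local_events[j]
            n_hat[k] = local_nhat[j]
            n_hat[k + 1] = local_nhat[j + 1]
            if local_events[j] > 0:
                km_hat[k] = local_km[j]
                last_event = k
            else:
                km_hat[k] = km_hat[last_event]
        cen_times_all.extend(cen_t.tolist())
        if not last_interval:
            n_hat[lower[i + 1]] = local_nhat[-1]

    # subjects still at risk after the last click: censored at the end
    remaining = int(n_hat[K] if n_hat[K] > 0 else 0)
    t_end = float(t_s[-1])

    event_times = np.repeat(t_s, n_event)
    cen_times = np.asarray(sorted(cen_times_all + [t_end] * remaining))

    # final pass: force the published total event count exactly.  Labels are
    # toggled at the *earliest* eligible times, where risk sets are largest
    # and one relabel moves the KM curve least (~S/n).
    if risk.total_events is not None:
        diff = int(risk.total_events) - event_times.size
        if diff > 0:
            take = min(diff, int(cen_times.size))
            if take > 0:
                moved, cen_times = cen_times[:take], cen_times[take:]
                event_times = np.sort(np.concatenate([event_times, moved]))
            if take < diff:
                logger.warning("could not reach published total events: short by %d", diff - take)
        elif diff < 0:
            take = min(-diff, event_times.size)
            moved, event_times = event_times[:take], event_times[take:]
            cen_times = np.sort(np.concatenate([cen_times, moved]))

    times = np.concatenate([event_times, cen_times])
    events = np.concatenate([np.ones(event_times.size, int), np.zeros(cen_times.size, int)])
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    times = np.maximum(times, 1e-6)  # subject-level times must be positive
    return IPDDataset(
        time=times,
        event=events,
        covariates=pd.DataFrame(index=range(times.size)),
        arm_label="reconstructed",
    )


# ---------------------------------------------------------------------------
# kernel hazard


def kernel_hazard(
    data: IPDDataset,
    grid: np.ndarray | None = None,
    bandwidth: float | str = "auto",
    km: StepSurvival | None = None,
) -> KernelHazard:
    """Kernel-weighted Nelson-Aalen hazard from KM data.

    h(t) = sum_i K_b(t - t_i) d_i / n_i over event times t_i, with an
    Epanechnikov kernel.  Near 0 and the end of follow-up the kernel mass
    falling outside the observation window is renormalized away
    (cut-and-normalize boundary correction), which keeps the estimate
    nonnegative.  ``bandwidth="auto"`` uses (t_last - t_first_event) / 8.
    """
    if data.n_events < 5:
        raise ValidationError("kernel hazard needs at least 5 events")
    if km is None:
        km = km_estimate(data)
    t_max = km.max_follow
    if grid is None:
        grid = np.linspace(0.0, t_max, 256)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > t_max + 1e-9):
        raise ValidationError("hazard grid must lie within observed follow-up")
    if bandwidth == "auto":
        b = (t_max - float(km.times.min())) / 8.0
    else:
        b = float(bandwidth)
    if not b > 0:
        raise ValidationError("bandwidth must be positive")

    increments = km.n_event / km.n_risk  # Nelson-Aalen jumps
    x = (grid[:, None] - km.times[None, :]) / b
    kern = np.where(np.abs(x) < 1.0, 0.75 * (1.0 - x ** 2), 0.0) / b
    raw = kern @ increments
    # mass of the kernel inside [0, t_max] for each grid point
    lo = np.clip(-grid / b, -1.0, 1.0)
    hi = np.clip((t_max - grid) / b, -1.0, 1.0)
    mass = 0.75 * (hi - hi ** 3 / 3.0) - 0.75 * (lo - lo ** 3 / 3.0)
    mass = np.maximum(mass, 1e-12)
    return KernelHazard(grid=grid, hazard=raw / mass, bandwidth=b)
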