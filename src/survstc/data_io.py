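"""Data model and delimited-text I/O for unanchored survival STC.

All tabular inputs cross this boundary: subject-level survival data for the
index arm (and Guyot-reconstructed comparator pseudo-IPD), digitized
Kaplan-Meier curve coordinates, numbers-at-risk tables, aggregate baseline
summaries of comparator trials, and the analysis configuration.

Conventions enforced here (and relied on everywhere downstream):

* time is measured in months, strictly positive at the subject level;
* event indicators are coded 0 (censored) / 1 (event);
* binary covariates are coded 0/1; continuous covariates pass through
  unscaled (centering happens inside model fitting);
* delimited text is comma-separated UTF-8 with a header row.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "IPDDataset",
    "DigitizedCurve",
    "RiskTable",
    "AggregateBaseline",
    "AnalysisConfig",
    "ValidationError",
    "read_ipd",
    "write_ipd",
    "read_digitized_curve",
    "write_digitized_curve",
    "read_risk_table",
    "write_risk_table",
    "read_aggregate_baseline",
    "write_aggregate_baseline",
    "read_analysis_config",
]


class ValidationError(ValueError):
    """An input violated the data model."""


# ---------------------------------------------------------------------------
# subject-level data


@dataclass(frozen=True)
class IPDDataset:
    """Individual patient data for one treatment arm.

    ``time`` holds follow-up in months (strictly positive), ``event`` the
    0/1 event indicator, and ``covariates`` one column per baseline
    covariate in a fixed order.  Missing covariate values are rejected at
    construction: the STC regression has no missing-data machinery.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame
    arm_label: str = "index"
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        object.__setattr__(self, "time", time)
        if time.ndim != 1 or event.shape != time.shape:
            raise ValidationError("time and event must be 1-d arrays of equal length")
        if time.size == 0:
            raise ValidationError("dataset is empty")
        bad = np.where(~(time > 0) | ~np.isfinite(time))[0]
        if bad.size:
            raise ValidationError(
                f"non-positive or non-finite follow-up time in row {bad[0] + 1}"
            )
        if not np.isin(event, [0, 1]).all():
            bad = np.where(~np.isin(event, [0, 1]))[0]
            raise ValidationError(f"event indicator not in {{0,1}} in row {bad[0] + 1}")
        object.__setattr__(self, "event", event.astype(int))
        cov = self.covariates
        if not isinstance(cov, pd.DataFrame):
            cov = pd.DataFrame(cov)
        if len(cov) != time.size:
            raise ValidationError("covariate table length does not match times")
        for name in cov.columns:
            col = cov[name]
            if col.isna().any():
                raise ValidationError(f"missing value in covariate '{name}'")
            if not np.issubdtype(np.asarray(col).dtype, np.number):
                raise ValidationError(f"covariate '{name}' is not numeric")
        object.__setattr__(self, "covariates", cov.reset_index(drop=True))
        if self.ids and len(self.ids) != time.size:
            raise ValidationError("ids length does not match times")

    # -- derived quantities ------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    @property
    def horizon(self) -> float:
        """Maximum observed follow-up time (months)."""
        return float(self.time.max())

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        missing = [c for c in names if c not in self.covariates.columns]
        if missing:
            raise ValidationError(f"covariates not in dataset: {missing}")
        return self.covariates[list(names)].to_numpy(dtype=float)

    def subset(self, idx: np.ndarray, arm_label: str | None = None) -> "IPDDataset":
        """Row subset / resample (used by the bootstrap)."""
        return IPDDataset(
            time=self.time[idx],
            event=self.event[idx],
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            arm_label=arm_label or self.arm_label,
            ids=tuple(self.ids[i] for i in idx) if self.ids else (),
        )


def read_ipd(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    arm_label: str | None = None,
) -> IPDDataset:
    """Read subject-level data from a CSV file.

    ``schema`` maps the roles ``time``, ``event`` and optionally ``id`` to
    column names (defaults: ``time``, ``event``, ``id``).  Every remaining
    column is treated as a covariate, in file order.
    """
    schema = dict(schema or {})
    time_col = schema.get("time", "time")
    event_col = schema.get("event", "event")
    id_col = schema.get("id", "id")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValidationError(f"required column '{col}' missing from {path}")
    ids: tuple[str, ...] = ()
    if id_col in df.columns:
        ids = tuple(str(v) for v in df[id_col])
        df = df.drop(columns=[id_col])
    cov_cols = [c for c in df.columns if c not in (time_col, event_col)]
    return IPDDataset(
        time=df[time_col].to_numpy(dtype=float),
        event=df[event_col].to_numpy(),
        covariates=df[cov_cols],
        arm_label=arm_label or Path(path).stem,
        ids=ids,
    )


def write_ipd(data: IPDDataset, path: str | Path) -> None:
    df = pd.DataFrame({"time": data.time, "event": data.event})
    if data.ids:
        df.insert(0, "id", list(data.ids))
    for c in data.covariate_names:
        df[c] = data.covariates[c].to_numpy()
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# digitized comparator curves and risk tables


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized (time, survival) coordinates of a published KM curve.

    Guaranteed to start at (0, 1), have strictly increasing times and
    non-increasing survival in [0, 1].  ``n_clamped`` records how many
    points had to be clamped to the running minimum on construction.
    """

    times: np.ndarray
    survival: np.ndarray
    n_clamped: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.ndim != 1 or s.shape != t.shape or t.size == 0:
            raise ValidationError("curve needs matching 1-d time/survival arrays")
        if not (t[0] == 0 and s[0] == 1):
            raise ValidationError("curve must start at (0, 1); use from_points()")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("curve times must be strictly increasing")
        if np.any(np.diff(s) > 0) or s.min() < 0 or s.max() > 1:
            raise ValidationError("survival must be non-increasing within [0, 1]")

    @classmethod
    def from_points(
        cls,
        times: Sequence[float],
        survival: Sequence[float],
        tol: float = 0.005,
    ) -> "DigitizedCurve":
        """Build a valid curve from raw digitized points.

        (0, 1) is prepended when absent; survival values are clamped to the
        running minimum (digitization noise never *raises* a KM curve), and
        values outside [0, 1] by more than ``tol`` are rejected.
        """
        t = np.asarray(times, dtype=float)
        s = np.asarray(survival, dtype=float)
        if t.size == 0:
            raise ValidationError("no digitized points supplied")
        order = np.argsort(t, kind="stable")
        t, s = t[order], s[order]
        if np.any(np.diff(t) <= 0):
            raise ValidationError("duplicate digitized time values")
        if s.min() < -tol or s.max() > 1 + tol:
            raise ValidationError(
                f"survival value outside [0,1] beyond tolerance {tol}"
            )
        s = np.clip(s, 0.0, 1.0)
        if t[0] != 0.0:
            t = np.concatenate([[0.0], t])
            s = np.concatenate([[1.0], s])
        running = np.minimum.accumulate(s)
        n_clamped = int(np.sum(s > running))
        if n_clamped:
            logger.info("clamped %d digitized survival points to running minimum", n_clamped)
        return cls(times=t, survival=running, n_clamped=n_clamped)

    def at(self, t: np.ndarray | float) -> np.ndarray:
        """Step-interpolated survival (right-continuous, last value carried)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.survival[np.clip(idx, 0, self.times.size - 1)]


def read_digitized_curve(path: str | Path) -> DigitizedCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValidationError("digitized curve file needs (time, survival) columns")
    return DigitizedCurve.from_points(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def write_digitized_curve(curve: DigitizedCurve, path: str | Path) -> None:
    pd.DataFrame({"time": curve.times, "survival": curve.survival}).to_csv(path, index=False)


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk at scheduled times, as printed under a KM figure."""

    interval_times: np.ndarray
    n_at_risk: np.ndarray
    total_events: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.interval_times, dtype=float)
        n = np.asarray(self.n_at_risk, dtype=int)
        object.__setattr__(self, "interval_times", t)
        object.__setattr__(self, "n_at_risk", n)
        if t.ndim != 1 or n.shape != t.shape or t.size == 0:
            raise ValidationError("risk table needs matching 1-d arrays")
        if t[0] != 0:
            raise ValidationError("risk table must start at time 0")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("risk-table times must be strictly increasing")
        if np.any(n < 0) or np.any(np.diff(n) > 0):
            raise ValidationError("numbers at risk must be non-negative and non-increasing")
        if self.total_events is not None and self.total_events < 0:
            raise ValidationError("total_events must be non-negative")


def read_risk_table(path: str | Path) -> RiskTable:
    """Read a risk table CSV with columns time, n_at_risk[, total_events].

    ``total_events``, when present, is a single value in the first row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    total = None
    if "total_events" in df.columns and pd.notna(df["total_events"].iloc[0]):
        total = int(df["total_events"].iloc[0])
    return RiskTable(
        interval_times=df.iloc[:, 0].to_numpy(),
        n_at_risk=df.iloc[:, 1].to_numpy(),
        total_events=total,
    )


def write_risk_table(risk: RiskTable, path: str | Path) -> None:
    df = pd.DataFrame({"time": risk.interval_times, "n_at_risk": risk.n_at_risk})
    if risk.total_events is not None:
        df["total_events"] = [risk.total_events] + [np.nan] * (len(df) - 1)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# aggregate baselines and configuration


@dataclass(frozen=True)
class AggregateBaseline:
    """Aggregate baseline characteristics of a comparator trial arm.

    ``values`` holds the mean covariate vector used by the STC plug-in
    predictor: reported proportions for binary covariates and a central
    value (median or mean, as published) for continuous ones.  Covariates a
    trial did not report are simply absent — absence is information, not
    zero.
    """

    values: Mapping[str, float]
    trial_label: str
    follow_up: float
    binary_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = {str(k): float(v) for k, v in dict(self.values).items()}
        object.__setattr__(self, "values", vals)
        if not self.follow_up > 0:
            raise ValidationError("follow_up must be positive (months)")
        binaries = set(self.binary_covariates) if self.binary_covariates else set(vals)
        for name, v in vals.items():
            if name in binaries and self.binary_covariates and not 0 <= v <= 1:
                raise ValidationError(f"proportion for '{name}' outside [0,1]: {v}")
            if not self.binary_covariates and not np.isfinite(v):
                raise ValidationError(f"non-finite baseline value for '{name}'")
            if v < 0:
                raise ValidationError(f"negative baseline value for '{name}': {v}")

    @property
    def reported(self) -> list[str]:
        return list(self.values)


def read_aggregate_baseline(path: str | Path) -> AggregateBaseline:
    """Read an aggregate baseline from YAML (or JSON, a YAML subset)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return AggregateBaseline(
        values=raw.get("covariates", {}),
        trial_label=str(raw.get("trial_label", Path(path).stem)),
        follow_up=float(raw["follow_up"]),
        binary_covariates=tuple(raw.get("binary_covariates", ())),
    )


def write_aggregate_baseline(baseline: AggregateBaseline, path: str | Path) -> None:
    payload = {
        "trial_label": baseline.trial_label,
        "follow_up": baseline.follow_up,
        "covariates": dict(baseline.values),
    }
    if baseline.binary_covariates:
        payload["binary_covariates"] = list(baseline.binary_covariates)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


#: default candidate model space: 7 standard parametric families plus
#: {1,2,3 internal knots} x {hazard, odds, normal} spline models = 16.
DEFAULT_FAMILIES = (
    "exponential",
    "weibull",
    "gompertz",
    "gamma",
    "loglogistic",
    "lognormal",
    "genf",
)
DEFAULT_LINKS = ("hazard", "odds", "normal")
DEFAULT_KNOT_COUNTS = (1, 2, 3)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of a full STC run; serialized into the run manifest."""

    candidate_families: tuple[str, ...] = DEFAULT_FAMILIES
    knot_counts: tuple[int, ...] = DEFAULT_KNOT_COUNTS
    links: tuple[str, ...] = DEFAULT_LINKS
    candidate_covariates: tuple[str, ...] = ()
    landmark_times: tuple[float, ...] = (6.0, 12.0, 18.0, 24.0)
    bootstrap_B: int = 1000
    seed: int = 1
    truncation_rule: str = "shorter-horizon"
    bandwidth: float | str = "auto"
    covariate_strategy: str = "aic_subset"

    def __post_init__(self) -> None:
        if self.bootstrap_B < 1:
            raise ValidationError("bootstrap_B must be >= 1")
        if any(t <= 0 for t in self.landmark_times):
            raise ValidationError("landmark times must be positive")
        if self.covariate_strategy not in ("aic_subset", "all_reported", "none"):
            raise ValidationError(f"unknown covariate strategy {self.covariate_strategy!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_analysis_config(path: str | Path) -> AnalysisConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for f in dataclasses.fields(AnalysisConfig):
        if f.name in raw:
            v = raw[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return AnalysisConfig(**kwargs)


def write_manifest(path: str | Path, payload: Mapping) -> None:
    """Write a JSON run manifest (config, seed, library versions)."""
    import scipy

    meta = {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }
    out = {"versions": meta, **payload}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=2, sort_keys=True, default=str)
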