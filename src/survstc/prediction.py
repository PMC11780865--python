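"""The STC core: predict the index treatment's survival curve in a
comparator population.

An outcome-regression model fitted to index-arm subject-level data is
evaluated at the *aggregate* baseline characteristics of a comparator
trial: the plug-in linear predictor is mu_hat + X_bar . beta_hat with X_bar
the comparator's reported mean covariate vector (proportions for binary
covariates, a central value for continuous ones).  For AFT families this
gives an acceleration factor theta_hat and curve S0(t * theta_hat); for
spline models the covariate shift enters the link-transformed spline; for
Gompertz it multiplies the baseline hazard.

Prediction is at mean covariates only — by the non-linearity of the
survival function this is not the population-average curve, but it is the
estimator this methodology defines.  When a comparator does not report a
selected covariate, the covariate is dropped and the model *must be refit*
on the reduced set (``align_covariates`` + refit), so adjustment sets may
differ between comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_io import AggregateBaseline, ValidationError
from .parametric import FittedSurvivalModel, linear_predictor

__all__ = ["STCPrediction", "align_covariates", "predict_at_population"]


@dataclass(frozen=True)
class STCPrediction:
    """A predicted index-treatment curve in a comparator population."""

    model: FittedSurvivalModel
    population: AggregateBaseline
    lp_value: float
    curve: Callable[[np.ndarray], np.ndarray]
    grid: np.ndarray
    dropped_covariates: tuple[str, ...] = ()

    @property
    def horizon(self) -> float:
        return float(self.grid[-1])

    def survival(self, t) -> np.ndarray:
        return self.curve(np.asarray(t, dtype=float))

    def hazard(self, t) -> np.ndarray:
        return self.model.hazard(dict(self.population.values), t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.grid, "survival": self.curve(self.grid)})


def align_covariates(
    selected: Sequence[str], baseline: AggregateBaseline
) -> list[str]:
    """Covariates usable against this comparator: selected AND reported.

    Order is preserved.  The caller must refit the outcome model on the
    reduced set before predicting — coefficients from the full model are
    not transferable.
    """
    reported = set(baseline.values)
    return [c for c in selected if c in reported]


def predict_at_population(
    model: FittedSurvivalModel,
    baseline: AggregateBaseline,
    grid: np.ndarray | int | None = None,
    dropped_covariates: Sequence[str] = (),
) -> STCPrediction:
    """Evaluate the fitted model at the comparator's mean covariate vector.

    ``grid`` may be an array of times, a point count (spread over the
    comparator follow-up), or None (1,000 points, the default export
    density).
    """
    missing = [c for c in model.covariate_coefs if c not in baseline.values]
    if missing:
        raise ValidationError(
            f"model covariates {missing} not reported by '{baseline.trial_label}'; "
            "run align_covariates and refit the model on the reduced set"
        )
    if grid is None:
        grid = 1000
    if np.isscalar(grid):
        grid = np.linspace(0.0, baseline.follow_up, int(grid) + 1)
    grid = np.asarray(grid, dtype=float)
    X = dict(baseline.values)
    lp = linear_predictor(model, X)

    def curve(t: np.ndarray) -> np.ndarray:
        return model.survival(X, t)

    return STCPrediction(
        model=model,
        population=baseline,
        lp_value=lp,
        curve=curve,
        grid=grid,
        dropped_covariates=tuple(dropped_covariates),
    )
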