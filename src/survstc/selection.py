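"""Two-stage AIC model selection and the sensitivity model set.

The candidate space is 16 survival distributions: 7 standard parametric
families (exponential, Weibull, Gompertz, gamma, log-logistic, log-normal,
generalized F) plus 9 spline models ({1,2,3} internal knots x {hazard,
odds, normal} links).  Fitting a covariate subset for each of the 16
distributions would be 16 x 2^10 fits, so selection is staged under the
working assumption that the best covariate subset does not depend on the
baseline distribution:

* stage 1 ranks all distributions with no covariates by AIC (non-converged
  fits dropped; ties broken by fewer parameters, then declared family
  order) and flags the top four (base case plus three sensitivities);
* stage 2 enumerates every covariate subset (2^p, p <= 16 guarded) on the
  stage-1 winner and returns the lowest-AIC converged fit, along with a
  report of the ten best subsets.

An exhaustive joint mode is available for problems small enough to afford
it.  The six sensitivity analyses are: the next three stage-1 distributions
with the stage-2 covariate set; the winner with all candidate covariates;
with none; and a naive KM-only comparison.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .data_io import AnalysisConfig, IPDDataset, ValidationError
from .parametric import FittedSurvivalModel, fit_parametric
from .splines import fit_spline

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "enumerate_candidates",
    "fit_spec",
    "stage1_select",
    "stage2_select",
    "sensitivity_set",
    "selection_report",
]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate distribution: a parametric family or a spline."""

    family: str
    link: str = "n/a"
    knots: int = 0  # internal knots; 0 for parametric families

    @property
    def label(self) -> str:
        if self.family == "spline":
            return f"spline_{self.knots}knot_{self.link}"
        return self.family


@dataclass(frozen=True)
class SensitivitySpec:
    """One entry of the sensitivity model set."""

    name: str
    spec: ModelSpec | None  # None => naive KM-only comparison
    covariates: tuple[str, ...] = ()
    naive: bool = False


def enumerate_candidates(config: AnalysisConfig | None = None) -> list[ModelSpec]:
    """The candidate distribution grid (default: 7 parametric + 9 spline = 16)."""
    config = config or AnalysisConfig()
    specs = [ModelSpec(family=f) for f in config.candidate_families]
    for m in config.knot_counts:
        for link in config.links:
            specs.append(ModelSpec(family="spline", link=link, knots=m))
    return specs


def fit_spec(
    data: IPDDataset, spec: ModelSpec, covariates: Sequence[str] = ()
) -> FittedSurvivalModel:
    if spec.family == "spline":
        return fit_spline(data, m=spec.knots, link=spec.link, covariates=covariates)
    return fit_parametric(data, spec.family, covariates=covariates)


def _rank_key(config: AnalysisConfig):
    order = {ModelSpec(family=f).label: i for i, f in enumerate(config.candidate_families)}
    n = len(order)
    for m in config.knot_counts:
        for link in config.links:
            order[ModelSpec(family="spline", link=link, knots=m).label] = n
            n += 1

    def key(item):
        spec, fit = item
        return (fit.aic, fit.n_params, order.get(spec.label, 999))

    return key


def stage1_select(
    data: IPDDataset,
    config: AnalysisConfig | None = None,
    include_excluded: bool = False,
):
    """Fit every candidate distribution with no covariates; rank by AIC.

    Returns the full (spec, fit) ranking, converged fits only; the first
    four entries are the base-case distribution and its three sensitivity
    alternates.  Raises if nothing converged.  With
    ``include_excluded=True`` also returns the non-converged (spec, fit)
    pairs, for the selection report.
    """
    config = config or AnalysisConfig()
    fits = []
    excluded = []
    for spec in enumerate_candidates(config):
        try:
            fit = fit_spec(data, spec, covariates=())
        except ValidationError as exc:
            logger.info("candidate %s failed: %s", spec.label, exc)
            continue
        if fit.converged:
            fits.append((spec, fit))
        else:
            logger.info("candidate %s did not converge; excluded", spec.label)
            excluded.append((spec, fit))
    if not fits:
        raise ValidationError("no candidate distribution converged")
    fits.sort(key=_rank_key(config))
    if include_excluded:
        return fits, excluded
    return fits


def stage2_select(
    data: IPDDataset,
    spec: ModelSpec,
    candidates: Sequence[str],
) -> tuple[FittedSurvivalModel, pd.DataFrame]:
    """Exhaustive covariate-subset search on one distribution.

    Fits all 2^|candidates| subsets (guarded at 16 candidates), drops
    non-converged fits, and returns the lowest-AIC fit plus a report of the
    ten best subsets.  With no candidates the intercept-only fit is
    returned.
    """
    candidates = list(candidates)
    if len(candidates) > 16:
        raise ValidationError("refusing exhaustive enumeration beyond 16 candidates")
    rows = []
    best: FittedSurvivalModel | None = None
    best_key = None
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            fit = fit_spec(data, spec, covariates=subset)
            rows.append(
                {
                    "covariates": "+".join(subset) or "(none)",
                    "n_covariates": r,
                    "loglik": fit.loglik,
                    "n_params": fit.n_params,
                    "aic": fit.aic,
                    "converged": fit.converged,
                }
            )
            if fit.converged:
                key = (fit.aic, fit.n_params)
                if best is None or key < best_key:
                    best, best_key = fit, key
    if best is None:
        raise ValidationError("no covariate subset converged")
    report = (
        pd.DataFrame(rows)
        .sort_values(["converged", "aic"], ascending=[False, True], kind="stable")
        .head(10)
        .reset_index(drop=True)
    )
    report.attrs["n_subsets_fitted"] = len(rows)
    return best, report


def joint_select(
    data: IPDDataset,
    candidates: Sequence[str],
    config: AnalysisConfig | None = None,
) -> tuple[ModelSpec, FittedSurvivalModel]:
    """Exhaustive joint (distribution x subset) search, for small problems."""
    config = config or AnalysisConfig()
    best = None
    for spec in enumerate_candidates(config):
        try:
            fit, _ = stage2_select(data, spec, candidates)
        except ValidationError:
            continue
        if best is None or (fit.aic, fit.n_params) < (best[1].aic, best[1].n_params):
            best = (spec, fit)
    if best is None:
        raise ValidationError("no model converged in joint selection")
    return best


def sensitivity_set(
    stage1: list[tuple[ModelSpec, FittedSurvivalModel]],
    stage2_covariates: Sequence[str],
    all_candidates: Sequence[str],
) -> list[SensitivitySpec]:
    """The six sensitivity analyses around the base case."""
    if not stage1:
        raise ValidationError("empty stage-1 ranking")
    winner = stage1[0][0]
    alternates = [spec for spec, _ in stage1[1:4]]
    if len(alternates) < 3:
        warnings.warn(
            f"only {len(alternates)} converged alternate distributions available",
            stacklevel=2,
        )
    out = [
        SensitivitySpec(
            name=f"alt_distribution_{i+1}_{spec.label}",
            spec=spec,
            covariates=tuple(stage2_covariates),
        )
        for i, spec in enumerate(alternates)
    ]
    out.append(
        SensitivitySpec(
            name="all_covariates", spec=winner, covariates=tuple(all_candidates)
        )
    )
    out.append(SensitivitySpec(name="no_covariates", spec=winner, covariates=()))
    out.append(SensitivitySpec(name="naive_km_only", spec=None, naive=True))
    return out


def selection_report(
    ranking: list[tuple[ModelSpec, FittedSurvivalModel]]
) -> pd.DataFrame:
    """One row per fitted candidate, ranked (stage-1 report CSV)."""
    rows = []
    for rank, (spec, fit) in enumerate(ranking, start=1):
        rows.append(
            {
                "rank": rank,
                "family": spec.family,
                "link": spec.link,
                "knots": spec.knots,
                "loglik": fit.loglik,
                "n_params": fit.n_params,
                "aic": fit.aic,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
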