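# survstc

Unanchored **simulated treatment comparison (STC)** for survival outcomes:
covariate-adjusted parametric and Royston–Parmar spline survival models
fitted to individual patient data (IPD) for one treatment, used to predict
survival at the aggregate baseline characteristics of comparator trials,
and compared against comparator Kaplan–Meier data through restricted mean
survival time (RMST) differences and time-varying (landmark) hazard ratios
with bootstrap uncertainty.

## Who this is for

Analysts performing population-adjusted indirect treatment comparisons when
no common control arm exists — e.g. health-technology-assessment work in
oncology where the trial of interest provides IPD but every comparator is
available only as a published KM figure, a numbers-at-risk table and a
baseline-characteristics table. Unlike Cox-based weighting approaches
(MAIC), the outcome-regression route makes no proportional-hazards
assumption and yields full predicted survival curves.

## The model

For subject *j* with covariates **X**ⱼ, the accelerated failure time (AFT)
families model

&nbsp;&nbsp;S(t | **X**ⱼ) = S₀(t·θⱼ), &nbsp; h(t | **X**ⱼ) = θⱼ·h₀(t·θⱼ),
&nbsp; log θⱼ = μ + **X**ⱼ·**β**,

so a covariate with coefficient log 2 halves expected survival when it
doubles. Seven standard baselines are available (exponential, Weibull,
Gompertz — as proportional hazards —, gamma, log-logistic, log-normal,
generalized F), plus nine Royston–Parmar flexible models in which a
restricted cubic spline in log time u = log t,

&nbsp;&nbsp;g(S(t, **X**)) = γ₀ + γ₁u + Σⱼ γⱼ₊₁ vⱼ(u) + **X**·**β**,

is linked to survival through log cumulative hazard, log cumulative odds,
or probit links (m ∈ {1,2,3} internal knots at quantiles of the uncensored
log event times; covariates act on γ₀). With m = 0 each link collapses
exactly to Weibull / log-logistic / log-normal — an identity the test suite
verifies.

The STC step plugs the comparator's published mean covariate vector
**X̄**₍₂₎ into the fitted model, log θ̂₁₍₂₎ = μ̂ + **X̄**₍₂₎·**β̂**, giving the
index treatment's predicted curve in the comparator population. Comparator
arms themselves are reconstructed as pseudo-IPD from digitized KM
coordinates and numbers-at-risk tables (Guyot's iterative algorithm, with
exact calibration to a published total event count). Effects are summarized
as the RMST difference up to the shorter follow-up and hazard ratios at 6,
12, 18 and 24 months (model hazard over an Epanechnikov-kernel hazard from
the comparator KM data); uncertainty comes from jointly resampling index
subjects and comparator pseudo-IPD, refitting the frozen model
specification per replicate (1,000 replicates by default; percentile
intervals; add-one one-sided p-values).

Model selection is the two-stage AIC workflow: rank all 16 distributions
unadjusted, then exhaustively search covariate subsets (2¹⁰ = 1,024 for ten
candidates) on the winner; six sensitivity analyses (three alternate
distributions, all/no covariates, naive KM-only) round out the model set.

## Worked example

`examples/stc_comparison.py` builds a synthetic two-population scenario
(the generator emulates an advanced renal-cell-carcinoma setting: ten
baseline covariates, mixed administrative and random censoring, and
comparators rendered as digitized curves + risk tables + baseline rows),
aligns the adjustment set to what the comparator reports, and bootstraps
the comparison:

```text
selected adjustment set: ['AGE', 'IMDC_FAVOURABLE', 'METS_GE2', 'LIVER_LESIONS']
reported by trial_J: ['AGE', 'FEMALE', 'IMDC_FAVOURABLE', 'METS_GE2', 'MSKCC_FAVOURABLE']
-> aligned set used for this comparison: ['AGE', 'IMDC_FAVOURABLE', 'METS_GE2']

comparison vs trial_J (tau = 46 months, B = 200 bootstrap replicates):
  RMST difference: 6.28 months (95% CI 4.09, 8.35), one-sided p = 0.0050
  HR at    6 months: 0.594 (95% CI 0.440, 0.772)
  HR at   12 months: 0.589 (95% CI 0.482, 0.749)
  HR at   18 months: 0.629 (95% CI 0.494, 0.806)
  HR at   24 months: 0.747 (95% CI 0.570, 0.966)
```

The index treatment gains 6.3 months of RMST over the comparator's 46-month
follow-up, and the landmark hazard ratios (< 1 favours the index treatment)
show the advantage attenuating over time — the scenario builds in a true
survival advantage, so this is the expected signature. The other examples
show model selection (`fit_and_select.py`) and KM-curve reconstruction
fidelity (`guyot_reconstruction.py`).

The same pipeline is scriptable from a shell:

```bash
survstc simulate --out scen --seed 3
survstc fit scen/index.csv --out fit1
survstc compare fit1/model.json scen/index.csv scen/trial_* --out results --seed 1
```

Every run writes a JSON manifest (config, seed, knot rule, dropped
covariates per comparator) sufficient to reproduce it bit-for-bit.

## Layout

| path | contents |
|---|---|
| `src/survstc/data_io.py` | data model + CSV/YAML readers and writers |
| `src/survstc/families.py` | baseline distributions (incl. stabilized generalized F) |
| `src/survstc/parametric.py` | covariate-adjusted AFT/PH maximum likelihood |
| `src/survstc/splines.py` | Royston–Parmar models, three links |
| `src/survstc/km.py` | KM, RMST, Guyot reconstruction, kernel hazards |
| `src/survstc/prediction.py` | covariate alignment + plug-in population prediction |
| `src/survstc/selection.py` | two-stage AIC selection, sensitivity set |
| `src/survstc/effects.py` | estimands and the dual bootstrap |
| `src/survstc/simulate.py` | synthetic scenario generator |
| `src/survstc/cli.py` | `survstc simulate / fit / compare` |

See `docs/methods.md` for the statistical details and design choices.
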