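# Methods

This note records the statistical model, the numerical choices, and the
limits of what the synthetic-data tests demonstrate. It states nothing the
test suite or `scripts/acceptance.py` does not itself compute.

## Setting and estimand

An unanchored indirect comparison contrasts a treatment observed with
subject-level data (the *index* arm) against comparators observed only in
aggregate: a published KM curve, a numbers-at-risk table, sometimes a total
event count, and a table of baseline characteristics. With no shared
control arm, validity rests entirely on the outcome model adjusting for
every prognostic factor and effect modifier — an untestable assumption that
this package inherits from the methodology; nothing here can detect an
unmeasured confounder.

The target population is the comparator's. The index model is fitted to
index IPD and evaluated at the comparator's mean covariate vector; the
comparator itself is summarized nonparametrically from its reconstructed
KM data. Relative effects are formed on two scales:

* **RMST difference** ∫₀^τ S₁(t)dt − ∫₀^τ S₂(t)dt, with τ the shorter of
  the index horizon and the comparator follow-up (never extrapolating);
* **landmark hazard ratios** h₁(t)/h₂(t) at fixed months, which accommodate
  non-proportional hazards; HR < 1 favours the index treatment.

Prediction is at mean covariates. Because the survival function is
non-linear, this is not the population-averaged curve; it is the estimator
the methodology defines, and the discrepancy (non-collapsibility) is a
known approximation, not a bug. No integration over a covariate
distribution is attempted.

## Survival models

**AFT families.** S(t|X) = S₀(t·θ), log θ = μ + Σβₖ(Xₖ−cₖ). Every family
uses a *unit-scale* baseline so that μ is exactly the (negative log) time
scale and the linear predictor is exactly the log acceleration factor:
exponential (no shape), Weibull S₀(u)=exp(−uᵃ), gamma (unit rate, shape a),
log-logistic S₀(u)=1/(1+uᵃ), log-normal (unit median, σ), and generalized F
in the stabilized (σ, Q, P) parameterisation: with δ=√(Q²+2P),
s₁=2/(Q²+2P+Qδ), s₂=2/(Q²+2P−Qδ), w=δ·log(u)/σ, survival is the
F(2s₁,2s₂) upper tail at e^w. Its documented limits — (Q=0,P=1) ≡
log-logistic(shape √2/σ), (Q=0,P→0) → log-normal(σ) — are verified in
tests against closed forms, and the implementation was cross-checked to
machine precision against an independent reference implementation during
development. **Gompertz** is proportional hazards, h(t|X)=e^{lp}·e^{bt}
with b unrestricted in sign; a defective distribution (b<0) is legitimate
and handled in simulation by administrative censoring.

**Royston–Parmar splines.** g(S(t,X)) = s(u,γ) + X·β on u = log t, with
restricted cubic basis vⱼ(u) = (u−kⱼ)₊³ − ϑⱼ(u−k_min)₊³ − (1−ϑⱼ)(u−k_max)₊³,
ϑⱼ=(k_max−kⱼ)/(k_max−k_min) — linear beyond the boundary knots. Links:
log cumulative hazard S=exp(−e^η); log cumulative odds S=1/(1+e^η); probit
S=Φ(−η). The probit link is written with the sign that makes η increasing
in time, matching the other links and making the m=0 model exactly
log-normal. Covariates act only on γ₀ (no time-varying effects). Knots:
boundary at min/max uncensored log event time, internal at equally spaced
quantiles of uncensored log event times (m=1: median; m=2: 33.3/66.7;
m=3: 25/50/75) — the conventional placement; it is recorded in the run
manifest since results are conditional on it.

## Estimation and numerics

Right-censored log-likelihood Σ d·log f(t|X) + (1−d)·log S(t|X), maximized
by BFGS on transformed parameters (log for positive shapes; identity for
Q, Gompertz b and all β), started from method-of-moments values, with a
Nelder–Mead polish when BFGS stalls on flat curvature (generalized F is the
usual offender) and up to five deterministic jittered restarts stopping at
the first convergence. The exponential family is solved by damped
Newton–Raphson on its concave Poisson-form likelihood (score X'(d−te^{lp}))
— exact, and fast enough to make the 1,024-subset enumeration routine.

Convergence is declared when the finite-difference gradient sup-norm falls
below max(10⁻³, 10⁻⁵·|loglik|) or the optimizer reports success; the scale
term reflects the precision actually achievable with finite differences on
likelihoods of magnitude 10³–10⁴. A spline fit whose s(u) is non-monotone
anywhere on a 1,000-point grid over the observed log-time range is flagged
non-converged (equivalent to a negative fitted hazard) rather than
constrained — non-converged models are excluded from selection, mirroring
the methodology's convergence filter. Continuous covariates are centered at
the sample mean for conditioning; this is likelihood-neutral (β identical,
μ shifted by Σβₖcₖ — a property test asserts it) and the centering vector
is stored with the model. The observed-information covariance (inverse
finite-difference Hessian) is attached for diagnostics only; all interval
estimation for estimands is by bootstrap.

Model fits are bit-reproducible: restart jitter uses a fixed internal seed,
and refitting the same data gives identical results.

## Selection

Stage 1 fits all 16 distributions unadjusted and ranks by AIC
(ties: fewer parameters, then the declared family order); the top four are
the base case plus three sensitivity alternates. Stage 2 fixes the winner
and exhaustively fits every covariate subset (guarded at 16 candidates),
under the working assumption that the best subset does not depend on the
baseline distribution; an exhaustive joint mode exists for small problems.
Both `aic_subset` and `all_reported` strategies are exposed, since
"adjust for everything reported" and "minimize AIC" are both defensible
and give different models; the manifest records which was used. The
sensitivity set is: three alternate distributions with the stage-2 subset,
the winner with all and with no covariates, and a naive KM-vs-KM
comparison.

## Comparator reconstruction and smoothing

**Guyot reconstruction.** Within each risk-table interval, the number of
censorings is solved iteratively so the at-risk count implied by the
digitized survival drops matches the next published number, censoring times
spread uniformly within the interval and events placed at the digitized
coordinates (ties: events before censorings). The final interval, which has
no closing at-risk constraint, assumes no interior censoring and censors
all remaining subjects at the last coordinate. A published total event
count is enforced exactly by a final pass that relabels the *earliest*
eligible times (largest risk sets, hence least KM distortion ≈ S/n per
relabel). Synthetic "digitized" inputs sample the KM step corners at
equally spaced survival levels — what a careful digitizer produces —
because uniform-in-time sampling under-resolves steep early segments and
bounds achievable fidelity. Measured round-trip error (25 arms, n 200–500,
20–40% censoring, 100–150 points, 6-month tables) stays below 0.02 on the
survival scale.

**Kernel hazard.** ĥ(t) = Σᵢ K_b(t−tᵢ)·dᵢ/nᵢ over the Nelson–Aalen
increments, Epanechnikov kernel, with cut-and-normalize boundary
correction (dividing by the kernel mass inside the observation window).
Müller-type linear boundary kernels have smaller boundary bias but can go
negative; nonnegativity was kept as the binding requirement since these
hazards enter log ratios. Default bandwidth (t_last − t_first-event)/8,
configurable. Landmark estimates in the last bandwidth of follow-up, or
where the risk set has decayed to a handful of subjects, are noisy — the
estimand tests size their samples so landmarks sit in the stable region.

## Bootstrap

Per replicate: index subjects and comparator pseudo-IPD rows are resampled
with replacement; the frozen specification (distribution, link, covariate
set) is refit, knots re-placed on the resample (they are data-derived);
selection is *not* repeated — so reported intervals do not carry
model-selection uncertainty, a declared limitation. Non-converged
replicates are dropped and counted; more than 20% aborts the comparison as
an unstable specification. Point estimates are bootstrap medians with
percentile 2.5/97.5 intervals; one-sided p-values use the add-one
estimator (1 + #{diff_b ≤ 0})/(B+1) (RMST) and (1 + #{log HR_b ≥ 0})/(B+1)
(hazard ratios), avoiding exact zeros. Other CI flavours (basic, normal)
were deliberately not implemented; percentile is the single supported
option.

## Synthetic data: what it does and does not show

The generator draws covariates (Bernoulli mixes plus continuous age),
event times by inverse transform from any supported family or a spline
truth (analytic inversion in the linear tails, bracketed root-finding
between the boundary knots), and censoring as min(administrative horizon,
exponential). The bundled scenario emulates a first-line
renal-cell-carcinoma comparison: ten covariates with realistic prevalences
(favourable-risk ~0.3, ≥2 metastatic sites ~0.7, median age 62), Weibull
truth with median ~30 months, ~35% censored by a 66-month horizon, four
comparators with shifted covariate mixes, differing follow-ups and
reporting subsets. Defaults (n≈350 index, n≈400 per comparator, 120 curve
points, 6-month risk tables, 1,000 bootstrap replicates) were fixed once
as representative of phase-3 oncology reporting.

Passing tests demonstrate internal correctness — likelihoods, identities,
reconstruction fidelity, frequentist calibration under a correctly
specified model — on data whose generating model is in the fitted class.
They do not demonstrate robustness to model misspecification, informative
censoring, covariate measurement error, digitization bias beyond ±0.005,
or unmeasured confounding; no synthetic experiment can validate the
no-unmeasured-confounders assumption an unanchored comparison needs.

## Test problem sizes

Statistical tests run at the smallest sizes that make their tolerances
meaningful: nesting identities at n=300 over 20 datasets; Wald coverage at
n=2000 over 200 replications; subset recovery at n=2000 over 100
replications (exponential family, where the Newton solver makes the full
102,400-fit enumeration cheap); estimand truth on exponential arms of
3,000–40,000 subjects (the largest only to stabilize the kernel hazard at
the 24-month landmark); null coverage over 50 repetitions at B=500. The
acceptance script uses reduced replicate counts for the same checks; its
values are recomputed fresh on every run from the supplied seed.
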