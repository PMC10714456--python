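# Methods

## The problem

A survival prediction model deployed in a changing environment — event
rates drifting, new treatments rolling out, the patient mix shifting —
loses calibration and, when new predictors appear, discrimination.
`dynasurv` implements and evaluates strategies for keeping such a model
current by repeated (dynamic) updating: data arrive in quarterly batches
`D_1, D_2, ...` after a development dataset `D_0`; in each period the
current model is first evaluated out of sample on the incoming quarter and
then updated with it, so that the model evaluated on `D_{u+1}` was last
updated with `D_u`.

## Models

The deployed model is a Cox proportional-hazards model

    h_i(t | x_i) = h0(t) exp(beta' x_i),

with survival predictions `S_i(t) = exp(-H0(t) exp(beta' x_i))`, where
`H0` is Breslow's estimate of the cumulative baseline hazard. Analysis
time is months since the subject's own entry; each period's dataset is
self-contained after its time origin has been reset to the period start.
Ties are handled by Breslow's method by default (Efron available), which
keeps the fit consistent with the Breslow baseline and with the
grid-search partial-likelihood oracle used in the tests.

Three update operators act on a fitted model:

* **Intercept recalibration** re-estimates the baseline hazard on the new
  quarter only, holding the log hazard ratios fixed: a Cox model with the
  frozen linear predictor as its only covariate and coefficient fixed at
  1, which reduces to the Breslow estimator with fixed offsets. It cannot
  change the ranking of subjects, hence leaves the C-index exactly
  unchanged, and cannot absorb new predictors.
* **Refitting** discards the old model and fits afresh on the new quarter
  only. A feasibility rule guards the small-sample case: the refit is
  abandoned (and the previous period's model retained, with a flag) when
  any covariate lacks variation, any binary covariate level carries zero
  events, the optimiser fails to converge, or the fitted log hazard
  ratios / standard errors exceed 20 in magnitude — the signature of
  separation with too few events.
* **Bayesian dynamic updating** assumes exponentially distributed survival
  within the period: `T_i ~ Exp(exp(omega_i))`, `omega_i = lambda_u +
  beta_u' x_i`, with priors `beta_u ~ N(beta_{u-1}, Sigma_{u-1}/xi)` and
  `lambda_u ~ N(0, sigma_lambda)`. The forgetting factor `xi` in (0, 1]
  inflates the carried-forward covariance so older information is
  down-weighted; coefficients absent from the previous model get
  independent N(0, 2.5) priors. Point estimates are posterior medians;
  predictions average `exp(-t e^omega)` over the posterior draws. The
  first update takes its priors from the Cox development fit (flagged,
  since those coefficients were estimated under a non-exponential
  baseline; with genuinely exponential data the two coincide
  asymptotically).

### Posterior computation

The posterior is log-concave (exponential log-likelihood plus Gaussian
priors). Each chain is an independence Metropolis–Hastings sampler whose
proposal is a multivariate Student-t (7 degrees of freedom, covariance
inflated by 1.2) centred at the posterior mode found by BFGS with the
analytic gradient; the curvature at the mode supplies the proposal
covariance. On typical period datasets this accepts ~75–85% of proposals
and delivers effective sample sizes above two thirds of the draw count.
Two (configurable) independent seeded chains are run so split-Rhat
applies; convergence requires Rhat < 1.1 for every parameter, with an
optional Monte-Carlo-standard-error criterion (MCSE below a configurable
fraction of the posterior SD). A non-converged update is discarded and
the previous period's model retained, mirroring the refit fallback.
Default settings are 2 chains of 7500 iterations with 1000 burn-in; the
test suite and acceptance script use 1200–1500 iterations, which the
diagnostics show is ample for this posterior.

## Performance assessment

All metrics are computed out of sample at the prediction horizon `v`
(3 months) and handle censoring by inverse-probability-of-censoring
weighting, with `G` the Kaplan–Meier estimator of the censoring
distribution on the evaluation cohort (covariate-independent, left
limits in the weights, weights truncated at `G < 0.01` with a logged
count):

* **IPCW C-index**: over pairs with `T_i < T_j`, `T_i <= v` and an event
  for i, the weighted (by `1/G(T_i-)^2`) proportion in which the model
  assigns i the higher risk; score ties count 1/2.
* **IPCW Brier score** (Graf): `mean[ S_i^2 1(T_i<=v, event)/G(T_i-) +
  (1-S_i)^2 1(T_i>v)/G(v) ]`.
* **Weak calibration** via log-link event-count regressions: the
  intercept from a Poisson model of the event indicator with
  `log Lambda_i` as offset (`Lambda_i` the predicted cumulative hazard at
  `min(T_i, v)`), and the slope from a regression on the linear predictor
  with the baseline cumulative hazard as offset. Targets are 0 and 1.
  Predicted cumulative hazards are floored at 1e-8 (a Cox baseline is
  exactly zero before its first jump) and capped at 1e8.

## The synthetic cohorts

Covariates: age in decades `x1 ~ U(1.8, 9.5)`; a biomarker
`x2 ~ N(1, 1)`; a binary comorbidity `x3` with constant prevalence 0.05,
except in the rare-risk-factor scenario where prevalence follows a
logistic model in age (slope 1 per decade) calibrated so 1% of over-55s
carry it; and, in treatment scenarios, a treatment `x4` introduced in Q2
and opened to ages 75+ first, the threshold dropping 10 years per
quarter, with 80% uptake among the newly eligible each quarter (in the
comorbidity variant, `x3 = 1` also confers eligibility). Default log
hazard ratios are 0.35, 0.3, 0.8 and −1.0. Event times are exponential;
the log baseline hazard of each period is solved numerically (bisection
against a 200,000-draw fixed sample of the covariate law) so the
marginal 1-year event probability hits the scenario's target path —
constant 5%, drifting 5%→2% or 5%→8%.

Two data-arrival frameworks:

* **Cohort with replacement**: a standing cohort of 10,000 followed
  through five quarters; a subject with an event is replaced by a fresh
  entrant at the start of the following month, and additional
  non-informative churn (random exits, also replaced) tops new entrants
  up to ~1,000 per quarter. Between quarters the clock is reset; within
  a quarter, mid-month entrants appear with delayed calendar entry but
  are analysed on their own time-since-entry scale (exact under the
  constant within-quarter hazard).
* **New cohorts**: three disjoint monthly waves of 1,000 fresh subjects
  per quarter, truncated at the quarter end, so the waves carry at most
  3, 2 and 1 months of follow-up — far fewer events per quarter, and a
  censoring distribution with mass at 1, 2 and 3 months.

The development dataset is always a single cohort of 10,000 censored at
12 months.

What the generator does **not** emulate: informative censoring, covariate
measurement error or drift in covariate distributions, non-exponential
(e.g. Weibull) event times, competing risks, and within-quarter hazard
changes. Passing tests therefore demonstrate the machinery and the
comparative behaviour of the updating strategies under proportional
hazards with known drift — not robustness to misspecified baselines or
real EHR data quality.

## Update schedules

Quarterly updating follows the evaluate-then-update cycle above. Ad-hoc
one-time updating emulates seven analysts choosing a single update time
in year 1 at fractions 0.0, 0.1, 0.25, 0.46, 0.5, 0.69, 0.75 of the
year: quarter-start analysts use the quarter of data ahead of them;
others use the trailing three complete months of accrued data (possibly
spanning a quarter boundary or reaching back into the development year).
Trailing windows are assembled by clipping each stored record to the
calendar window — events outside the window become censorings at the
clip boundary — which is exact under the memoryless within-period
hazard. The updated model is deployed at the window end and evaluated on
every subsequent quarter.

## Reproducibility and problem sizes

All randomness flows from a single master seed through
`numpy.random.SeedSequence` spawn keys: replicate `i` derives its
generation stream and its per-update sampler seeds from
`SeedSequence(master, spawn_key=(i,))`, so any replicate can be re-run in
isolation and a full experiment replays bit-identically.

Generator defaults are the full study conditions (10,000 development
subjects, ~1,000 replacements or 3×1,000 monthly entrants per quarter,
600 replicates, ξ = 0.9). The test suite and the acceptance script run
the same pipeline at reduced scale — typically 20–100 replicates, with
some structural tests on cohorts of a few hundred — chosen so that each
directional effect they assert is well above its Monte-Carlo noise at
that scale. The treatment-introduction discrimination comparison is the
exception: its achievable C-index gain under the default parameters
(~+0.01 to +0.03) is small, so it is run at the full default cohort
sizes with reduced replication, and the refit-vs-no-update comparison is
asserted only in the replacement framework, where quarterly refits are
routinely feasible.

## Known limitations

* Exact per-scenario parameter values of the original simulation design
  are not public; the defaults here reproduce every pinned value (true
  comorbidity log-HR 0.8, 5%→2%/8% rate paths, cohort sizes, ξ = 0.9,
  N(0, 2.5) priors) and the qualitative findings, but absolute metric
  levels (e.g. the final-period C-index) are properties of these
  defaults.
* The Bayesian model's exponential baseline is correct for the generator
  by construction; with a non-constant true baseline the Cox-derived
  priors for the first update would be systematically misaligned.
* `sigma_lambda` defaults to 2.5 (vague on the log-hazard scale);
  extremely rare outcomes may warrant a wider choice.
* The ad-hoc trailing-window assembly splits a subject's follow-up into
  exposure intervals treated independently, which is exact for the
  exponential likelihood and an approximation for the Cox partial
  likelihood.
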