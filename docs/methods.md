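# Methods

This package implements the statistical machinery of a randomized,
embedded, multifactorial adaptive platform (REMAP) trial of pre-operative
pharmacologic conditioning in older elective-surgery patients: the ordinal
composite endpoint, the randomization scheme, the Bayesian primary
analysis with borrowing across doses and exposure durations, the
frequentist secondary/sensitivity/subgroup suite, and a Monte-Carlo study
of the design's operating characteristics. Because the motivating trial's
patient-level records are not public, every analysis here runs on a
synthetic cohort generator calibrated to the trial population's published
summary statistics.

## The endpoint

HFD-90 (90-day hospital-free days) is an ordinal composite on
{-1, 0, 1, ..., 90}: -1 for death intraoperatively or within 90
postoperative days, 0 for patients alive but hospitalized the entire
period, and otherwise the count of days alive and out of hospital.

Boundary conventions are fixed so the arithmetic is reproducible: day 0 is
the day of surgery; the scoring window is days [0, 90); a patient
discharged on day d is out of hospital from day d onward; readmission
intervals are half-open [start, end); the death day is never an
out-of-hospital day. Published descriptions of this endpoint do not state
these conventions; ours make an uncomplicated discharge on day 2 score 88.

## The synthetic cohort generator

The generator emulates the trial population:

* **Covariates.** ~90% of patients aged >= 60 (mean 68, SD 6), the rest
  younger with Charlson comorbidity index > 2 (the eligibility rule); 45%
  female; surgical strata spine/general/colorectal/other in a
  0.29/0.38/0.13/0.20 mix; planned pre-operative exposure windows short
  (7-28 d) / medium (29-90 d) / long (>90 d) in a 0.61/0.28/0.11 mix;
  three synthetic clinics.
* **Baseline outcome.** HFD-90 is a mixture: death mass `p_death` (0.010
  at the reference stratum), never-discharged mass `p_zero` (0.002), else
  90 minus the total in-hospital days, which are negative-binomial
  (mean 2.0, shape 0.7 at the reference stratum, truncated at 89).
  Spine and colorectal strata are worse and "other" slightly better than
  general surgery via cumulative-odds shifts (odds 5.0 / 5.0 / 0.8),
  consistent with the large stratum contrasts the trial reported. These
  four numbers were calibrated once against the analytic mixture quantiles
  so the pooled null cohort has median 88 and IQR (85, 90), the trial's
  observed distribution; they were not revisited afterward.
* **Events.** 90-day reoperation 13.5% and morbidity 22% (marginal, among
  operated patients); readmissions arise by splitting a patient's
  in-hospital days between the index stay and a later interval (conditional
  probability 0.20, inducing a ~10% marginal rate, inside the trial's
  9-12% band). Surgery occurs with probability 0.934 (20/302 enrollees
  never reached the operating room).
* **Compliance.** Nonadherence 18.4% marginal, of which withdrawal 6.7%;
  withdrawal implies nonadherence; independent of arm by default (the
  trial found no dose or duration dependence).

**Treatment effects are exact proportional-odds shifts.** An arm with
proportional-odds ratio `por` (orientation: >1 = higher odds of *fewer*
hospital-free days, i.e. worse) has its baseline cumulative distribution
shifted by that constant odds ratio and the outcome drawn by inverse
transform. Stratum differences are also cumulative-odds shifts, so the
analysis model below is exactly correctly specified on generated data and
parameter-recovery experiments are interpretable. What the generator does
**not** emulate: non-proportional treatment effects, site effects on
outcome, informative nonadherence, out-of-system hospitalizations, or
calendar-time drift — so green tests here demonstrate correctness of the
machinery under the design's own assumptions, not robustness to their
violation.

## Randomization

Placebo and three daily doses (500/1000/1500 mg) are allocated
sqrt(3):1:1:1 — the square-root rule for k active arms against a shared
control — stratified by clinic, age category, and duration stratum.
Since sqrt(3) is irrational, permuted blocks use the rational
approximation 7:4:4:4 (block size 19; |7/19 - 0.36603| < 0.003); simple
weighted draws are a config option. At each interim, doses meeting the
futility or inferiority rule drop to zero weight permanently; surviving
doses are re-weighted proportional to P(best)^0.5 (exponent configurable)
and placebo is held at sqrt(3) times the mean active-dose weight so the
comparator keeps accruing information. After a weight change, open blocks
are discarded and new block compositions come from largest-remainder
apportionment of the updated probabilities.

## The Bayesian primary model

A cumulative-logit (proportional-odds) model on the ordinal endpoint,
ordered worst to best:

    logit P(Y_i <= k) = gamma_k + lambda_{s(i)} + theta_{a(i)}

with ordered cutpoints gamma, surgical-stratum fixed effects lambda
(reference: first stratum present), theta = 0 for placebo, and a 3 x 3
hierarchical treatment grid

    theta(d, u) = mu + alpha_d + beta_u + eps_{d,u}
    alpha_d ~ N(0, tau_alpha^2),  beta_u ~ N(0, tau_beta^2),
    eps_{d,u} ~ N(0, tau_eps^2),  tau ~ Half-Normal(0.5),  mu ~ N(0, 1).

exp(theta) is the proportional odds ratio toward fewer hospital-free days
(mpOR > 1 = worse). The hierarchy realizes "borrowing": as tau_eps -> 0
the nine cells collapse to an additive dose + duration structure, and
small tau_alpha/tau_beta pull everything toward the common effect mu.
Dose-level (and duration-level) contrasts are the cell effects averaged
with that arm's observed duration (dose) composition. Priors: N(0, 10^2)
on the first cutpoint, N(0, 1.5^2) on log cutpoint increments, N(0, 2^2)
on stratum effects. All scales are config values.

**Category grid.** The 92-category outcome is fit on a collapsed grid
(default: -1, 0, 5-day bins over 1-80, single days 81-90; 28 categories)
because cutpoints for nearly-empty categories are weakly identified at
trial-scale n; a full-resolution grid exists. Proportional-odds effects
are invariant to merging adjacent categories, so the collapse does not
bias the odds ratios. Categories unobserved in a dataset are dropped
before fitting.

**Engines.** Two posterior engines share one log-posterior with analytic
gradients:

* *Laplace* (default, used in the trial-simulation inner loop): L-BFGS-B
  finds the joint mode, a finite-difference Hessian of the analytic
  gradient gives the Gaussian approximation, and summaries come from draws
  of that Gaussian. The hierarchy log-SDs are bounded in [log 0.02,
  log 10] during optimization: the unbounded joint mode sits at tau = 0
  (the usual hierarchical funnel), which both distorts the mode and makes
  the Hessian numerically singular; with the bound, 95% intervals achieve
  ~95% coverage in recovery experiments. Bound-active log-SD coordinates
  are pinned in the Hessian (their spread is not of interest).
* *MCMC* (for spot-check fits): Hamiltonian Monte Carlo on the
  non-centered parameterization (v = tau * v_tilde, which bounds the
  funnel's density), whitened by the Cholesky factor of the Laplace
  covariance, 4 independent chains, step size adapted to ~80% acceptance
  during warmup with per-iteration jitter to break resonances.
  Convergence is gated at split-R-hat <= 1.05 and monitored on the
  quantities the results report — cutpoints, stratum effects, and
  data-informed cell effects. The internal split of a cell effect into
  mu/alpha/beta/eps is identified only through sums; its decomposition
  mixes slowly and is a prior-level nuisance, so it is summarized but not
  gated. A failed gate raises, with the draws attached for inspection.

**Decision rules.** Superiority: one-sided posterior probability of
benefit strictly greater than 0.975. Inferiority / futility: P(no
benefit) > 0.99 / > 0.95. Equivalence: posterior mass of the odds ratio
inside (1/1.25, 1.25) above 0.90. The trial printed only the 0.975
superiority rule; the other bounds (its statistical analysis plan is not
public) are config values with these defaults. Statuses are mutually
exclusive with precedence superior > inferior > futile > equivalent >
continue.

**Model checking.** A posterior-predictive exceedance check compares
observed versus predicted P(Y >= k) per arm — the practical check of the
proportional-odds assumption.

## Frequentist suite

Binary 90-day endpoints: univariable logistic regression (Wald 95% CI;
Haldane-Anscombe 0.5 correction for zero cells, flagged). Time-to-event:
Cox proportional hazards with Efron ties plus Kaplan-Meier curves,
administrative censoring at day 90, withdrawn patients excluded (a
censor-at-withdrawal switch is the alternative). Continuous endpoints:
OLS with identity link. The frequentist sensitivity analysis of the
primary endpoint is a maximum-likelihood cumulative-logit fit reported on
the *more*-HFD orientation (OR > 1 = benefit) — the reciprocal of the
Bayesian convention, and the two multiply to ~1 on shared data.
Significance is one-sided p < 0.025 in the prespecified benefit
direction. Subgroup analyses (age median split, sex, frailty, stratum,
operative stress) reuse the pooled contrast within each level, carry no
multiplicity adjustment, and are flagged exploratory.

Contrast sets: pooled treatment vs placebo, by dose, by duration, and
low-dose-short vs all other treatment combinations.

## Trial simulation and operating characteristics

One replicate simulates the design end to end: enrollment at 20
patients/week; sequential stratified randomization; outcomes revealed only
90 days after each patient's surgery (patients without complete follow-up
at an interim date contribute nothing to that interim — the conservative
information rule, since the trial did not publish its own); analyses at
every 500th enrollment, the last at the 2500 cap on complete data.  At
each analysis the hierarchical model is fit (Laplace engine by default)
and doses classified; a dose crossing the superiority bound ends the
platform with that winner (if several cross, the one with the highest
P(best)); futile/inferior doses drop from randomization permanently; if
all doses drop the platform stops for futility. Skipped analyses (fewer
than 100 complete outcomes) are recorded as such.

Operating characteristics aggregate independent replicates (child seeds
spawned from one master seed; byte-identical reruns): power = fraction of
replicates declaring the scenario's truly best dose superior, type-I
error = fraction declaring any dose under the null, plus expected sample
size and arm-selection frequencies, each with binomial Monte-Carlo
standard errors.

**Scenario presets.** "uniform-15": one dose (1000 mg by convention)
carries the design's maximal effect in all three durations;
"no-short-effect": the same effect in medium and long only; "null". The
maximal effect is operationalized as proportional-odds ratio 0.85 toward
fewer HFD — the beneficial reading of a "15% improvement in the odds of
more hospital-free days" (descriptions of such designs phrase the 15%
both as improvement and reduction; the beneficial reading is adopted and
the magnitude is a config value). The cap is 2500 with 2000 available as
an alternative.

**A note on attainable power.** With an ordinal endpoint the asymptotic
variance of a cumulative-logit log odds ratio is bounded below by
3 (1/n_1 + 1/n_2) (it equals 3 (1/n_1 + 1/n_2) / (1 - sum_k p_k^3) for
category probabilities p_k). At a 2500-patient cap, even a perfectly
balanced two-arm single-look comparison therefore has se(log OR) >= 0.069,
so a por of 0.85 (log = -0.163) yields one-sided-0.975 power of at most
~65%; the actual design — sqrt(3)-weighted placebo, three dose arms,
hierarchical shrinkage toward the two null doses, and the interim
information lag — measures well below that (the acceptance script prints
the honest Monte-Carlo value, typically ~20-30% for the uniform preset at
these settings). Published power figures in the 80s for designs of this
shape imply a larger effect size, laxer bounds, or a different effect
definition in their (unpublished) analysis plans; no generator
calibration can close an information-theoretic gap, and none was
attempted.

## Simulation sizes and numerical choices

Default posterior summaries use 2000-4000 draws. The acceptance script
runs 200 replicate trials per power scenario; the test suite uses 40-60
replicates for stochastic checks and 50 for coverage experiments, sizes
chosen so binomial Monte-Carlo error is explicit in each assertion.
Likelihood evaluations collapse data to (stratum, arm, category) counts,
making a full 2500-patient fit a few hundred microseconds per
gradient evaluation. Ties in the best-dose argmin resolve to the lowest
dose index (numpy argmin); probabilities are clipped at 1e-300 before
logs; logit arguments are clipped at |35|.

## Known limitations

* The Laplace engine's intervals are asymptotic-Gaussian; at very small
  interim information sets (n ~ 100) they are approximate, which is one
  reason interim dropping bounds are conservative defaults.
* R-hat for the MCMC engine is computed on reported quantities only (see
  above).
* The generator's negative-binomial stay-length shape is a calibration
  convenience; only its induced HFD-90 quantiles are tied to published
  numbers.
* Equivalence/futility/inferiority bounds are package defaults, not the
  trial's unpublished values; operating characteristics depend on them.

## Appendix: column dictionary for generated tables

`spry generate` writes one row per patient with:

| column | meaning |
|---|---|
| `patient_id` | opaque identifier |
| `age`, `cci`, `sex` | years; Charlson comorbidity index; female/male |
| `stratum` | surgical stratum: spine / general / colorectal / other |
| `frailty_category` | not-frail / pre-frail / frail |
| `operative_stress` | ordered 1-5 operative stress score |
| `clinic_id` | enrollment site |
| `planned_lead_time_days` | enrollment-to-surgery window (>= 7) |
| `arm`, `duration` | placebo or dose (mg); short / medium / long |
| `surgery_performed` | whether the operation happened |
| `discharge_day` | index-stay discharge (postoperative day; empty = never) |
| `readmission_intervals` | half-open day ranges, `s-e;s-e` |
| `reoperation_day`, `death_day`, `morbidity_day` | event days or empty |
| `adherent`, `withdrew` | compliance flags (withdrawal implies nonadherent) |
| `hfd90` | the ordinal endpoint, -1..90 (empty if no surgery) |
| `*_90`, `*_time` | 90-day secondary endpoint flags and event days |
| `index_los_days`, `censor_day` | index length of stay; censoring day |
| `excluded_from_tte` | withdrawn, hence excluded from time-to-event fits |
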