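# Methods

This document specifies the statistical model implemented by `pscox`, the
synthetic-data generator used to exercise it, and the numerical conventions
that fix otherwise ambiguous details.

## 1. Study design being modelled

A retrospective matched-cohort design on an insurance-claims database:

* **Exposed cohort** — men over 50 with at least two COPD diagnosis dates
  (ICD-9-CM 491/492/496) on or before the index date and at least three
  prescription claims for COPD pharmacotherapy inside a one-year accrual
  window (2004).  The index date is the first treated visit.  A 365-day
  washout (no COPD prescription in the year before index) enforces new-user
  status; persons with a prostate-cancer code (ICD-9 185) on or before index
  are excluded.
* **Comparison cohort** — 3:1 matched controls drawn without replacement
  from persons with no COPD claims, matched on sex and age band (51–60,
  61–70, >70) at the case's accrual year.  Controls inherit the matched
  case's index date and are subject to the same prior-outcome and enrolment
  checks; pool exhaustion in any stratum is an error, never a silent
  shortfall.
* **Follow-up** — from index until the earliest of the first prostate-cancer
  diagnosis (the event), disenrolment/death, or administrative closure
  (2008-12-31).  An outcome code dated on or before index is a consistency
  error at this stage because such persons must have been excluded upstream.

### Charlson comorbidity index

Fifteen comorbidity categories are detected by ICD-9 prefix matching on
diagnosis claims dated on or before index.  The default score is the
**unweighted count** of categories present (each contributes 1); classical
Charlson weights (2 for complicated diabetes, paraplegia, renal disease,
moderate/severe liver disease; 6 for metastatic carcinoma and AIDS) are
available as `CHARLSON_WEIGHTS`.  The unit-weight default was chosen because
it reproduces the reference cohort means (≈1.7 exposed, ≈1.2 unexposed)
implied by the comorbidity prevalence table this design emulates, which a
classically weighted score does not.

## 2. Two-stage propensity-score calibration

Covariates split into `E` (shared: age, CCI) and `M` (missing from the main
data: smoking, alcohol, BMI).  Scores:

* `PS  = Pr(D=1 | E)` — main study;
* `PS_c = Pr(D=1 | E)` — validation study (error-prone score);
* `PS_m = Pr(D=1 | E, M)` — validation study (gold standard).

All three are maximum-likelihood logistic regressions.  By default `PS_c` is
refit within the validation sample; `transport_ps=True` instead scores the
validation subjects with the main-study coefficients.

Stage 1 fits the main-study Cox model with the propensity score as a
continuous covariate:

```
H(t | D, PS) = H0(t) · exp(β·D + β_c·PS)
```

yielding the error-prone `(β̂, β̂_c)`.  Stage 2 fits, by ordinary least
squares in the validation sample,

```
E(PS_m | D, PS_c) = γ₀ + γ·D + γ_c·PS_c
```

and corrects

```
β* = β̂ − γ̂ · β̂_c / γ̂_c          (formula_mode="standard_rc", default)
```

**Derivation.**  Write the target model as `exp(β·D + β_m·PS_m)` and replace
`PS_m` by its conditional expectation: the fitted coefficients satisfy
`β̂ ≈ β + β_m·γ` and `β̂_c ≈ β_m·γ_c`, so `β_m ≈ β̂_c/γ̂_c` and subtracting
`γ̂·β̂_c/γ̂_c` removes the omitted-confounder term.

A second mode, `formula_mode="paper_literal"`, computes
`β* = β̂ − β̂_c·γ̂_c·γ̂` — multiplying where the calibration algebra divides.
It reproduces a published transcription of the correction formula verbatim;
the two modes coincide exactly when `γ̂_c = ±1` and are both tagged in every
result object so audits can tell them apart.  The standard form is the
default because it is the classical regression-calibration estimator;
`|γ̂_c| < 1e-6` is rejected as unidentified rather than divided through.

### Uncertainty

The calibrated estimator has no convenient closed-form variance, so the CI
and p-value come from a percentile bootstrap: the main cohort and the
validation sample are resampled independently, each within itself and at its
original size; replicate `j` uses `numpy.random.default_rng([seed, j])`, so
results do not depend on evaluation order.  With `B` replicates the 95%
interval is read off order statistics `ceil(0.025·B)` and `floor(0.975·B)`
(the 25th and 975th of 1000 sorted replicates).  The empirical two-sided
p-value for H0: effect = 0 is `2·min(#{β*≤0}, #{β*≥0})/B`, floored at `1/B`
and capped at 1; an add-one variant `(count+1)/(B+1)` is available.
Replicates on which an inner fit fails are dropped; more than 5% failures
aborts the interval, and `B < 40` is rejected outright because the 2.5%
order statistic degenerates.

### Assumptions and limitations

The correction is consistent when (i) the outcome model is linear in `PS_m`
on the log-hazard scale, (ii) the error model is linear, and (iii) the
error-prone score carries no outcome information beyond `(D, PS_m)`
(surrogacy).  When confounder effects on the outcome are not proportional to
their effects on the exposure logit — or the logistic response is strongly
curved over the score range — PSC under-corrects; the acceptance recovery
experiment therefore constructs a configuration in which these assumptions
hold (proportional effects, a single comorbidity channel, exposure
prevalence 0.5) and demonstrates both the bias reduction and near-unbiased
mean recovery.  Two further caveats apply generally: the hazard ratio is
non-collapsible, so marginal and conditional effects differ slightly even
without confounding, and the matched design (controls inheriting index
dates, age-band matching) changes the estimand relative to a random sample.

## 3. Medication-class analysis

Within the exposed cohort, prescriptions map to five inhaled classes (SAMA,
SABA, LAMA, LABA, LABA+ICS) plus co-medications (statin, aspirin, oral
steroid, NSAID); xanthines are oral bronchodilators and carry no inhaled
class.  Rules:

* a claim **qualifies** iff `days_supplied > 14` (strict);
* a person's class is the unique class with ≥3 qualifying claims in the
  first year after index (stationary-medication rule);
* two qualifying classes ⇒ combination user, excluded from the model;
* short-acting claims of ≤14 days held by a regular long-acting user are
  on-demand **rescue** use (flagged, not excluded); the leniency is
  one-directional — any long-acting claim held by a short-acting user marks
  a combination;
* unmapped drug codes trigger a warning and land in an `unclassified`
  bucket, never silently dropped.

The multivariable Cox model holds one indicator per inhaled class (persons
with no class are the implicit reference), the four co-medication flags, the
CCI and continuous age — eleven terms.  Zero-variance terms are dropped with
a warning.  An `accumulate_per_person` rule variant pools days supplied
across claims of a class before applying the 14-day threshold.

## 4. Synthetic-data generator

`SimulationConfig` defaults are calibrated to the study conditions the
package models: ~63,870 persons yielding ~12,400 treated COPD men over 50
with 3:1 matched controls, five-year maximum follow-up, prostate-cancer
incidence in the region of 630 vs 360 per 100,000 person-years, CCI means
≈1.7/1.2, and a validation survey of roughly 310 exposed / 800 unexposed
men carrying the lifestyle confounders.

Generation proceeds per person:

1. **Age** — three bands (51–60, 61–70, 71–85) with configured weights,
   uniform integer age within band.
2. **Lifestyle confounders** — smoking and alcohol as Bernoulli draws, BMI
   as a truncated normal; each has a log-odds effect on exposure and a
   log-hazard effect on the outcome.
3. **Comorbidities** — each category is drawn at its mixture-marginal
   prevalence `π·p₁ + (1−π)·p₀`; the implied log odds ratio
   `logit(p₁) − logit(p₀)` enters the exposure model, which reproduces the
   conditional prevalence pair to close approximation without conditioning
   the draw on the not-yet-drawn exposure.
4. **Exposure** — logistic in the confounder and comorbidity contributions;
   the intercept is solved numerically (Brent's method) so the population
   prevalence matches `copd_prevalence` exactly in expectation.
5. **Event times** — exponential with subject-specific rate
   `exp(log λ₀ + β·D + Σ effects·M + age and CCI terms)`; censoring uses an
   independent exponential withdrawal clock plus administrative closure.
6. **Claims materialisation** (`simulate_population`) — diagnosis claims,
   monthly prescription claims starting at index (capped so the third claim
   falls inside the accrual year), washout-respecting histories, stray COPD
   codes in the control pool, comorbidity claims, rescue/combination
   prescription patterns and an outcome diagnosis claim when the event is
   observable.  A configurable fraction of COPD persons violates one entry
   criterion at random.

All randomness flows through named child streams spawned from one
`SeedSequence`, so output is byte-reproducible and the draws for earlier
persons do not change when `n_persons` grows within a stream.  The hidden
truth (confounders, latent clocks, true exposure) is exported separately and
never joined into main-study tables; `simulate_cohort` omits the confounder
columns from the main table by construction and the calibration layer
refuses a main table that carries them.

## 5. Numerical conventions

* Cox fits use the partial likelihood via `statsmodels.PHReg`; ties use
  Efron's method by default (`breslow` optional).  Zero or negative
  follow-up times and zero-event datasets are errors.
* Follow-up of a same-day event is floored at half a day so durations stay
  positive.
* Logistic and OLS fits are maximum likelihood / least squares via
  statsmodels; non-convergence and perfect separation raise typed errors.
* Incidence rates are events per 100,000 person-years with
  365.25 days/year.
* Reported proportions and hazard ratios round **half-up** (1.625 → 1.63),
  matching epidemiological reporting conventions rather than banker's
  rounding.
* The chi-square test is the classical Pearson statistic without continuity
  correction.
* Cumulative-hazard curves are Nelson–Aalen estimates (via lifelines),
  exported as long-format tables for plotting elsewhere.
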