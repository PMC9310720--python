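# Methods

This note records the models, conventions and numerical choices behind
`mddburden`, in the order the pipeline runs.

## Data model

Seven CSV tables with declared schemas (see `mddburden.registry.SCHEMAS`):
persons, residency intervals, diagnoses, dispensations, procedures,
outpatient visits, inpatient stays, work-loss spells.  All dates are
ISO-8601 calendar dates without times; **every interval is half-open
[start, end)**.  Validation is strict by default (any invariant violation
raises, naming the column or pattern); lenient mode drops offending rows and
counts them per table.  Writing is canonical (fixed column order, ISO dates,
`%g` floats), so `write(load(x))` is byte-stable for canonical files.

Clinical concepts are defined by a YAML-overridable codebook of ICD-10/ATC
prefixes with optional exclusions (e.g. stress = F43 excluding F43.1).
Ranges like `F20-F29` expand to their ten 3-character prefixes at load time;
matching is prefix matching, mirroring hierarchical coding.  Quetiapine
counts as depression add-on therapy only when the prescribed daily dose is
strictly above 100 mg; dispensations without a recorded dose are excluded
from the add-on set (conservative — the augmentation dose cannot be
established).  Tablets convert to days of supply at one tablet per day
unless configured otherwise.

## Synthetic registry generator

The generator emulates the *structure* of a regional healthcare warehouse
linked to social-insurance data, not any region's joint distributions.  One
master seed; each person uses an independent substream keyed by
`(seed, person_index)`, so growing the population leaves existing persons'
records bit-identical.

Defaults are the study conditions the pipeline targets:

| parameter | default | meaning |
|---|---|---|
| `annual_mdd_onset_rate` | 0.0082 /py | incident-MDD onset rate |
| `sex_ratio_cases` | 0.632 | fraction of cases female (population 50/50) |
| `age_mean`, `age_sd` | 41.3, 19.4 y | age at the window midpoint, truncated 5–95 |
| `care_level_mix` | 0.682/0.273/0.046 | primary/psychiatric/other at onset |
| `episode_median_days`, `episode_sigma` | 398 d, 0.7 | log-normal true episode duration |
| `baseline_mortality_rate` | 5.4 /1000 py | control death hazard (constant) |
| `case_log_hr` | log 2.2 | hazard increment from onset |
| `dispensation_interval_days`, `tablets_per_fill` | 90 d, 100 | refill pattern |
| `max_event_gap_days` | 300 | cap on in-episode event spacing |
| `referral_propensity` | 0.138 | primary-onset cases with a psychiatric MDD contact in year 1 |
| `emigration_rate` | 0.012 /py | exponential residency termination |

Mechanics worth knowing:

- **Episodes.** Each case has a log-normal episode starting at a uniform
  onset within the inclusion window, with 30% recurrence after a > 400-day
  gap (keeping true episodes separable under the 365-day rule).  The
  diagnosis stream places a dx at onset, renewal-process interior diagnoses
  with gaps capped at 300 days, and a terminal dx at the episode end, so the
  stitching algorithm can recover ≥ 99% of true episode days and the KM
  median is identified.  Refills stop ~35 days before the episode end so the
  closing event is a diagnosis, not a fill (otherwise the supply extension
  would systematically inflate reconstructed durations — a real property of
  the episode proxy, but one that would confound duration-recovery tests).
- **Comorbidity ramp.** Case comorbidities are drawn within 5 years before
  onset with density ∝ (1 − back/5y)² (configurable power), giving the
  ≈ 2× rise in cumulative recorded prevalence over the final pre-index year;
  everyone also accrues flat background diagnoses.
- **Mortality** is piecewise exponential: constant baseline hazard, multiplied
  by `exp(case_log_hr)` from onset.  Deaths and emigration end residency and
  truncate all event streams; event days are emitted on an integer-day grid
  strictly inside the (rounded) residency interval.
- **Utilization / work loss.** Background physician visits, admissions and
  sick-leave spells accrue for everyone at control rates; cases get
  additional visits (+5.4/py), psychiatric admissions and sick-leave spells
  during episodes.  Work-loss spells are only generated for persons aged
  20–64 at spell start, matching the analysis filter.
- `simulate_survival` is the mortality submodel alone, vectorized: uniform
  7-year accrual with administrative censoring, 2%/yr emigration, exponential
  deaths — mean follow-up ≈ 3.3 years, ~2,800 deaths per 50,000 pairs.  It
  exists so hazard-ratio recovery can run at registry scale (100,000
  individuals in well under a second) without generating full event tables.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: age- and sex-dependent mortality, pre-index
elevation of utilization among future cases (prodrome), seasonality,
municipality-level heterogeneity, misclassified or missing codes, and any
dependence between matching variables and outcomes.  Recovery tests
demonstrate estimator correctness under the stated model, not robustness to
real-registry messiness.

## Cohort

- Index = first-ever MDD diagnosis date; persons whose first diagnosis
  precedes the inclusion window are never incident.
- Same-day diagnoses at several care levels: psychiatric > primary > other
  (specialist recording assumed authoritative; configurable).
- Age at index = floor((index − birth)/365.25) whole years; the matching
  caliper is |age difference| ≤ 2 whole years.
- Exclusion history = any psychosis/mania/bipolar/dementia code dated ≤
  index (full lookback, unlike the 5-year comorbidity description).
- Residency requirement = one merged residency interval continuously
  covering [index − 365 d, index].
- Control sampling is uniform within the stratum, with replacement across
  cases, from a pool pre-screened on the any-time rules (no depression,
  self-harm, or antidepressant record in the whole data window).
- Censoring = earliest of death, emigration (end of the residency interval
  containing the index, if before end of data), first post-index exclusion
  diagnosis, end of data (2018-12-31 by default).  Same-day ties resolve
  death > emigration > exclusion.  Matched controls are censored by the same
  rules from the case's index date.

## Episodes

The scan keeps an episode ongoing while the next day-event is ≤ G days after
the previous one (raw event dates; a variant measuring from supply-extended
ends exists behind `extended_gap_checks`, default off, since the source rule
is stated on recorded events).  Same-day events collapse to one day-event:
`has_diagnosis = any`, `tablets = max over same-day fills`; a mixed day uses
the dispensation for extension and still counts as a diagnosis for starting
episodes.  On closure by gap, a terminal dispensation extends the end by
min(ceil(tablets/tablets_per_day), 100) days.  An episode whose last event
lies within G of the data end cannot be distinguished from an ongoing one
and is flagged `open_at_data_end`; the duration analysis censors it at the
follow-up end.  Episode ends never exceed the data end.

Correctness is established two ways: hand-traced fixtures, and exact
agreement with an independent day-grid flood-fill oracle on 1,000 random
event streams per gap rule.

Kaplan–Meier estimation is delegated to lifelines (product-limit, Greenwood
variance, log-log pointwise bands, Brookmeyer–Crowley-style median CI)
behind `km_fit`; the package's contribution is the episode construction, not
the estimator.

## Trajectories

Calendar-month grid anchored on the index month (month 0 contains the index
date); months −12..+12.  A unit is one panel row, so a control matched to
two cases contributes twice, at two index dates.  At-risk in month m ⇔ the
month starts on or before the follow-up end.  Fractional supply days round
up (coverage-favouring).  Point series default to the at-risk denominator;
cumulative series default to the fixed full-panel denominator, which makes
them monotone by construction (with the at-risk denominator, censoring of
ever-treated persons can make the curve dip — both are exposed).
Comorbidity curves count a person from max(−12, month of first qualifying
diagnosis), qualifying = dated within 5 years before index through the end
of month +12; the month-0 value therefore matches a baseline table built
with the same lookback.

## Burden

Two window conventions coexist deliberately: monthly figures use calendar
months; annual summaries use day-based windows pre = [index−365 d, index),
post = [index, index+365 d).  Follow-up covers [index, follow_up_end]
inclusive; the post-index weight is followed days / 365 (365-day year by
default, configurable).  The pre-index window is fully observed by design
(the 12-month residency requirement).  Bed days are interval overlaps with
the window, so psychiatric + non-psychiatric = total exactly.  The estimator
is the linearized ratio form given in the README; its small-sample behaviour
(|bias| < 1%, 93–97% CI coverage at n = 1,000 over 500 replicates of Poisson
outcomes with Beta(5,1) weights) is verified in the suite.  Reported ratios
round half-up to one decimal.

## Mortality

Survival records: time = days from index to follow-up end, event = death as
the censoring reason; zero-length follow-up is clamped to 0.5 day rather
than dropped (logged in the record), so same-day deaths contribute.  With a
single binary covariate the partial likelihood's risk-set sums reduce to
per-group at-risk counts at each distinct death time; both Efron and Breslow
corrections are expanded per tie slot as A + B·e^β, giving exact analytic
gradient U = D₁ − Σp and information I = Σp(1−p), p = B·e^β/(A+B·e^β).
Newton–Raphson from β = 0 converges when the log-likelihood change is below
1e-9 (50-iteration cap); the fit agrees with `survival::coxph` (Efron, eps
1e-12) to ~1e-14 on random datasets with and without day-level ties.  A
monotone likelihood (all deaths in one group) is reported as a flagged
non-finite estimate.  The default model is unstratified, mirroring a crude
case-vs-control contrast; `fit_cox_stratified` conditions on matched pairs
as a sensitivity analysis.  Rates use 365.25-day person-years.

## Referrals

Timepoints at index + {0, 91, 182, 273, 365} days (quarterly, 3 months ≈
91.25 d rounded; configurable).  The state at a timepoint is the care level
of the latest depression event dated on or before it, after a canonical
(date, class, source, level) sort so record order never matters;
dispensations carry no care level and never change the state.  Once
censored, always censored; flow totals are conserved at every timepoint.
The "primary → psychiatric within year 1" share is event-based by default
(any psychiatric-level depression event in (index, index+365]); a
state-based variant using the four quarterly states is available.

## Problem sizes

The test suite simulates 4,000- and 20,000-person registries (shared
fixtures), 50,000-pair survival draws (20 replicates), 1,000 random episode
streams per gap rule, 500 estimator-calibration replicates at n = 1,000, and
one 20,000-person end-to-end determinism run — the full suite completes in a
few minutes on one CPU.  The acceptance script uses 50,000 pairs.  Duration
recovery uses onsets restricted to the first years of the window so that
right-censoring of episode durations stays below ~5%.

## Known limitations

- The episode construct measures healthcare contact spans, not symptom
  duration, and by design can only overestimate the latter.
- The supplement with the study's exact code lists is not public; the
  codebook defaults combine body-text codes with conventional ICD-10 choices
  for the comorbidity panel and are meant to be overridden per deployment.
- The generator's marginals are coarse (flat background rates, constant
  hazards); absolute utilization levels in synthetic output are indicative
  only, and only explicitly configured quantities should be compared against
  recovery targets.
- Monthly exposure denominators, supply rounding, and the 365- vs
  365.25-day year are documented choices where the underlying study is
  silent; all are configurable.
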