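# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions taken where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

Long-format daily diaries per patient: day index (0-based integers from
randomization; no calendar arithmetic), four ordinal symptom items
(dyspnea 0–4, cough 0–3, sputum 0–3, nocturnal awakening 0–4), up to three
morning PEF attempts (l/min; the daily value is the best of the attempts),
and salbutamol puffs/day. Episodes carry onset day, end day and severity
(moderate = oral corticosteroid course, severe = hospitalization); episodes
of one patient never overlap. Baseline tables include the ten CCQ items
(0–6); the CCQ total is the mean of all ten items, with the standard domain
map (items 1, 2, 5, 6 symptom; 3, 4 mental; 7–10 functional) configurable.

A *properly scored* day requires all four symptom items; missing PEF or
salbutamol does not disqualify a day, because the completeness filters
concern the symptom diaries while PEF is analysed as its own signal. Days
with partial symptom entries are excluded wholly from weekly means rather
than contributing partially. Missing values are empty CSV cells, never
numeric sentinels.

## Course profiling

Eligibility for onset-aligned profiling of the first episode: ≥50% proper
days in relative days −28..−1 **and** in 0..55, and no second onset within
relative days 1..56 (such episodes are treatment failures). Exclusions carry
reason codes (`out_of_window`, `treatment_failure`, `incomplete_diary`), in
that precedence order.

Week boundaries: week 1 = relative days 0..6 (the onset day belongs to the
acute phase), …, week 8 = days 49..55; baseline week −4 = days −28..−22. A
patient-level weekly mean needs ≥4 of 7 proper days (the global filter is
50%; the per-week threshold is our choice for a defined mean). Group
contrasts are two-sided paired t-tests on patient weekly means (Wilcoxon
signed-rank available), patients contributing both weeks; fewer than two
pairs gives an undefined p; identical pairs report p = 1. No multiplicity
adjustment across the eight weekly tests — raw per-week p-values are the
output.

**Recovery week** = smallest w such that no week in w..8 is significantly
*worse* than week −4 — elevated for symptoms/salbutamol, depressed for PEF.
Direction matters: a week significantly *better* than baseline does not
block recovery, since the quantity of interest is persistence of
exacerbation-related worsening. A week with an undefined p cannot certify
recovery (every w at or below it is ineligible). Signals significant in the
worse direction at week 8 are "not recovered by week 8" (rank 9 for
ordering purposes).

This estimator is deliberately strict and therefore sensitive to isolated
late false positives: one falsely significant null week (probability ≈
α/2 per week in the worsening direction) inflates the estimate past that
week. With, e.g., a true recovery week of 4 there are five null weeks, so
the estimate exceeds 4 in roughly 1 − 0.975⁵ ≈ 12% of cohorts even with a
perfect implementation; the replicate experiments in the acceptance tests
must be read with this property in mind. We keep the strict definition
because a "recovered" label should certify that *all* later weeks are
clean.

Episode-class comparisons (first vs second moderate, severe vs moderate)
use patient-level means over the pre period (days −28..0, 29 days) and post
period (days 1..56): paired tests for first-vs-second over patients with
both; Welch's two-sample test for severe-vs-moderate pre-period means
(pairing is impossible — few patients have both a severe and a moderate
episode); no severe post-period comparison (diaries are largely missing
after hospitalization).

## Window score and hazard model

Score at day t = mean(signal, days t−7..t−1) − mean(signal, days t−14..t−8),
attributed to day t, so only strictly earlier data enter. A running-text
formulation with 6-day blocks would be internally inconsistent with the
worked arithmetic example (block means 10 then 13 → +3 at day 115); the two
7-day-block form is the one implemented. Blocks tolerate missing days
inside diary coverage, using the mean of available proper days with a
4-day minimum; the full 14-day window must lie inside the patient's diary
coverage (with a diary starting at day 1 the earliest defined score is day
15). For PEF the score is negated by default so that a positive score
always means deterioration.

The counting-process table has one row per at-risk patient-day with a
defined score; the event row is the first onset day; patients leave the
risk set at first onset or end of follow-up. Onsets before any defined
score contribute no event row (logged on the result). Whether risk sets
should include patients with undefined scores on a day is unknowable from
the analysis description; we exclude them that day.

The time-dependent Cox fit maximizes the day-wise partial likelihood by
Newton–Raphson with step-halving; ties use Breslow by default (Efron
available — it matches `lifelines.CoxTimeVaryingFitter` to 1e-6, which
serves as an independent oracle in the tests, never as the implementation).
Standard errors are the inverse observed information at the maximum; Wald
95% CIs. A model whose covariates do not vary within any event-day risk set
is flagged non-identifiable and returned at β = 0. Change-bin relative
risks use indicator covariates for [1,2), [2,3), [3,∞) points against the
(−∞,1) reference; empty bins are dropped with a warning and reported NaN.

ROC evaluation is day-level: cases are the event rows, controls all other
at-risk rows (one could sample one control day per patient instead; we use
all person-days, matching the day-wise time-dependent framing). AUC is the
tie-corrected rank statistic, identical to the trapezoidal area under the
empirical curve; no CI is attached by default because day rows within a
patient are dependent (a patient-level bootstrap would be the right
resampling unit).

## Rate and duration models

Exacerbation counts per patient: Poisson GLM with log link and offset
log(person-years), person-years = followup_days/365.25. Rescaling exposure
units moves only the intercept. The intercept-only fitted rate equals total
events / total person-years exactly. The CCQ enters as the total score by
default; with `ccq="domains"` the three domain means are fitted jointly and
the smallest-p domain is retained in a refit — our reading of an
under-specified stepwise procedure. The Pearson dispersion statistic is
reported alongside the fit because the Poisson assumption may not hold in
real cohorts.

Episode durations (end − onset + 1 days): linear mixed model on log
duration with a patient random intercept (patients contribute several
episodes; the random intercept is the minimal structure consistent with
that), severity plus baseline covariates as fixed effects, REML via
statsmodels MixedLM. When every patient has one episode the variance is
unidentifiable and the model falls back to OLS with the variance pinned at
0 (warned). Effects are reported multiplicatively; pack-years additionally
as exp(5b) per 5 pack-years. Empirical geometric means per severity are
reported next to the adjusted severity ratio because covariate adjustment
and truncation by follow-up can make the two differ.

## Synthetic cohort generator

The generator is the package's verification instrument: it emulates the
structure the analyses assume, with known ground truth stored in a truth
record.

* **Baselines.** Per-patient latent baselines per signal, drawn from normal
  distributions centred at stable-phase values typical of a moderate-to-
  severe COPD trial population (dyspnea 1.5, cough/sputum 1.1, nocturnal
  0.3, salbutamol 1.5 puffs, PEF 279 l/min) with between-patient SDs of
  0.5–1 score points (45 l/min for PEF).
* **Daily noise.** Stationary AR(1) with lag-1 correlation 0.5 and marginal
  SDs of 0.6–0.8 latent points (15 l/min PEF). The autocorrelation is
  essential realism: with iid noise the two-week change score is far too
  narrow (no days in the upper change bins, day-level AUC near 1 for
  moderate effects), whereas persistent day-to-day symptom drift yields a
  realistic score spread and AUCs in the 0.6–0.7 range.
* **Episode bump.** Latent course addition: linear rise from 14 days before
  onset, reaching 1/3 of the peak 7 days before, steeper linear rise to the
  full peak amplitude (default 1 latent point per symptom; −20 l/min PEF)
  at day 0, then square-root decay reaching exactly zero at day
  7·(recovery_weeks − 1), so the mean course is flat from the configured
  recovery week on. Defaults: cough/sputum 4, salbutamol 6, dyspnea 7,
  nocturnal 8, PEF 2 weeks. The decay form is a design choice — only
  significance-based recovery times, not functional forms, are identified
  by the weekly analysis; square-root decay keeps the last elevated week
  clearly detectable. Severe episodes add one extra latent point (10 l/min
  PEF) before onset. Each patient reuses one jittered amplitude multiplier
  (lognormal, σ = 0.1) across episodes — an assumption standing in for the
  unknown within-patient correlation of episode shapes.
* **Discretization.** Round-and-clamp of the latent value onto each ordinal
  scale — the simplest mechanism that produces bounded, realistic mean
  curves. PEF attempts are the latent value plus attempt noise (SD 8);
  salbutamol rounds to non-negative puffs.
* **Missingness.** Whole-day, completely at random (default 5%). Real
  diaries are plausibly missing-not-at-random around severe episodes; this
  generator does not model that, so passing tests certify the estimators
  under MCAR only.
* **Shape mode** schedules one or more episodes per patient (onsets uniform
  in days 42–84, subsequent episodes ~150 days apart) with the full
  pre+post bump. It is the ground truth for profiling tests.
* **Hazard mode** draws each day's onset from
  p_t = 1 − exp(−h0·exp(β_true·s_t)), where s_t is the *observed* window
  score (0 while undefined) computed exactly as the analysis computes it —
  so the fitted Cox model is well-specified with known β. Defaults
  h0 = 0.004/day (≈1.5 exacerbations/patient-year) and β_true = 0.5.
  Crucially, the episode bump is applied only from the onset day onward in
  this mode: a retroactive pre-onset prodrome would decouple the realized
  hazard from the covariate the analysis sees and bias β̂ upward (the
  pre-onset rise instead emerges endogenously, because onsets
  preferentially follow chance upward drifts). Onsets are blocked during an
  episode and, by default, for 56 days after an onset (configurable off).
* **Durations.** Log-normal, median 10 days moderate, ×1.62 severe, σ =
  0.55 on the log scale, a patient random intercept (SD 0.3) for the mixed
  model to estimate, rounded and clipped to 2–119 days. Episodes are
  truncated at end of follow-up; duration analyses aiming at unbiased
  recovery should use configurations where episodes fit inside follow-up.

Determinism: identical (params, seed) reproduce byte-identical outputs; all
randomness flows from one `numpy` Generator.

## Experimental conditions in the acceptance tests

Replicate experiments use the generator defaults above at the following
problem sizes, chosen to give the estimators adequate power while keeping
the suite quick: estimator bias/coverage at n = 500 patients × 365 days,
200 replicates; type-I calibration at n = 200 × 365, 800 replicates;
recovery-week ordering at n = 150 × 180 days, 100 replicates; change-bin
monotonicity at β_true = 1.0 (chosen by power analysis: at β = 0.5 the top
bin holds too few events for stable bin-wise estimates).

## Known limitations

* The profiling stage is purely empirical (means and paired tests); no
  trajectory model, no imputation.
* The recovery-week estimator's false-positive sensitivity (above) means
  replicate-level orderings of estimated recovery weeks hold in roughly
  85–90% of cohorts at n = 150, not always.
* Day-level ROC treats patient-days as exchangeable; dependence within
  patients is acknowledged but only addressed by the optional
  patient-level bootstrap.
* The Poisson rate model reports, but does not correct for,
  overdispersion.
* The generator's MCAR missingness and single-bump episode shape are
  simplifications; conclusions about real diary data are correspondingly
  qualified.
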