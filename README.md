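# exaflare

Course profiling and day-level prediction of COPD exacerbations from daily
symptom diaries.

Patients with moderate-to-severe COPD keep daily record cards: four ordinal
symptom scores (shortness of breath 0–4, cough 0–3, sputum 0–3, nocturnal
awakening 0–4), three morning peak-expiratory-flow (PEF) attempts, and rescue
salbutamol use. Around an exacerbation these signals rise for about two weeks,
spike in the final week before the onset, and return to baseline at
signal-specific rates over the following weeks. `exaflare` implements the two
analyses this structure invites, plus the synthetic cohort generator needed to
verify them end to end:

1. **Onset-aligned course profiling.** Eligible first episodes (≥50% properly
   scored diary days in the 4 pre-onset and 8 post-onset weeks, no new
   exacerbation within 8 weeks) are aligned at relative day 0. Each post-onset
   week *k* (days 7(k−1)..7k−1) is compared against the stable baseline week
   −4 (days −28..−22) with a paired test on patient-level weekly means; the
   *recovery week* of a signal is the first week from which no later week is
   significantly worse than baseline.

2. **Moving-window prediction.** The change score at day *t* is the
   difference of two moving weekly averages,

   ```
   s(t) = mean(x over days t−7 .. t−1) − mean(x over days t−14 .. t−8),
   ```

   computed for every patient-day (a mean of 10 points over days 101–107 and
   13 over days 108–114 scores +3 at day 115). The scores enter a Cox model
   as a time-dependent covariate over day-wise risk sets, with data used only
   up to the first exacerbation:

   ```
   λ_i(t) = λ0(t) · exp(β · s_i(t))
   ```

   fitted by Newton–Raphson on the Breslow (or Efron) partial likelihood.
   The same day-level table yields relative risks by change bin (<1 point
   reference, 1–2, 2–3, >3) and ROC curves whose AUC is the tie-corrected
   rank statistic — the probability that a randomly chosen onset day scores
   above a randomly chosen non-onset day.

Supporting models: Poisson regression of annual exacerbation rates on
baseline covariates (FEV₁ %predicted, age, sex, smoking, CCQ) with a
log person-years offset, and a linear mixed model on log episode durations
with a patient random intercept.

## Worked example

Profile a shape-mode cohort (150 patients, one scheduled episode each, true
recovery weeks cough/sputum 4, dyspnea 7, nocturnal 8, PEF 2):

```
$ exaflare simulate --seed 1 --out demo/cohort
wrote 51996 diary rows, 150 episodes, 150 patients to demo/cohort
$ exaflare profile --diary demo/cohort/diary.csv --episodes demo/cohort/episodes.csv --out demo/profile
profiled 150 eligible first episodes -> demo/profile
$ cat demo/profile/recovery_weeks.csv
signal,recovery_week
dyspnea,7
cough,4
sputum,4
nocturnal,8
total,7
pef,2
salbutamol,7
```

The estimated recovery weeks reproduce the generator's ordering: cough and
sputum settle by week 4, dyspnea by week 7, nocturnal awakening last, and
PEF is back within 2 weeks.

Predict onsets in a hazard-mode cohort, where each day's onset probability is
`1 − exp(−h0·exp(β_true·s(t)))` with β_true = 0.5 (true RR per point
e^0.5 ≈ 1.65):

```
$ exaflare simulate --config cohort.yaml --seed 1 --out demo/hz     # mode: hazard
wrote 103966 diary rows, 373 episodes, 300 patients to demo/hz
$ exaflare predict --diary demo/hz/diary.csv --episodes demo/hz/episodes.csv --signal total --out demo/predict
total: RR per point = 1.80 (95% CI 1.57-2.06), AUC = 0.645, 216 events over 51977 patient-days
$ exaflare rates --patients demo/hz/patients.csv --episodes demo/hz/episodes.csv --out demo/rates
{
  "annual_rate_intercept": 1.29,
  "geometric_mean_moderate_days": 9.91,
  "geometric_mean_severe_days": 18.07,
  "severity_ratio_adjusted": 1.83,
  "random_intercept_var": 0.109,
  ...
}
```

The fitted relative risk per point of two-week change covers the generating
value; the day-level AUC of ~0.65 shows the realistic situation in which a
strongly significant hazard ratio still gives only moderate discrimination.
The annual rate (1.29/patient-year) and the moderate/severe geometric-mean
durations (9.9 vs 18.1 days) recover the generator's settings.

The same commands run on any diary/episode/patient CSVs in the documented
dialect (see `docs/methods.md` and the module docstrings).

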