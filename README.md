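# chronomeal

Validating self-declared meal schedules against continuous glucose
monitoring (CGM) and wrist-worn circadian monitoring.

## The problem

Chrononutrition needs reliable timestamps for eating occasions under
free-living conditions, but self-declared meal logs have never been easy to
audit. Because a meal is normally followed by a postprandial glycemic
excursion, an interstitial glucose trace provides an objective physiological
check: if someone says they ate at 14:30, a glucose peak should appear
within the next two hours. `chronomeal` implements that validation pipeline
for cohorts wearing a CGM sensor, a wrist device recording movement
intensity (MI) and distal skin temperature (DST) with an eating-event
marker button, and a smartphone app for prospective/retrospective meal
annotation.

## What it computes

- **CGM summary** per participant on 5-min epochs: mean glucose, CV,
  time in range (70–180 mg/dL) and MAGE (mean amplitude of glycemic
  excursions), with a normal/flagged glucose-status screen.
- **Excursion peaks** via the MAGE moving-average algorithm: centred moving
  averages of 5 and 32 epochs segment the trace at their crossings, each
  segment contributes a raw local extremum, and a nadir→peak pair qualifies
  when its amplitude ≥ 1 × SD of the trace.
- **Annotation cleaning**: within-source deduplication (gap ≤ 15 min),
  app↔wrist-marker coupling (|lag| ≤ 30 min, greedy one-to-one) with the
  coincidence rate, and exclusion of events lacking postprandial glucose
  coverage.
- **Peak-related accuracy**: each app annotation is linked to its nearest
  subsequent unclaimed glucose peak; the per-meal-type percentage of
  annotations whose peak lies within 2 h, `100 · n_linked / n_total`.
- **Window analysis**: meal-anchored 2-h postprandial stacks and
  peak-anchored zeitgeber-time stacks (−1 h … +2 h, ZT = 0 at the glucose
  peak) of glucose, MI and DST, with mean ± SEM curves, trapezoidal AUC and
  pre/post-peak contrasts.
- **Inference**: Shapiro–Wilk normality screen, Wilcoxon signed-rank for
  paired contrasts (exact null up to n = 25), Friedman omnibus with tie
  correction and Bonferroni-corrected pairwise post hocs.
- **Synthetic cohorts** with full ground truth (true meal times, true
  excursion lags/amplitudes) so every stage has a recoverable target; see
  `docs/methods.md` for the generative model.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/03_meal_accuracy.py` simulates five participants for a
week, cleans their annotations and links meals to detected peaks:

```
KE-KW coincidence: 79.1% (110/139 app annotations confirmed by a wrist press)

peak-related accuracy:
meal_type  n_linked  n_total  accuracy_percent
breakfast        33       33             100.0
    lunch        35       35             100.0
   dinner        30       30             100.0
    snack        20       36              55.6
  overall       118      134              88.1

lag between annotation and its glucose peak (linked events):
meal_type  n  mean_lag_min  sem_lag_min
breakfast 33         42.85         2.31
    lunch 35         49.20         2.85
   dinner 30         47.07         3.79
    snack 20         50.75         5.17
```

Main meals reach high accuracy because their excursions clear the 1-SD
threshold; snack excursions are smaller and often go undetected, so snack
accuracy is markedly lower. Linked lags recover the generator's
excursion-lag means (41.5/48.4/47.0 min for breakfast/lunch/dinner).

The same analysis runs from the shell on files in the three supported text
dialects (glucose CSV, ACM epoch table, meal log):

```bash
chronomeal simulate --out cohort/ --seed 1
chronomeal run --in cohort/ --out report/ --seed 1
chronomeal report --in report/
```

`run` writes `participants.csv`, `accuracy.csv`, `lags.csv`, `curves.csv`,
`stats.csv` and a stage-by-stage `run.log`; identical seeds give
byte-identical bundles.

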