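# Methods

## Overview

`chronomeal` asks a simple physiological question of a meal diary: is each
declared eating occasion followed by a glycemic excursion? The pipeline
couples three data streams recorded on the participant's own wall clock —
interstitial glucose (native 60 s cadence, analysed at 300 s epochs), wrist
actimetry in 30 s epochs (movement intensity MI in G/epoch, distal skin
temperature DST in °C, three light channels, an event-marker button), and a
meal log with meal type (breakfast/lunch/dinner/snack) and entry mode
(prospective/retrospective). Timestamps are timezone-naive throughout; the
study design synchronises all devices to the phone clock, so the pipeline
never performs zone arithmetic.

## Epoching and CGM metrics

Glucose is averaged into 5-min epochs on a midnight-anchored half-open grid
`[t, t+300 s)`; empty bins stay missing rather than being dropped, so
coverage is always explicit. Per participant we report mean glucose, SD,
CV = 100·SD/mean, time in range (fraction of epochs in 70–180 mg/dL, the
consensus CGM band) and MAGE. A glucose-status screen flags a participant
when mean > 108 mg/dL, CV > 36 % or TIR < 70 % (strict inequalities);
cohorts of healthy adults should classify as `normal`. Traces with fewer
than 3 well-covered days (≥ 90 % of epochs present) are computed anyway but
carry a low-coverage flag.

## Excursion detection

Peak calling follows the moving-average formulation of MAGE. On each
gap-free segment (gaps > 1 h split the trace; shorter gaps are bridged by
linear interpolation for the averages only):

1. compute centred moving averages of 5 and 32 epochs; the windows shrink
   **symmetrically** at the boundaries (half-width `min(h, i, n−1−i)`), so a
   linear trend equals its own average and produces no spurious boundary
   crossings — with one-sided shrinking a monotone ramp would generate a
   fake excursion spanning the whole segment;
2. cut the segment where the short average crosses the long one; each
   inter-crossing run contributes the raw-trace extremum of its sign (max
   where short > long, min below), so peak times coincide with the visible
   apex rather than a smoothed one;
3. pair consecutive nadir→peak extrema; a pair qualifies when its amplitude
   reaches `threshold_sd_mult` (default 1) × SD of the whole epoched trace,
   nights included.

MAGE is the mean qualifying amplitude (0 with a no-excursion flag when
nothing qualifies). Downward excursions are not analysed. A naive reference
implementation (`chronomeal.reference.turning_point_peaks`) enumerates all
turning points and iteratively merges the smallest sub-threshold swing —
the manual procedure the moving-average algorithm approximates; when a
sub-threshold swing touches a trace boundary the more extreme endpoint
survives, so truncated excursions keep their apex. The test suite requires
the two routes to agree (peak times within ±1 epoch, qualifying-set Jaccard
≥ 0.9 over 20 one-day traces).

## Annotation cleaning and linkage

Within each source, annotations ≤ 15 min after the last kept one are
dropped, keeping the **earliest** event of a close cluster (the first bite
marks meal onset; the cleaning rule itself does not dictate a choice). App
(KE) and wrist-marker (KW) events are then matched one-to-one, greedily by
ascending |lag| within a 30-min window, ties to the earlier KW event; the
coincidence rate is coupled KE / total KE. Events whose 2-h postprandial
window has more than 20 % of epochs missing are excluded (the 20 % cut-off
is a project choice; the exclusion rule itself only states that events
without glucose are dropped).

Each surviving app annotation is assigned the nearest **subsequent**
unclaimed peak (strictly positive lag). A peak can validate at most one
meal, earliest-event priority — two annotations close enough to share an
excursion should already have been merged by deduplication, and exclusivity
prevents one excursion from vouching for both. A meal is *linked* when its
peak lies within `max_lag` = 120 min; unlinked events keep their candidate
lag for distance plots. Peak-related accuracy is the per-meal-type linked
percentage, half-up rounded to one decimal for reporting (raw fractions are
retained); lag summaries report mean ± SEM over linked events, with SEM
absent below n = 2.

## Window analysis

Stacks collect equal-length windows of one signal on a 5-min offset grid:
meal-anchored (0 → +120 min) for postprandial curves and peak-anchored
(−60 → +120 min) for zeitgeber-time architecture, ZT = 0 at the glucose
peak. ACM epochs are resampled to the grid by arithmetic mean; partial
boundary windows are padded missing and the per-offset n accounts for it.
Overlapping windows are all retained. AUC uses the trapezoidal rule over
0–120 min with interior gaps bridged linearly (mg/dL·min; a flat
100 mg/dL window gives exactly 12 000). Pre/post-peak contrasts average
offsets in [−60, 0) and (0, +120] per participant, the anchor sample
belonging to neither side.

## Inference

Shapiro–Wilk (α = 0.05) is logged but not acted on: the pipeline is
nonparametric throughout, matching cohort sizes of ~20 where normality of
every variable cannot be assured. Wilcoxon signed-rank drops zero
differences and uses the exact null distribution up to n = 25 tie-free
differences (the regime a 20-participant cohort actually exercises),
otherwise the tie- and continuity-corrected normal approximation; both
routes delegate to scipy. Friedman is computed in-package in the
tie-robust form

    χ² = (k−1) · [Σⱼ Rⱼ² − n²k(k+1)²/4] / [Σᵢⱼ rᵢⱼ² − nk(k+1)²/4]

because scipy's version omits the tie correction; identical columns give a
0/0 degeneracy reported as statistic 0, p 1. Post hocs are all C(k,2)
pairwise signed-rank tests with p multiplied by C(k,2), capped at 1.

## Synthetic cohort generator

The generator emulates the study conditions — 20 participants × 7 days —
and is the package's substitute for raw data that is not publicly
deposited. Defaults (all overridable in `CohortParams`):

| parameter | default | meaning |
|---|---|---|
| mesor, between-participant SD | 95, 4 mg/dL | participant baseline |
| circadian amplitude, acrophase | 5 mg/dL, 16 h | cosine glucose rhythm |
| meal times (h) | B 9.37 ± 1.28, L 14.90 ± 0.55, D 21.96 ± 0.60 | habitual times across participants; day-to-day jitter SD 0.3 h |
| snacks | Poisson(0.97)/day, uniform 10–23 h, ≥ 1.5 h from mains | between-meal occasions |
| excursion amplitude (mg/dL) | B 48, L 48, D 38.4, snack 20; SD 10 | kernel peak height |
| excursion lag (min) | B 41.5, L 48.4, D 47.0, snack 45; SD 12 | meal-to-peak time |
| sensor noise | 3 mg/dL | Gaussian, per native minute |
| annotation error / omission / recall | SD 10 min / 5 % / 6 % | app behaviour |
| wrist-marker coverage | 80 %, ± 5 min of the app entry | KW presses |
| CGM dropout | 1 % per hour | missing-data gaps |

Glucose is mesor + cosine + Σ meal kernels + noise, floored at 40 mg/dL.
The kernel is gamma-shaped (shape 3, scale lag/2, support ≤ 4 h): peak
height equals the drawn amplitude at the drawn lag, giving a realistic
40–50 min rise and slower decay. MI is lognormal around a low sleep mean
(2 G/epoch) inside a per-participant nightly window (onset ~00:30 ± 0.5 h,
~8 h) and a high wake mean (15 G/epoch), with a 1-h ramp out of sleep and a
post-breakfast boost; DST runs ≥ 1 °C higher at night, its rise
anticipating sleep onset by ~1 h, plus a post-lunch elevation ramping to
+0.65 °C at +2 h. Light channels are constant day/night levels. All
randomness flows from one seed; per-participant substreams are spawned from
it, so cohorts are bit-reproducible.

What the generator does **not** emulate: true glucose–insulin dynamics
(no pre-meal dips, no meal-composition effects), realistic accelerometer
waveforms, naps or irregular sleep, light exposure beyond day/night
constants. Two consequences matter when reading test results against real
data. First, because the kernel adds its whole mass above the baseline,
trace-level summaries sit somewhat above their real-world counterparts
(cohort mean ≈ mesor + ~8 mg/dL; detected nadir-to-peak amplitudes run
5–10 % above the drawn kernel heights because nadirs dip below baseline).
Second, passing recovery tests therefore demonstrates that the pipeline
recovers *its generator's* parameters — lags within ±5 min, amplitudes
within ±15 %, postprandial elevation detectable by signed-rank — not that
a real cohort would print any particular value.

## Numerical choices and edge cases

- Duplicate glucose timestamps average; unparseable or out-of-band
  (outside 20–500 mg/dL) readings become missing samples, never dropped
  rows. Floats are written in shortest round-tripping decimal form and
  parsed with correctly-rounded conversion, so write→read→write is
  byte-stable.
- Dedup is idempotent and order-preserving; coupling never reuses a KW
  event; accuracy is monotone in `max_lag`.
- Exact-p Wilcoxon switches to the approximation at ties or n > 25; all
  reported p-values live in [0, 1] by construction.
- Traces shorter than the long moving average yield an empty, flagged peak
  set; a zero-SD (constant) trace yields none.

## Known limitations

- Only upward excursions are modelled; hypoglycemic analytics are out of
  scope.
- Meal–peak assignment is deterministic nearest-after matching; no
  probabilistic assignment or deconvolution of overlapping excursions.
- Sleep periods are not scored from actimetry; the generator's sleep window
  is a modelling device, not an inference target.
- The LibreView/Kronowise export dialects are project-defined plain-text
  forms, not the proprietary vendor layouts.
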