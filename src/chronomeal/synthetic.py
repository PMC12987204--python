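"""Synthetic free-living cohorts with known ground truth.

The generator emulates a one-week, twenty-participant protocol of CGM,
wrist-worn circadian monitoring and smartphone meal annotation:

* interstitial glucose = participant mesor + a circadian cosine (acrophase
  mid-afternoon) + one gamma-shaped excursion kernel per eating occasion
  (peak at the drawn lag, peak height equal to the drawn amplitude, support
  capped at 4 h) + Gaussian sensor noise, floored at 40 mg/dL;
* movement intensity is lognormal around a low nightly mean inside a
  per-participant sleep window and a high waking mean, with a ramp out of
  sleep and a post-breakfast elevation;
* distal skin temperature runs >= 1 degC higher at night than by day (the
  rise anticipating sleep onset), with a ramped postprandial elevation of
  +0.65 degC over the two hours after lunch;
* declared meal times are the true times plus Gaussian annotation error,
  minus omitted events; wrist-marker (KW) presses accompany a declared meal
  with fixed probability and land within 5 min of the app annotation.

Every random draw flows from one seed; per-participant substreams are
spawned from it so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.ndimage import gaussian_filter1d

from chronomeal.types import ACMTrace, GlucoseTrace, MealEvent, ParameterError
from chronomeal import io_formats

START_DATE = pd.Timestamp("2024-03-04 00:00")  # arbitrary Monday
MAIN_MEALS = ("breakfast", "lunch", "dinner")
GLUCOSE_FLOOR = 40.0
KERNEL_SUPPORT_MIN = 240.0


class CohortParams(BaseModel):
    """Cohort-level simulation parameters.

    Defaults mirror the observed study conditions: a 20 x 7-day cohort, a
    late Spanish meal schedule (breakfast 9.37 +- 1.28 h, lunch
    14.90 +- 0.55 h, dinner 21.96 +- 0.60 h, about one snack per day),
    postprandial excursions peaking 41-48 min after the meal with amplitudes
    of 48/48/38.4 mg/dL for breakfast/lunch/dinner, and imperfect
    annotation (10-min timing error, 5% omissions, 6% recalls, 80%
    wrist-marker coverage).
    """

    n_participants: int = Field(default=20, gt=0)
    n_days: int = Field(default=7, gt=0)
    glucose_mesor: float = Field(default=95.0, gt=0)
    mesor_sd: float = Field(default=4.0, ge=0)
    circadian_glucose_amplitude: float = Field(default=5.0, ge=0)
    glucose_acrophase_hour: float = 16.0
    sensor_noise_sd: float = Field(default=3.0, ge=0)
    meal_time_mean_h: dict[str, float] = Field(
        default_factory=lambda: {"breakfast": 9.37, "lunch": 14.90, "dinner": 21.96}
    )
    meal_time_sd_h: dict[str, float] = Field(
        default_factory=lambda: {"breakfast": 1.28, "lunch": 0.55, "dinner": 0.60}
    )
    day_jitter_sd_h: float = Field(default=0.3, ge=0)
    snack_rate_per_day: float = Field(default=0.97, ge=0)
    snack_window_h: tuple[float, float] = (10.0, 23.0)
    snack_meal_clearance_h: float = Field(default=1.5, ge=0)
    excursion_amplitude_mean: dict[str, float] = Field(
        default_factory=lambda: {
            "breakfast": 48.0, "lunch": 48.0, "dinner": 38.4, "snack": 20.0,
        }
    )
    excursion_amplitude_sd: float = Field(default=10.0, ge=0)
    excursion_lag_mean_min: dict[str, float] = Field(
        default_factory=lambda: {
            "breakfast": 41.5, "lunch": 48.4, "dinner": 47.0, "snack": 45.0,
        }
    )
    excursion_lag_sd_min: float = Field(default=12.0, ge=0)
    annotation_timing_sd_min: float = Field(default=10.0, ge=0)
    annotation_omission_prob: float = Field(default=0.05, ge=0, le=1)
    kw_marker_prob: float = Field(default=0.8, ge=0, le=1)
    retrospective_prob: float = Field(default=0.06, ge=0, le=1)
    missing_data_prob: float = Field(default=0.01, ge=0, le=1)
    mi_sleep_mean: float = Field(default=2.0, gt=0)
    mi_wake_mean: float = Field(default=15.0, gt=0)
    mi_postbreakfast_boost: float = Field(default=4.0, ge=0)
    dst_day_c: float = 28.5
    dst_night_c: float = 30.5
    dst_postlunch_rise_c: float = Field(default=0.65, ge=0)
    dst_noise_sd: float = Field(default=0.15, ge=0)
    sleep_onset_mean_h: float = 0.5
    sleep_onset_sd_h: float = Field(default=0.5, ge=0)
    sleep_duration_mean_h: float = 8.0
    sleep_duration_sd_h: float = Field(default=0.5, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_dicts(self) -> "CohortParams":
        for meal in MAIN_MEALS:
            if meal not in self.meal_time_mean_h or meal not in self.meal_time_sd_h:
                raise ParameterError(f"meal schedule missing {meal}")
        for meal in MAIN_MEALS + ("snack",):
            if meal not in self.excursion_amplitude_mean:
                raise ParameterError(f"excursion amplitude missing {meal}")
            if meal not in self.excursion_lag_mean_min:
                raise ParameterError(f"excursion lag missing {meal}")
        if any(v < 0 for v in self.excursion_amplitude_mean.values()):
            raise ParameterError("excursion amplitudes must be >= 0")
        return self


@dataclass
class GroundTruth:
    """Simulated truth: one row per eating occasion plus per-participant mesor.

    ``meals`` columns: participant_id, meal_type, true_time, true_lag_min,
    true_amplitude, true_peak_time, declared, declared_time, retrospective,
    kw_time (NaT where no marker was pressed).
    """

    meals: pd.DataFrame
    mesor: dict[str, float]


@dataclass
class CohortBundle:
    glucose: list[GlucoseTrace]
    acm: list[ACMTrace]
    events: list[MealEvent]
    truth: GroundTruth


def _excursion_kernel(minutes: np.ndarray, lag: float, amplitude: float) -> np.ndarray:
    """Gamma-shaped (shape 3) rise-decay with peak ``amplitude`` at ``lag`` min."""
    tau = np.clip(minutes, 0.0, None)
    k = (tau / lag) ** 2 * np.exp(2.0 - 2.0 * tau / lag)
    k[(minutes < 0) | (minutes > KERNEL_SUPPORT_MIN)] = 0.0
    return amplitude * k


def _draw_meals(rng: np.random.Generator, params: CohortParams) -> list[tuple[str, float]]:
    """Per-participant eating occasions as (meal_type, hours since start)."""
    meals: list[tuple[str, float]] = []
    habitual = {
        m: rng.normal(params.meal_time_mean_h[m], params.meal_time_sd_h[m])
        for m in MAIN_MEALS
    }
    for day in range(params.n_days):
        day_mains = []
        for m in MAIN_MEALS:
            t = day * 24.0 + habitual[m] + rng.normal(0.0, params.day_jitter_sd_h)
            day_mains.append(t)
            meals.append((m, t))
        lo, hi = params.snack_window_h
        for _ in range(rng.poisson(params.snack_rate_per_day)):
            # snacks are between-meal occasions: keep clear of the mains
            for _attempt in range(20):
                t = day * 24.0 + rng.uniform(lo, hi)
                if all(abs(t - tm) >= params.snack_meal_clearance_h for tm in day_mains):
                    break
            meals.append(("snack", t))
    meals.sort(key=lambda mt: mt[1])
    return meals


def _simulate_participant(
    pid: str, rng: np.random.Generator, params: CohortParams
) -> tuple[GlucoseTrace, ACMTrace, list[MealEvent], pd.DataFrame, float]:
    total_min = params.n_days * 1440
    minute = np.arange(total_min, dtype=float)
    hour_of_day = (minute / 60.0) % 24.0

    mesor = rng.normal(params.glucose_mesor, params.mesor_sd)
    glucose = mesor + params.circadian_glucose_amplitude * np.cos(
        2 * np.pi * (hour_of_day - params.glucose_acrophase_hour) / 24.0
    )

    meals = _draw_meals(rng, params)
    truth_rows = []
    for meal_type, t_h in meals:
        t_min = t_h * 60.0
        amp = max(0.0, rng.normal(params.excursion_amplitude_mean[meal_type],
                                  params.excursion_amplitude_sd))
        lag = max(10.0, rng.normal(params.excursion_lag_mean_min[meal_type],
                                   params.excursion_lag_sd_min))
        lo = int(np.floor(t_min))
        hi = min(total_min, int(np.ceil(t_min + KERNEL_SUPPORT_MIN)) + 1)
        if lo < total_min:
            glucose[lo:hi] += _excursion_kernel(minute[lo:hi] - t_min, lag, amp)
        truth_rows.append(
            {
                "participant_id": pid,
                "meal_type": meal_type,
                "true_time": START_DATE + pd.Timedelta(minutes=t_min),
                "true_lag_min": lag,
                "true_amplitude": amp,
                "true_peak_time": START_DATE + pd.Timedelta(minutes=t_min + lag),
            }
        )

    glucose += rng.normal(0.0, params.sensor_noise_sd, total_min)
    glucose = np.maximum(glucose, GLUCOSE_FLOOR)

    # hour-level CGM dropout
    n_hours = params.n_days * 24
    dropped_hours = rng.random(n_hours) < params.missing_data_prob
    for h in np.flatnonzero(dropped_hours):
        glucose[h * 60:(h + 1) * 60] = np.nan

    g_times = START_DATE + pd.to_timedelta(minute, unit="m")
    glucose_trace = GlucoseTrace(
        participant_id=pid,
        times=pd.DatetimeIndex(g_times),
        values=np.round(glucose, 2),
        epoch_seconds=60,
    )

    # ---- annotations --------------------------------------------------
    events: list[MealEvent] = []
    declared_flags, declared_times, retro_flags, kw_times = [], [], [], []
    for row in truth_rows:
        declared = rng.random() >= params.annotation_omission_prob
        declared_time = pd.NaT
        kw_time = pd.NaT
        retro = False
        if declared:
            err = rng.normal(0.0, params.annotation_timing_sd_min)
            declared_time = (row["true_time"] + pd.Timedelta(minutes=err)).round("min")
            retro = (
                row["meal_type"] in MAIN_MEALS
                and rng.random() < params.retrospective_prob
            )
            events.append(
                MealEvent(
                    participant_id=pid,
                    timestamp=declared_time,
                    source="KE",
                    meal_type=row["meal_type"],
                    entry_mode="retrospective" if retro else "prospective",
                )
            )
            if rng.random() < params.kw_marker_prob:
                kw_time = (
                    declared_time + pd.Timedelta(minutes=rng.uniform(-5.0, 5.0))
                ).round("30s")
        declared_flags.append(declared)
        declared_times.append(declared_time)
        retro_flags.append(retro)
        kw_times.append(kw_time)
    truth = pd.DataFrame(truth_rows)
    truth["declared"] = declared_flags
    truth["declared_time"] = declared_times
    truth["retrospective"] = retro_flags
    truth["kw_time"] = kw_times
    events.sort(key=lambda e: e.timestamp)

    # ---- ACM ----------------------------------------------------------
    n_epochs = params.n_days * 2880
    acm_sec = np.arange(n_epochs, dtype=float) * 30.0
    acm_hod = (acm_sec / 3600.0) % 24.0
    onset = rng.normal(params.sleep_onset_mean_h, params.sleep_onset_sd_h) % 24.0
    duration = max(4.0, rng.normal(params.sleep_duration_mean_h,
                                   params.sleep_duration_sd_h))
    since_onset = (acm_hod - onset) % 24.0
    asleep = since_onset < duration

    mi_mean = np.where(asleep, params.mi_sleep_mean, params.mi_wake_mean).astype(float)
    # ramp from sleep to wake level over the first hour after sleep offset
    since_wake = (acm_hod - (onset + duration)) % 24.0
    ramp = since_wake < 1.0
    mi_mean[ramp] = params.mi_sleep_mean + (
        params.mi_wake_mean - params.mi_sleep_mean
    ) * since_wake[ramp]
    for row, declared in zip(truth_rows, declared_flags):
        if row["meal_type"] == "breakfast":
            t0 = (row["true_time"] - START_DATE).total_seconds()
            sel = (acm_sec > t0) & (acm_sec <= t0 + 7200)
            mi_mean[sel] += params.mi_postbreakfast_boost
    sigma = 0.5
    mi = mi_mean * np.exp(rng.normal(0.0, sigma, n_epochs) - sigma**2 / 2)

    # DST: nocturnal elevation anticipates sleep by ~1 h, smoothed transitions
    since_dst_onset = (acm_hod - (onset - 1.0)) % 24.0
    dst_night = since_dst_onset < (duration + 1.0)
    dst = np.where(dst_night, params.dst_night_c, params.dst_day_c).astype(float)
    dst = gaussian_filter1d(dst, sigma=60.0, mode="nearest")  # 30-min SD
    for row in truth_rows:
        if row["meal_type"] == "lunch":
            t0 = (row["true_time"] - START_DATE).total_seconds()
            tau_min = (acm_sec - t0) / 60.0
            bump = np.zeros(n_epochs)
            rise = (tau_min > 0) & (tau_min <= 120)
            fall = (tau_min > 120) & (tau_min <= 180)
            bump[rise] = params.dst_postlunch_rise_c * tau_min[rise] / 120.0
            bump[fall] = params.dst_postlunch_rise_c * (1.0 - (tau_min[fall] - 120.0) / 60.0)
            dst += bump
    dst += rng.normal(0.0, params.dst_noise_sd, n_epochs)

    daytime = (acm_hod >= 7.0) & (acm_hod < 22.0) & ~asleep
    light_total = np.where(daytime, 500.0, 5.0)
    light_blue = np.where(daytime, 100.0, 1.0)
    light_ir = np.where(daytime, 200.0, 50.0)

    acm_times = START_DATE + pd.to_timedelta(acm_sec, unit="s")
    marker = np.zeros(n_epochs, dtype=bool)
    for kw_time in kw_times:
        if pd.isna(kw_time):
            continue
        idx = int((kw_time - START_DATE).total_seconds() // 30)
        if 0 <= idx < n_epochs:
            marker[idx] = True
    acm_trace = ACMTrace(
        participant_id=pid,
        times=pd.DatetimeIndex(acm_times),
        mi=np.round(mi, 3),
        dst=np.round(dst, 3),
        light_total=light_total,
        light_blue=light_blue,
        light_ir=light_ir,
        marker=marker,
        epoch_seconds=30,
    )
    return glucose_trace, acm_trace, events, truth, float(mesor)


def simulate_cohort(params: CohortParams) -> CohortBundle:
    """Simulate a full cohort; bit-reproducible for a given ``params.seed``."""
    if params.n_participants <= 0 or params.n_days <= 0:
        raise ParameterError("cohort size must be positive")
    glucose, acm, events, truths = [], [], [], []
    mesors: dict[str, float] = {}
    for i in range(params.n_participants):
        pid = f"P{i + 1:02d}"
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=params.seed, spawn_key=(i,))
        )
        g, a, ev, truth, mesor = _simulate_participant(pid, rng, params)
        glucose.append(g)
        acm.append(a)
        events.extend(ev)
        truths.append(truth)
        mesors[pid] = mesor
    truth = GroundTruth(meals=pd.concat(truths, ignore_index=True), mesor=mesors)
    return CohortBundle(glucose=glucose, acm=acm, events=events, truth=truth)


def write_cohort(bundle: CohortBundle, directory) -> list[Path]:
    """Write a bundle as the pipeline's three dialects plus ground truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    p = directory / "glucose.csv"
    io_formats.write_glucose_csv(bundle.glucose, p)
    written.append(p)
    for trace in bundle.acm:
        p = directory / f"acm_{trace.participant_id}.txt"
        io_formats.write_acm_table(trace, p)
        written.append(p)
    p = directory / "meals.csv"
    io_formats.write_meal_log(bundle.events, p)
    written.append(p)
    p = directory / "truth.csv"
    truth = bundle.truth.meals.copy()
    truth["mesor"] = truth["participant_id"].map(bundle.truth.mesor)
    truth.to_csv(p, index=False)
    written.append(p)
    return written
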