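"""Meal-to-peak assignment and the peak-related accuracy statistic.

A declared meal is *linked* when its nearest subsequent glucose peak falls
within the first two postprandial hours.  Peak-related accuracy is, per meal
type, the percentage of declared meals that are linked.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from chronomeal.types import (
    AccuracyTable,
    ContractError,
    LinkedMeal,
    MealEvent,
    PeakCall,
)

MEAL_ORDER = ("breakfast", "lunch", "dinner", "snack", "unknown")


def link_meals_to_peaks(
    events: list[MealEvent],
    peaks: list[PeakCall],
    max_lag_minutes: float = 120.0,
) -> list[LinkedMeal]:
    """Assign each meal its nearest subsequent unclaimed glucose peak.

    Events are processed in time order; a peak can be claimed by at most one
    event (earliest-event priority), so a single excursion never validates
    two annotations at once.  Candidate peaks lie strictly after the
    annotation (lag > 0); peaks at or before it are never candidates.
    Unlinked events keep their candidate lag, if any, for distance plots.
    """
    events = sorted(events, key=lambda e: e.timestamp)
    peaks = sorted(peaks, key=lambda p: p.peak_time)
    claimed: set[int] = set()
    linked: list[LinkedMeal] = []
    for ev in events:
        candidate = None
        candidate_lag = None
        for j, pk in enumerate(peaks):
            if j in claimed:
                continue
            lag = (pk.peak_time - ev.timestamp).total_seconds() / 60.0
            if lag <= 0:
                continue
            candidate, candidate_lag = j, lag
            break
        if candidate is not None and candidate_lag <= max_lag_minutes:
            claimed.add(candidate)
            linked.append(
                LinkedMeal(event=ev, peak=peaks[candidate],
                           lag_minutes=candidate_lag, linked=True)
            )
        else:
            linked.append(
                LinkedMeal(event=ev, peak=None, lag_minutes=candidate_lag,
                           linked=False)
            )
    return linked


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def peak_related_accuracy(linked: list[LinkedMeal]) -> AccuracyTable:
    """Per-meal-type linked/total counts and accuracy percentages.

    Reported percentages are half-up rounded to one decimal; the raw
    fractions are retained alongside.
    """
    if not linked:
        raise ContractError("peak_related_accuracy: empty linkage list")
    rows = []
    raw: dict[str, float] = {}
    present = [m for m in MEAL_ORDER if any(lm.event.meal_type == m for lm in linked)]
    for meal in present + ["overall"]:
        sel = (
            linked
            if meal == "overall"
            else [lm for lm in linked if lm.event.meal_type == meal]
        )
        n_total = len(sel)
        n_linked = sum(lm.linked for lm in sel)
        frac = n_linked / n_total
        raw[meal] = frac
        rows.append(
            {
                "meal_type": meal,
                "n_linked": n_linked,
                "n_total": n_total,
                "accuracy_percent": _round1(100.0 * frac),
            }
        )
    return AccuracyTable(table=pd.DataFrame(rows), raw_fractions=raw)


def lag_summary(linked: list[LinkedMeal]) -> pd.DataFrame:
    """Mean +- SEM of meal-to-peak lag (minutes) per meal type, linked events only.

    Types with no linked events are omitted; SEM is reported absent (NaN)
    when only one lag is available.
    """
    rows = []
    for meal in MEAL_ORDER:
        lags = np.array(
            [lm.lag_minutes for lm in linked if lm.linked and lm.event.meal_type == meal]
        )
        if lags.size == 0:
            continue
        sem = float(lags.std(ddof=1) / np.sqrt(lags.size)) if lags.size > 1 else np.nan
        rows.append(
            {"meal_type": meal, "n": int(lags.size),
             "mean_lag_min": float(lags.mean()), "sem_lag_min": sem}
        )
    return pd.DataFrame(rows)
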