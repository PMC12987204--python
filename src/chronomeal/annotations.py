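"""Cleaning rules for meal annotations.

Three filters run, in order, before any meal is linked to a glucose peak:
redundant annotations closer than 15 min within one source are dropped,
app (KE) and wrist-marker (KW) annotations within 30 min of each other are
coupled into one eating occasion, and events without adequate postprandial
glucose coverage are excluded.
"""

from __future__ import annotations

import numpy as np

from chronomeal.types import ContractError, CoupledEvent, GlucoseTrace, MealEvent


def _check_homogeneous(events: list[MealEvent], same_source: bool) -> None:
    pids = {e.participant_id for e in events}
    if len(pids) > 1:
        raise ContractError(f"events span multiple participants: {sorted(pids)}")
    if same_source and len({e.source for e in events}) > 1:
        raise ContractError("events span multiple sources")


def dedup_events(
    events: list[MealEvent], min_gap_minutes: float = 15.0
) -> list[MealEvent]:
    """Drop annotations too close (<= min_gap) to the last kept one.

    Scanning in time order and keeping the earliest event of each close
    cluster means the surviving time stamps mark meal onsets; the result is
    idempotent and all surviving gaps exceed ``min_gap_minutes``.
    """
    if not events:
        return []
    _check_homogeneous(events, same_source=True)
    events = sorted(events, key=lambda e: e.timestamp)
    kept = [events[0]]
    for ev in events[1:]:
        gap = (ev.timestamp - kept[-1].timestamp).total_seconds() / 60.0
        if gap > min_gap_minutes:
            kept.append(ev)
    return kept


def couple_ke_kw(
    ke: list[MealEvent],
    kw: list[MealEvent],
    window_minutes: float = 30.0,
) -> tuple[list[CoupledEvent], float]:
    """One-to-one KE-KW matching by ascending absolute lag.

    Both annotation streams are assumed deduplicated.  Each KW marker can
    confirm at most one app annotation; candidate pairs are taken greedily by
    smallest |lag| (ties resolve to the earlier KW event).  The returned
    coincidence rate is coupled KE events over total KE events.
    """
    if ke:
        _check_homogeneous(ke, same_source=True)
    if kw:
        _check_homogeneous(kw, same_source=True)
    if ke and kw and ke[0].participant_id != kw[0].participant_id:
        raise ContractError("KE and KW events belong to different participants")

    pairs: list[tuple[float, float, int, int]] = []
    for i, e in enumerate(ke):
        for j, w in enumerate(kw):
            lag = (w.timestamp - e.timestamp).total_seconds() / 60.0
            if abs(lag) <= window_minutes:
                pairs.append((abs(lag), w.timestamp.value, i, j))
    pairs.sort()

    matched_ke: dict[int, tuple[int, float]] = {}
    used_kw: set[int] = set()
    for _, _, i, j in pairs:
        if i in matched_ke or j in used_kw:
            continue
        lag = (kw[j].timestamp - ke[i].timestamp).total_seconds() / 60.0
        matched_ke[i] = (j, lag)
        used_kw.add(j)

    coupled: list[CoupledEvent] = []
    for i, e in enumerate(ke):
        if i in matched_ke:
            j, lag = matched_ke[i]
            coupled.append(CoupledEvent(ke_event=e, kw_event=kw[j], lag_minutes=lag))
        else:
            coupled.append(CoupledEvent(ke_event=e))
    rate = (len(matched_ke) / len(ke)) if ke else 0.0
    return coupled, rate


def exclude_missing_glucose(
    events: list[MealEvent],
    trace: GlucoseTrace,
    window_minutes: float = 120.0,
    max_missing_fraction: float = 0.2,
) -> list[MealEvent]:
    """Keep events whose postprandial window has adequate glucose coverage.

    An event survives iff at least ``1 - max_missing_fraction`` of the epochs
    in ``(t, t + window]`` carry glucose values; windows reaching beyond the
    trace end count the overhang as missing, so such events are excluded.
    """
    kept: list[MealEvent] = []
    series = trace.to_series()
    n_expected = max(1, int(round(window_minutes * 60 / trace.epoch_seconds)))
    for ev in events:
        if ev.participant_id != trace.participant_id:
            raise ContractError(
                f"event participant {ev.participant_id} does not match trace "
                f"{trace.participant_id}"
            )
        t0, t1 = ev.timestamp, ev.timestamp + np.timedelta64(int(window_minutes * 60), "s")
        window = series.loc[(series.index > t0) & (series.index <= t1)]
        n_present = int(window.notna().sum())
        if n_present >= (1.0 - max_missing_fraction) * n_expected:
            kept.append(ev)
    return kept
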