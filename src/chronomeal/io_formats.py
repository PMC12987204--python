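"""Readers and writers for the three text dialects used by the pipeline.

* Glucose CSV — ``participant_id,timestamp,glucose_mg_dl``, one row per native
  sensor sample, optional preamble lines (LibreView-style exports carry a
  header block) skipped with ``skip_rows``.
* ACM epoch table — ``timestamp,mi_g,dst_c,light_total,light_blue,light_ir,marker``
  at a fixed 30 s cadence, tab-delimited by default.
* Meal-annotation log — ``participant_id,timestamp,source,meal_type,entry_mode``.

Parsing never silently drops data rows: unparseable or out-of-range glucose
becomes a missing sample, duplicate timestamps are collapsed to their mean,
and each reader can return a row-accounting report.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

from chronomeal.types import (
    ACMTrace,
    ContractError,
    FormatError,
    GlucoseTrace,
    MealEvent,
)

GLUCOSE_COLUMNS = ["participant_id", "timestamp", "glucose_mg_dl"]
ACM_COLUMNS = ["timestamp", "mi_g", "dst_c", "light_total", "light_blue", "light_ir", "marker"]
MEAL_COLUMNS = ["participant_id", "timestamp", "source", "meal_type", "entry_mode"]

TIME_FMT_MIN = "%Y-%m-%d %H:%M"
TIME_FMT_SEC = "%Y-%m-%d %H:%M:%S"


def _require_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {', '.join(missing)}")


def _read_table(path, sep: str, skip_rows: int) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, skiprows=skip_rows, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty file")
    df.columns = [c.strip() for c in df.columns]
    return df


def read_glucose_csv(
    path,
    epoch_seconds: int = 60,
    skip_rows: int = 0,
    return_report: bool = False,
):
    """Parse a glucose CSV into one :class:`GlucoseTrace` per participant.

    Rows with unparseable or physiologically impossible glucose (outside the
    20-500 mg/dL sensor band) become missing samples at their timestamp.
    Out-of-order rows are sorted; duplicate timestamps collapse to their mean.
    """
    df = _read_table(path, ",", skip_rows)
    _require_columns(df, GLUCOSE_COLUMNS, str(path))
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")

    times = pd.to_datetime(df["timestamp"], errors="coerce")
    if times.isna().any():
        bad = int(times.isna().idxmax())
        raise FormatError(f"{path}: unparseable timestamp at data row {bad + 1}")
    glucose = pd.Series(_parse_float_column(df["glucose_mg_dl"]))
    # sensor band: values outside (20, 500) cannot be real readings
    glucose = glucose.where((glucose > 20) & (glucose < 500))

    work = pd.DataFrame(
        {"pid": df["participant_id"].str.strip(), "t": times, "g": glucose}
    )
    n_rows = len(work)
    traces: list[GlucoseTrace] = []
    n_samples = 0
    n_merged = 0
    for pid, grp in work.groupby("pid", sort=True):
        grp = grp.sort_values("t")
        merged = grp.groupby("t")["g"].mean()
        n_merged += len(grp) - len(merged)
        traces.append(
            GlucoseTrace(
                participant_id=str(pid),
                times=pd.DatetimeIndex(merged.index),
                values=merged.to_numpy(),
                epoch_seconds=epoch_seconds,
            )
        )
        n_samples += len(merged)
    report = {"rows_in": n_rows, "samples_out": n_samples, "rows_merged": n_merged}
    if return_report:
        return traces, report
    return traces


def write_glucose_csv(traces: list[GlucoseTrace] | GlucoseTrace, path) -> None:
    if isinstance(traces, GlucoseTrace):
        traces = [traces]
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": tr.participant_id,
                    "timestamp": tr.times.strftime(TIME_FMT_MIN),
                    "glucose_mg_dl": [_fmt_float(v) for v in tr.values],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _fmt_float(v: float) -> str:
    # shortest round-tripping decimal form
    return "" if not np.isfinite(v) else repr(float(v))


def _parse_float_column(series: pd.Series) -> np.ndarray:
    """Correctly-rounded float parsing (Python float), blanks/junk -> NaN."""
    out = np.empty(len(series))
    for i, s in enumerate(series.to_numpy()):
        s = s.strip()
        try:
            out[i] = float(s) if s else np.nan
        except ValueError:
            out[i] = np.nan
    return out


def read_acm_table(
    path,
    participant_id: Optional[str] = None,
    sep: str = "\t",
    skip_rows: int = 0,
    epoch_seconds: int = 30,
) -> ACMTrace:
    """Parse one participant's ACM epoch table.

    ``participant_id`` defaults to the file stem. Negative movement intensity
    and non-monotone timestamps are format errors (they indicate a corrupted
    export, not a plausible measurement).
    """
    df = _read_table(path, sep, skip_rows)
    _require_columns(df, ACM_COLUMNS, str(path))
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    times = pd.to_datetime(df["timestamp"], errors="coerce")
    if times.isna().any():
        bad = int(times.isna().idxmax())
        raise FormatError(f"{path}: unparseable timestamp at data row {bad + 1}")
    diffs = times.diff().dt.total_seconds().iloc[1:]
    if (diffs <= 0).any():
        bad = int(np.argmax(diffs.to_numpy() <= 0))
        raise FormatError(f"{path}: non-monotone timestamps at data row {bad + 2}")

    def numeric(col: str) -> np.ndarray:
        return _parse_float_column(df[col])

    mi = numeric("mi_g")
    if np.any(mi[np.isfinite(mi)] < 0):
        raise FormatError(f"{path}: negative movement intensity value")
    marker = pd.to_numeric(df["marker"], errors="coerce").fillna(0).astype(int).to_numpy()
    if participant_id is None:
        participant_id = os.path.splitext(os.path.basename(str(path)))[0]
    return ACMTrace(
        participant_id=participant_id,
        times=pd.DatetimeIndex(times),
        mi=mi,
        dst=numeric("dst_c"),
        light_total=numeric("light_total"),
        light_blue=numeric("light_blue"),
        light_ir=numeric("light_ir"),
        marker=marker.astype(bool),
        epoch_seconds=epoch_seconds,
    )


def write_acm_table(trace: ACMTrace, path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "timestamp": trace.times.strftime(TIME_FMT_SEC),
            "mi_g": [_fmt_float(v) for v in trace.mi],
            "dst_c": [_fmt_float(v) for v in trace.dst],
            "light_total": [_fmt_float(v) for v in trace.light_total],
            "light_blue": [_fmt_float(v) for v in trace.light_blue],
            "light_ir": [_fmt_float(v) for v in trace.light_ir],
            "marker": trace.marker.astype(int),
        }
    )
    df.to_csv(path, sep=sep, index=False)


def extract_kw_events(trace: ACMTrace) -> list[MealEvent]:
    """Turn marker epochs into KW meal-event candidates (no type, no entry mode)."""
    return [
        MealEvent(
            participant_id=trace.participant_id,
            timestamp=t,
            source="KW",
            meal_type="unknown",
            entry_mode="na",
        )
        for t in trace.times[trace.marker]
    ]


def read_meal_log(path, skip_rows: int = 0) -> list[MealEvent]:
    """Parse the meal-annotation log, sorted by (participant, timestamp).

    Type-invariant violations (a retrospective snack, an unknown meal-type
    literal) are rejected with the offending row named.
    """
    df = _read_table(path, ",", skip_rows)
    _require_columns(df, MEAL_COLUMNS, str(path))
    events: list[MealEvent] = []
    for i, row in df.iterrows():
        t = pd.to_datetime(row["timestamp"], errors="coerce")
        if pd.isna(t):
            raise FormatError(f"{path}: unparseable timestamp at data row {i + 1}")
        source = row["source"].strip()
        meal_type = row["meal_type"].strip() or "unknown"
        entry_mode = row["entry_mode"].strip() or "na"
        try:
            events.append(
                MealEvent(
                    participant_id=row["participant_id"].strip(),
                    timestamp=t,
                    source=source,
                    meal_type=meal_type,
                    entry_mode=entry_mode,
                )
            )
        except (FormatError, ContractError) as exc:
            raise type(exc)(f"{path}: data row {i + 1}: {exc}") from None
    events.sort(key=lambda e: (e.participant_id, e.timestamp))
    return events


def write_meal_log(events: list[MealEvent], path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in events],
            "timestamp": [e.timestamp.strftime(TIME_FMT_SEC) for e in events],
            "source": [e.source for e in events],
            "meal_type": [e.meal_type for e in events],
            "entry_mode": [e.entry_mode for e in events],
        }
    )
    df.to_csv(path, index=False)
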