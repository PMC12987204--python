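"""Event-anchored window stacks and postprandial summaries.

Two anchor conventions are used: meal-time anchors (0 to +120 min after the
annotation) for postprandial curves, and glucose-peak anchors (-60 to
+120 min around the excursion apex, a zeitgeber-time axis with ZT = 0 at the
peak) for the temporal architecture of excursions and the circadian signals
around them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from chronomeal.types import (
    ACMTrace,
    ContractError,
    GlucoseTrace,
    MealEvent,
    PeakCall,
    PrePostContrast,
    WindowStack,
)


def _anchor_time(anchor) -> pd.Timestamp:
    if isinstance(anchor, MealEvent):
        return anchor.timestamp
    if isinstance(anchor, PeakCall):
        return anchor.peak_time
    return pd.Timestamp(anchor)


def _anchor_pid(anchor, default: str) -> str:
    return anchor.participant_id if isinstance(anchor, MealEvent) else default


def _gridded(series: pd.Series, grid_seconds: int) -> pd.Series:
    """Bin a series onto a midnight-anchored grid by mean."""
    binned = series.groupby(series.index.floor(f"{grid_seconds}s")).mean()
    full = pd.date_range(binned.index[0], binned.index[-1], freq=f"{grid_seconds}s")
    return binned.reindex(full)


def _stack_signal(
    anchors,
    series: pd.Series,
    pids: list[str],
    anchor_kind: str,
    signal: str,
    pre_minutes: float,
    post_minutes: float,
    grid_minutes: float,
) -> WindowStack:
    grid_seconds = int(grid_minutes * 60)
    gridded = _gridded(series.dropna(), grid_seconds) if series.notna().any() else series
    offsets = np.arange(-pre_minutes, post_minutes + grid_minutes / 2, grid_minutes)
    rows = np.full((len(anchors), len(offsets)), np.nan)
    for i, anchor in enumerate(anchors):
        t0 = _anchor_time(anchor).floor(f"{grid_seconds}s")
        times = t0 + pd.to_timedelta(offsets, unit="m")
        vals = gridded.reindex(times).to_numpy()
        rows[i] = vals
    return WindowStack(
        anchor_kind=anchor_kind,
        signal=signal,
        offsets=offsets,
        rows=rows,
        anchor_ids=pids,
    )


def extract_stack(
    anchors,
    glucose: GlucoseTrace | None = None,
    acm: ACMTrace | None = None,
    anchor_kind: str = "meal_time",
    pre_minutes: float = 0.0,
    post_minutes: float = 120.0,
    grid_minutes: float = 5.0,
) -> dict[str, WindowStack]:
    """Build per-signal window stacks around a list of anchors.

    Anchors may be meal events, peak calls or bare timestamps; windows that
    extend beyond a trace's span are padded with missing values.  ACM 30-s
    epochs are resampled to the grid by arithmetic mean.  Returns a dict with
    keys among {"glucose", "mi", "dst"}, depending on the traces supplied.
    """
    if not anchors:
        raise ContractError("extract_stack: empty anchor list")
    default_pid = ""
    if glucose is not None:
        default_pid = glucose.participant_id
    elif acm is not None:
        default_pid = acm.participant_id
    pids = [_anchor_pid(a, default_pid) for a in anchors]
    out: dict[str, WindowStack] = {}
    if glucose is not None:
        out["glucose"] = _stack_signal(
            anchors, glucose.to_series(), pids, anchor_kind, "glucose",
            pre_minutes, post_minutes, grid_minutes,
        )
    if acm is not None:
        for name in ("mi", "dst"):
            out[name] = _stack_signal(
                anchors, acm.signal(name), pids, anchor_kind, name,
                pre_minutes, post_minutes, grid_minutes,
            )
    return out


def postprandial_auc(offsets: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal area under one postprandial window, in mg/dL*min.

    Interior missing points are bridged linearly; the integral runs over the
    span between the first and last finite samples.  Fewer than two finite
    points is undefined (NaN).
    """
    offsets = np.asarray(offsets, dtype=float)
    values = pd.Series(np.asarray(values, dtype=float)).interpolate(
        limit_area="inside"
    ).to_numpy()
    ok = np.isfinite(values)
    if ok.sum() < 2:
        return float("nan")
    return float(np.trapezoid(values[ok], offsets[ok]))


def stack_aucs(stack: WindowStack) -> np.ndarray:
    """Per-row AUC of a (0..post) postprandial stack."""
    return np.array([postprandial_auc(stack.offsets, row) for row in stack.rows])


def postprandial_vs_mean(
    events: list[MealEvent],
    trace: GlucoseTrace,
    window_minutes: float = 120.0,
    grid_minutes: float = 5.0,
) -> tuple[float, float]:
    """One participant's (mean 2-h postprandial glucose, overall mean glucose).

    The postprandial mean pools all sampled offsets across the given events;
    paired across participants these feed the signed-rank comparison of
    postprandial versus average glucose.
    """
    if not events:
        raise ContractError("postprandial_vs_mean: no events")
    stacks = extract_stack(
        events, glucose=trace, anchor_kind="meal_time",
        pre_minutes=0.0, post_minutes=window_minutes, grid_minutes=grid_minutes,
    )
    rows = stacks["glucose"].rows
    post_mean = float(np.nanmean(rows)) if np.isfinite(rows).any() else float("nan")
    overall = float(np.nanmean(trace.values))
    return post_mean, overall


def prepost_contrast(
    stack: WindowStack,
    pre_minutes: float = 60.0,
    post_minutes: float = 120.0,
) -> list[PrePostContrast]:
    """Per-participant pre-anchor vs post-anchor means of one signal.

    Pre spans offsets in [-pre, 0) and post spans (0, +post]; the anchor
    sample itself belongs to neither side.  Each participant's contrast uses
    only that participant's windows.
    """
    pre_mask = (stack.offsets < 0) & (stack.offsets >= -pre_minutes)
    post_mask = (stack.offsets > 0) & (stack.offsets <= post_minutes)
    out: list[PrePostContrast] = []
    for pid in sorted(set(stack.anchor_ids)):
        rows = stack.rows[[i for i, p in enumerate(stack.anchor_ids) if p == pid]]
        pre_vals = rows[:, pre_mask]
        post_vals = rows[:, post_mask]
        pre = float(np.nanmean(pre_vals)) if np.isfinite(pre_vals).any() else float("nan")
        post = float(np.nanmean(post_vals)) if np.isfinite(post_vals).any() else float("nan")
        out.append(
            PrePostContrast(
                participant_id=pid, pre_mean=pre, post_mean=post,
                pre_minutes=pre_minutes, post_minutes=post_minutes,
            )
        )
    return out


def merge_stacks(stacks: list[WindowStack]) -> WindowStack:
    """Concatenate per-participant stacks sharing one offset grid."""
    if not stacks:
        raise ContractError("merge_stacks: nothing to merge")
    first = stacks[0]
    for s in stacks[1:]:
        if not np.array_equal(s.offsets, first.offsets):
            raise ContractError("merge_stacks: offset grids differ")
        if (s.anchor_kind, s.signal) != (first.anchor_kind, first.signal):
            raise ContractError("merge_stacks: incompatible stacks")
    return WindowStack(
        anchor_kind=first.anchor_kind,
        signal=first.signal,
        offsets=first.offsets.copy(),
        rows=np.vstack([s.rows for s in stacks]),
        anchor_ids=[pid for s in stacks for pid in s.anchor_ids],
    )


def stack_to_long(stack: WindowStack) -> pd.DataFrame:
    """Long-format (anchor_id, signal, offset_min, value) table of a stack."""
    records = []
    for i, pid in enumerate(stack.anchor_ids):
        for off, val in zip(stack.offsets, stack.rows[i]):
            records.append(
                {"anchor_id": f"{pid}:{i}", "signal": stack.signal,
                 "offset_min": off, "value": val}
            )
    return pd.DataFrame(records)
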