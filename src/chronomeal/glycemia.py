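"""CGM epoch aggregation, summary metrics and glycemic-excursion peak calls.

Peak detection follows the moving-average MAGE algorithm used for CGM
glycemic-variability analysis: two centred moving averages (a short one that
tracks the trace and a long one that tracks its trend) are compared, the
trace is cut at their crossings, each inter-crossing run contributes one raw
local extremum, and consecutive nadir-to-peak upswings qualify as excursions
when their amplitude reaches one standard deviation of the whole trace.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from chronomeal.types import (
    CGMMetrics,
    ContractError,
    GlucoseTrace,
    ParameterError,
    PeakCall,
)

#: moving-average lengths (in 5-min epochs) of the published MAGE algorithm
SHORT_MA_EPOCHS = 5
LONG_MA_EPOCHS = 32


def to_epochs(trace: GlucoseTrace, epoch_seconds: int = 300) -> GlucoseTrace:
    """Average a trace into longer epochs on a midnight-anchored grid.

    Each output sample is the mean of the available source samples in its
    half-open bin ``[t, t + epoch)``; bins with no data are missing. The
    output grid is contiguous from the first to the last occupied bin.
    """
    if epoch_seconds <= 0 or epoch_seconds % trace.epoch_seconds != 0:
        raise ParameterError(
            f"target epoch {epoch_seconds}s is not a multiple of source "
            f"epoch {trace.epoch_seconds}s"
        )
    if len(trace) == 0:
        raise ContractError("to_epochs: empty trace")
    s = trace.to_series()
    binned = s.groupby(s.index.floor(f"{epoch_seconds}s")).mean()
    grid = pd.date_range(binned.index[0], binned.index[-1], freq=f"{epoch_seconds}s")
    binned = binned.reindex(grid)
    return GlucoseTrace(
        participant_id=trace.participant_id,
        times=grid,
        values=binned.to_numpy(),
        epoch_seconds=epoch_seconds,
    )


def _complete_days(trace: GlucoseTrace, min_fraction: float = 0.9) -> int:
    """Number of calendar days covered at >= min_fraction of their epochs."""
    s = trace.to_series()
    per_day = s.groupby(s.index.normalize()).count()
    expected = 86400 / trace.epoch_seconds
    return int((per_day >= min_fraction * expected).sum())


def cgm_metrics(
    trace: GlucoseTrace,
    range_low: float = 70.0,
    range_high: float = 180.0,
    min_complete_days: int = 3,
) -> CGMMetrics:
    """Mean glucose, SD, CV, time in range and MAGE for one participant.

    Missing epochs are excluded from every denominator.  Traces with fewer
    than ``min_complete_days`` well-covered days are still computed but carry
    a low-coverage flag (study inclusion asked for at least 3 complete days).
    """
    if len(trace) == 0:
        raise ContractError("cgm_metrics: empty trace")
    values = trace.values[np.isfinite(trace.values)]
    if values.size == 0:
        raise ContractError("cgm_metrics: trace has no glucose values")
    low_coverage = _complete_days(trace) < min_complete_days
    if low_coverage:
        warnings.warn(
            f"{trace.participant_id}: fewer than {min_complete_days} complete days",
            stacklevel=2,
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    cv = 100.0 * sd / mean
    tir = 100.0 * float(np.mean((values >= range_low) & (values <= range_high)))
    epoched = trace if trace.epoch_seconds == 300 else to_epochs(trace, 300)
    peaks = detect_peaks(epoched)
    mage = float(np.mean([p.amplitude for p in peaks])) if peaks else 0.0
    return CGMMetrics(
        mean_glucose=mean,
        sd_glucose=sd,
        cv_percent=cv,
        tir_percent=tir,
        mage=mage,
        n_excursions=len(peaks),
        low_coverage=low_coverage,
    )


def _segments(values: np.ndarray, max_gap_epochs: int) -> list[tuple[int, int]]:
    """Half-open index ranges separated by missing runs longer than the gap."""
    finite = np.isfinite(values)
    segs: list[tuple[int, int]] = []
    start = None
    gap = 0
    for i, ok in enumerate(finite):
        if ok:
            if start is None:
                start = i
            gap = 0
        else:
            if start is not None:
                gap += 1
                if gap > max_gap_epochs:
                    end = i - gap + 1
                    segs.append((start, end))
                    start = None
                    gap = 0
    if start is not None:
        # trim trailing missing epochs
        end = len(values)
        while end > start and not finite[end - 1]:
            end -= 1
        segs.append((start, end))
    return segs


def _centered_ma(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with symmetric shrinking at the boundaries.

    The half-width shrinks to ``min(h, i, n-1-i)`` near the edges so the
    window stays symmetric around each point; a linear trend therefore maps
    to itself and produces no spurious short-long crossings at the ends.
    """
    n = len(values)
    h = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    hw = np.minimum(np.minimum(idx, n - 1 - idx), h)
    lo = idx - hw
    hi = idx + hw + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def _alternating_extrema(
    diff: np.ndarray, raw: np.ndarray
) -> list[tuple[int, int]]:
    """Per-crossing-run raw extrema as (index, kind) with kind +1 max / -1 min.

    Runs where the short MA sits above the long MA contribute a local maximum
    of the raw trace, runs below contribute a minimum; adjacent same-kind
    extrema (possible when a run's sign is ambiguous at zero) keep the more
    extreme one so the sequence alternates.
    """
    sign = np.sign(diff)
    # carry the previous sign through exact zeros
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    if len(sign) and sign[0] == 0:
        nz = np.flatnonzero(sign)
        sign[0] = sign[nz[0]] if nz.size else 1.0

    extrema: list[tuple[int, int]] = []
    run_start = 0
    for i in range(1, len(sign) + 1):
        if i == len(sign) or sign[i] != sign[run_start]:
            seg = raw[run_start:i]
            if sign[run_start] >= 0:
                idx = run_start + int(np.nanargmax(seg))
                kind = 1
            else:
                idx = run_start + int(np.nanargmin(seg))
                kind = -1
            if extrema and extrema[-1][1] == kind:
                prev_idx, _ = extrema[-1]
                better = raw[idx] > raw[prev_idx] if kind == 1 else raw[idx] < raw[prev_idx]
                if better:
                    extrema[-1] = (idx, kind)
            else:
                extrema.append((idx, kind))
            run_start = i
    return extrema


def detect_peaks(
    trace: GlucoseTrace,
    short_ma: int = SHORT_MA_EPOCHS,
    long_ma: int = LONG_MA_EPOCHS,
    threshold_sd_mult: float = 1.0,
) -> list[PeakCall]:
    """MAGE-style glycemic-excursion calls on a 5-min epoched trace.

    Gaps longer than one hour split the trace into independently processed
    segments (shorter gaps are bridged by linear interpolation for the
    moving averages only).  The amplitude threshold is ``threshold_sd_mult``
    times the SD of the whole epoched trace.  Extrema are located on the raw
    trace so peak times coincide with the visible excursion apex.
    """
    if len(trace) < long_ma:
        warnings.warn("trace shorter than the long moving average; no peaks called",
                      stacklevel=2)
        return []
    values = trace.values
    sd = float(np.nanstd(values, ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        return []
    threshold = threshold_sd_mult * sd
    max_gap_epochs = int(3600 // trace.epoch_seconds)

    calls: list[PeakCall] = []
    for start, end in _segments(values, max_gap_epochs):
        seg = pd.Series(values[start:end]).interpolate(limit_area="inside")
        raw = seg.to_numpy()
        if len(raw) < 3:
            continue
        short = _centered_ma(raw, short_ma)
        long_ = _centered_ma(raw, long_ma)
        extrema = _alternating_extrema(short - long_, raw)
        for (i0, k0), (i1, k1) in zip(extrema, extrema[1:]):
            if k0 == -1 and k1 == 1:
                amplitude = raw[i1] - raw[i0]
                if amplitude >= threshold and amplitude > 0:
                    calls.append(
                        PeakCall(
                            nadir_time=trace.times[start + i0],
                            nadir_value=float(raw[i0]),
                            peak_time=trace.times[start + i1],
                            peak_value=float(raw[i1]),
                        )
                    )
    calls.sort(key=lambda p: p.peak_time)
    return calls


def classify_glucose_status(
    metrics: CGMMetrics,
    mean_max: float = 108.0,
    cv_max: float = 36.0,
    tir_min: float = 70.0,
) -> str:
    """Flag participants whose CGM summary departs from normal homeostasis.

    Cutoffs are strict inequalities: a participant sitting exactly on a
    boundary is still ``normal``.
    """
    flagged = (
        metrics.mean_glucose > mean_max
        or metrics.cv_percent > cv_max
        or metrics.tir_percent < tir_min
    )
    return "flagged" if flagged else "normal"
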