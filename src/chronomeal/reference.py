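"""Naive reference implementations used to cross-check the fast paths.

These are deliberately simple, exhaustive procedures — the kind one would
apply by hand — kept algorithmically independent of the production code so
the two routes can be compared in tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _turning_points(v: np.ndarray) -> list[int]:
    """Alternating local extrema of a series, endpoints included."""
    d = np.sign(np.diff(v))
    d[d == 0] = 1  # flats continue the previous direction
    idx = np.flatnonzero(d[1:] != d[:-1]) + 1
    return [0, *idx.tolist(), len(v) - 1]


def turning_point_peaks(
    values: np.ndarray, threshold_sd_mult: float = 1.0
) -> tuple[list[int], list[float]]:
    """Glycemic-excursion peaks by exhaustive turning-point enumeration.

    The classic manual procedure behind MAGE: list every turning point of
    the trace, iteratively merge away the smallest adjacent swing while it
    stays below ``threshold_sd_mult`` x SD(trace), then report each
    remaining upswing's peak index and nadir-to-peak amplitude.  When a
    sub-threshold swing touches a trace boundary the more extreme of its two
    points survives, so truncated excursions keep their apex.
    """
    v = pd.Series(np.asarray(values, dtype=float)).interpolate(
        limit_area="inside"
    ).to_numpy()
    sd = float(np.nanstd(values, ddof=1))
    if not np.isfinite(sd) or sd == 0.0 or len(v) < 3:
        return [], []
    thr = threshold_sd_mult * sd

    tp = _turning_points(v)
    while len(tp) > 2:
        swings = [abs(v[tp[i + 1]] - v[tp[i]]) for i in range(len(tp) - 1)]
        j = int(np.argmin(swings))
        if swings[j] >= thr:
            break
        if j == 0:
            # merge into the run ending at tp[2]: keep the boundary extremum
            # opposite in kind to tp[2]
            rising_next = v[tp[2]] > v[tp[1]]
            keep = tp[0] if (v[tp[0]] < v[tp[1]]) == rising_next else tp[1]
            tp = [keep] + tp[2:]
        elif j == len(tp) - 2:
            rising_prev = v[tp[-2]] > v[tp[-3]]
            keep = tp[-2] if (v[tp[-2]] > v[tp[-1]]) == rising_prev else tp[-1]
            tp = tp[:-2] + [keep]
        else:
            del tp[j : j + 2]

    peaks: list[int] = []
    amplitudes: list[float] = []
    for a, b in zip(tp, tp[1:]):
        rise = v[b] - v[a]
        if rise >= thr:
            peaks.append(b)
            amplitudes.append(float(rise))
    return peaks, amplitudes
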