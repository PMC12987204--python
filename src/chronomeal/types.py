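"""Domain types shared across the pipeline.

All timestamps are timezone-naive local clock times: the study devices are
synchronised to the participant's phone clock and the analysis never crosses
time zones.  Missing measurements are NaN, never dropped rows, so every trace
keeps an explicit record of its coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

MealType = Literal["breakfast", "lunch", "dinner", "snack", "unknown"]
EntryMode = Literal["prospective", "retrospective", "na"]
Source = Literal["KE", "KW"]

MAIN_MEALS: tuple[str, ...] = ("breakfast", "lunch", "dinner")
MEAL_TYPES: tuple[str, ...] = ("breakfast", "lunch", "dinner", "snack")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ContractError(ValueError):
    """An operation was called outside its precondition."""


class ParameterError(ValueError):
    """A configuration or simulation parameter is out of range."""


def _check_grid(times: pd.DatetimeIndex, epoch_seconds: int, what: str) -> None:
    if epoch_seconds <= 0:
        raise ParameterError(f"{what}: epoch_seconds must be positive")
    if len(times) > 1:
        deltas = np.diff(times.asi8) / 1e9
        if np.any(deltas <= 0):
            i = int(np.argmax(deltas <= 0))
            raise ContractError(
                f"{what}: timestamps not strictly increasing at row {i + 1}"
            )
        if np.any(np.abs(np.round(deltas / epoch_seconds) * epoch_seconds - deltas) > 1e-6):
            raise ContractError(
                f"{what}: timestamp spacing is not a multiple of {epoch_seconds} s"
            )


@dataclass
class GlucoseTrace:
    """One participant's interstitial glucose series on a regular epoch grid.

    ``values`` holds glucose in mg/dL with NaN for missing epochs.  Native
    sensor cadence is 60 s; analysis runs on 300 s epochs.
    """

    participant_id: str
    times: pd.DatetimeIndex
    values: np.ndarray
    epoch_seconds: int

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ContractError("GlucoseTrace: times and values length mismatch")
        _check_grid(self.times, self.epoch_seconds, "GlucoseTrace")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() <= 20 or finite.max() >= 500):
            raise ContractError("GlucoseTrace: glucose outside (20, 500) mg/dL")

    def __len__(self) -> int:
        return len(self.times)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.times, name="glucose_mg_dl")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass
class ACMTrace:
    """Wrist-device record: movement intensity, distal skin temperature, light.

    MI is summed absolute triaxial acceleration per epoch (G/epoch); DST is
    wrist temperature in degrees C.  The event marker flags epochs where the
    wearer pressed the meal button.
    """

    participant_id: str
    times: pd.DatetimeIndex
    mi: np.ndarray
    dst: np.ndarray
    light_total: np.ndarray
    light_blue: np.ndarray
    light_ir: np.ndarray
    marker: np.ndarray
    epoch_seconds: int = 30

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        n = len(self.times)
        for name in ("mi", "dst", "light_total", "light_blue", "light_ir"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ContractError(f"ACMTrace: {name} length mismatch")
            setattr(self, name, arr)
        self.marker = np.asarray(self.marker, dtype=bool)
        if len(self.marker) != n:
            raise ContractError("ACMTrace: marker length mismatch")
        _check_grid(self.times, self.epoch_seconds, "ACMTrace")
        if len(self.times) > 1:
            deltas = np.unique(np.diff(self.times.asi8))
            if len(deltas) > 1:
                raise ContractError("ACMTrace: timestamp step is not fixed")
        if np.any(self.mi[np.isfinite(self.mi)] < 0):
            raise ContractError("ACMTrace: negative movement intensity")

    def __len__(self) -> int:
        return len(self.times)

    def signal(self, name: str) -> pd.Series:
        return pd.Series(getattr(self, name), index=self.times, name=name)


@dataclass(frozen=True)
class MealEvent:
    """A declared eating occasion from either device.

    KE (smartphone app) events carry a meal type and an entry mode; KW (wrist
    marker button) events carry neither, so they take ``unknown`` / ``na``.
    Retrospective entries are restricted to main meals.
    """

    participant_id: str
    timestamp: pd.Timestamp
    source: str = "KE"
    meal_type: str = "unknown"
    entry_mode: str = "na"

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", pd.Timestamp(self.timestamp))
        if self.source not in ("KE", "KW"):
            raise ContractError(f"MealEvent: unknown source {self.source!r}")
        if self.meal_type not in MEAL_TYPES + ("unknown",):
            raise FormatError(f"MealEvent: unknown meal_type {self.meal_type!r}")
        if self.entry_mode not in ("prospective", "retrospective", "na"):
            raise FormatError(f"MealEvent: unknown entry_mode {self.entry_mode!r}")
        if self.source == "KW":
            if self.meal_type != "unknown" or self.entry_mode != "na":
                raise ContractError(
                    "MealEvent: KW events carry no meal type or entry mode"
                )
        if self.entry_mode == "retrospective" and self.meal_type not in MAIN_MEALS:
            raise ContractError(
                "MealEvent: retrospective annotation is restricted to main meals"
            )


@dataclass(frozen=True)
class CoupledEvent:
    """A KE annotation with its matched KW marker, if one lies within the window."""

    ke_event: MealEvent
    kw_event: Optional[MealEvent] = None
    lag_minutes: Optional[float] = None  # kw - ke, signed

    @property
    def coupled(self) -> bool:
        return self.kw_event is not None


@dataclass(frozen=True)
class PeakCall:
    """One detected glycemic excursion: the nadir-to-peak upswing."""

    nadir_time: pd.Timestamp
    nadir_value: float
    peak_time: pd.Timestamp
    peak_value: float

    def __post_init__(self) -> None:
        if not self.nadir_time < self.peak_time:
            raise ContractError("PeakCall: nadir must precede peak")
        if self.amplitude <= 0:
            raise ContractError("PeakCall: amplitude must be positive")

    @property
    def amplitude(self) -> float:
        return self.peak_value - self.nadir_value


@dataclass(frozen=True)
class LinkedMeal:
    """A meal annotation with its nearest subsequent glucose peak, or unlinked.

    ``lag_minutes`` is the candidate lag even when the event is unlinked
    (lag beyond the window), so distance distributions can still be plotted.
    """

    event: MealEvent
    peak: Optional[PeakCall] = None
    lag_minutes: Optional[float] = None
    linked: bool = False


@dataclass
class CGMMetrics:
    """Per-participant CGM summary: mean, SD, CV, time in range and MAGE."""

    mean_glucose: float
    sd_glucose: float
    cv_percent: float
    tir_percent: float
    mage: float
    n_excursions: int = 0
    low_coverage: bool = False

    @property
    def has_excursions(self) -> bool:
        return self.n_excursions > 0


@dataclass
class AccuracyTable:
    """Peak-related accuracy per meal type plus an overall row.

    ``table`` columns: meal_type, n_linked, n_total, accuracy_percent
    (half-up rounded to one decimal); ``raw_fractions`` keeps the unrounded
    values.
    """

    table: pd.DataFrame
    raw_fractions: dict[str, float]

    def accuracy(self, meal_type: str) -> float:
        row = self.table.loc[self.table["meal_type"] == meal_type]
        if row.empty:
            raise KeyError(meal_type)
        return float(row["accuracy_percent"].iloc[0])


@dataclass
class WindowStack:
    """Equal-length event-anchored windows of one signal.

    Rows are events, columns are minute offsets relative to the anchor; the
    mean/SEM curves aggregate over non-missing entries per offset.
    """

    anchor_kind: str  # "meal_time" | "glucose_peak"
    signal: str  # "glucose" | "mi" | "dst"
    offsets: np.ndarray  # minutes relative to anchor
    rows: np.ndarray  # (n_events, n_offsets) with NaN padding
    anchor_ids: list[str]

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.shape[1] != len(self.offsets):
            raise ContractError("WindowStack: rows/offsets shape mismatch")

    @property
    def n_per_offset(self) -> np.ndarray:
        return np.sum(np.isfinite(self.rows), axis=0)

    @property
    def mean_curve(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(np.where(np.isfinite(self.rows), self.rows, np.nan), axis=0)

    @property
    def sem_curve(self) -> np.ndarray:
        """Standard error per offset; NaN where fewer than two windows contribute."""
        n = self.n_per_offset.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            sd = np.nanstd(self.rows, axis=0, ddof=1)
            sem = sd / np.sqrt(n)
        sem[n < 2] = np.nan
        return sem


@dataclass
class PrePostContrast:
    """Per-participant pre- vs post-anchor means of one signal."""

    participant_id: str
    pre_mean: float
    post_mean: float
    pre_minutes: float
    post_minutes: float


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test."""

    method: str
    statistic: float
    p_value: float
    n: int
    adjusted: bool = False
    label: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ContractError("TestResult: p-value outside [0, 1]")
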