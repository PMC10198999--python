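"""Core data containers for the phenology-extraction pipeline.

All GPP values are in g C m⁻² day⁻¹; all dates are day-of-year (DOY,
1-based). A "composite" is an 8-day aggregated observation assigned to the
first day of its window (DOY 1, 9, …, 361), giving 46 values per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InsufficientDataError(ValueError):
    """Raised when a pixel-year has too few usable observations.

    Callers that process many pixels catch this and emit the pixel as
    missing rather than aborting.
    """


@dataclass
class GppSeries:
    """A dated GPP sequence for one pixel/site and one calendar year.

    Missing observations are NaN in ``values``.
    """

    year: int
    doy: np.ndarray  # int, strictly increasing, 1-based
    values: np.ndarray  # float, NaN = missing
    cadence: int = 8  # composite length in days: 8 or 1

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.doy.shape != self.values.shape:
            raise ValueError("doy and values must have equal length")
        if np.any(np.diff(self.doy) <= 0):
            raise ValueError("doy must be strictly increasing")
        if self.cadence not in (1, 8):
            raise ValueError("cadence must be 1 (daily) or 8 (composite)")
        if self.cadence == 8 and self.doy.size > 46:
            raise ValueError("at most 46 composites per year")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < 0):
            raise ValueError("GPP values must be >= 0 or missing")

    @property
    def n_days(self) -> int:
        return 366 if _is_leap(self.year) else 365


@dataclass
class DailySeries:
    """Daily-resolution GPP for one year (interpolated, not yet smoothed)."""

    year: int
    doy: np.ndarray  # 1..365/366, contiguous
    values: np.ndarray


@dataclass
class SmoothedSeries:
    """Daily smoothed GPP (the smoothing-spline curve GPP_S) plus audit trail."""

    year: int
    doy: np.ndarray
    values: np.ndarray  # final Savitzky-Golay smooth
    n_iterations: int  # outer smoothing iterations performed (<= max_iter)
    replaced: np.ndarray  # bool per day: observation replaced by smooth value

    def value_at(self, days: np.ndarray) -> np.ndarray:
        """Smoothed values at the given (1-based) days."""
        return self.values[np.asarray(days, dtype=int) - 1]


@dataclass
class ChangePointSet:
    """PELT segmentation of a daily series.

    ``breakpoints`` are 1-based days where a new segment starts (the first
    segment implicitly starts at day 1); ``segment_means`` has one entry per
    segment, i.e. ``len(breakpoints) + 1``.
    """

    breakpoints: np.ndarray  # int, strictly increasing, within (1, n]
    segment_means: np.ndarray
    penalty: float
    min_segment_days: int
    n_days: int

    @property
    def segment_bounds(self) -> list[tuple[int, int]]:
        """Inclusive (start_day, end_day) per segment, 1-based."""
        starts = [1, *self.breakpoints.tolist()]
        ends = [*(b - 1 for b in self.breakpoints.tolist()), self.n_days]
        return list(zip(starts, ends))


@dataclass
class Extremum:
    """A bottom or peak of the segment-mean series."""

    kind: str  # "bottom" | "peak"
    day: int  # day of the smoothed-series extremum within the segment
    value: float  # segment mean (the baseline)
    seg_start: int
    seg_end: int


@dataclass
class Cycle:
    """One full photosynthesis cycle: Bottom1 → Peak → Bottom2.

    Baseline values are segment means of the PELT segmentation; the
    amplitude on each flank is peak minus the flanking bottom baseline.
    """

    bottom1_day: int
    bottom1_value: float
    peak_day: int
    peak_value: float
    bottom2_day: int
    bottom2_value: float

    def __post_init__(self) -> None:
        if not (self.bottom1_day < self.peak_day < self.bottom2_day):
            raise ValueError("cycle days must satisfy bottom1 < peak < bottom2")
        if self.rising_amplitude <= 0 or self.falling_amplitude <= 0:
            raise ValueError("cycle amplitudes must be positive")

    @property
    def rising_amplitude(self) -> float:
        return self.peak_value - self.bottom1_value

    @property
    def falling_amplitude(self) -> float:
        return self.peak_value - self.bottom2_value


@dataclass
class PhenologyMetrics:
    """SOS/EOS/LOS for one growing season at each amplitude threshold.

    Dates are real-valued DOY (threshold crossings linearly interpolated
    between adjacent days). ``sos``/``eos``/``los`` map threshold fraction
    (e.g. 0.25) to the date; a flank on which a threshold is unreachable is
    absent from the dicts, with the reason recorded in ``missing``.
    """

    year: int
    season_index: int  # 1 = first growing season of the year
    thresholds: tuple[float, ...]
    sos: dict[float, float]
    eos: dict[float, float]
    los: dict[float, float]
    cycle: Cycle | None = None
    missing: dict[float, str] = field(default_factory=dict)

    def to_record(self) -> dict:
        rec: dict = {"year": self.year, "season": self.season_index}
        for thr in self.thresholds:
            pct = int(round(thr * 100))
            rec[f"sos{pct}"] = self.sos.get(thr, np.nan)
            rec[f"eos{pct}"] = self.eos.get(thr, np.nan)
            rec[f"los{pct}"] = self.los.get(thr, np.nan)
        return rec


@dataclass
class UncertaintyEnvelope:
    """Bootstrap 5th/95th-percentile envelope for one metric value."""

    low: float
    up: float
    n_replicates: int  # successful replicates the percentiles are based on
    rng_seed: int


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
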