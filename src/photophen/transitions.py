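"""Transition dates: SOS, EOS and LOS at amplitude thresholds.

For a cycle with baselines Bottom₁, Peak, Bottom₂ (segment means) and a
threshold fraction ``thr``, the start of season is the day on the rising
flank at which the smoothed series reaches

    Bottom₁ + (Peak − Bottom₁) × thr

and the end of season the day on the falling flank at which it drops back
to Bottom₂ + (Peak − Bottom₂) × thr. Crossings are linearly interpolated
between adjacent days (real-valued DOY); the length of season is
EOS − SOS exactly.

Crossings are anchored at the peak: SOS is the *last* upward crossing of
the level before the peak, EOS the *first* downward crossing after it.
Scanning outward from the peak makes the dates immune to noise bumps
during dormancy, which can exceed the low 10 % level weeks away from the
season; a bump inside the season sits far above every level, so it cannot
truncate the season either. On a clean monotone flank the crossing is
unique and the scan direction is irrelevant.
"""

from __future__ import annotations

from .types import Cycle, PhenologyMetrics, SmoothedSeries


def _rise_crossing(vals, lo_day: int, peak_day: int, level: float) -> float | None:
    """Last upward crossing of ``level`` at or before ``peak_day``.

    Scans backward from the peak for the last day with vals < level; the
    crossing is interpolated between that day and the next. Returns
    ``lo_day`` if the series is already at/above the level there, None if
    the level is never reached on [lo_day, peak_day].
    """
    if vals[peak_day - 1] < level:
        return None
    for d in range(peak_day, lo_day - 1, -1):
        if vals[d - 1] < level:
            v0, v1 = vals[d - 1], vals[d]
            return d + (level - v0) / (v1 - v0)
    return float(lo_day)


def _fall_crossing(vals, peak_day: int, hi_day: int, level: float) -> float | None:
    """First downward crossing of ``level`` at or after ``peak_day``."""
    if vals[peak_day - 1] < level:
        return None
    for d in range(peak_day, hi_day + 1):
        if vals[d - 1] < level:
            v0, v1 = vals[d - 2], vals[d - 1]
            return (d - 1) + (v0 - level) / (v0 - v1)
    return float(hi_day)


def extract_transitions(cycle: Cycle,
                        smoothed: SmoothedSeries,
                        thresholds: tuple[float, ...] = (0.10, 0.25, 0.50),
                        year: int | None = None,
                        season_index: int = 1) -> PhenologyMetrics:
    """SOS/EOS/LOS of one cycle at each amplitude threshold.

    A threshold whose level is not reached on a flank (degenerate flat
    cycle) is omitted from the date dicts and recorded in ``missing``
    with a reason code.
    """
    vals = smoothed.values
    thresholds = tuple(sorted(thresholds))
    sos: dict[float, float] = {}
    eos: dict[float, float] = {}
    los: dict[float, float] = {}
    missing: dict[float, str] = {}
    for thr in thresholds:
        rise_level = cycle.bottom1_value + cycle.rising_amplitude * thr
        fall_level = cycle.bottom2_value + cycle.falling_amplitude * thr
        s = _rise_crossing(vals, cycle.bottom1_day, cycle.peak_day, rise_level)
        e = _fall_crossing(vals, cycle.peak_day, cycle.bottom2_day, fall_level)
        if s is None:
            missing[thr] = "rising flank never reaches threshold level"
            continue
        if e is None:
            missing[thr] = "falling flank never reaches threshold level"
            continue
        sos[thr] = s
        eos[thr] = e
        los[thr] = e - s
    return PhenologyMetrics(year=year if year is not None else smoothed.year,
                            season_index=season_index, thresholds=thresholds,
                            sos=sos, eos=eos, los=los, cycle=cycle,
                            missing=missing)
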