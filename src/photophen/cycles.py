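"""Bottoms, peaks, and full photosynthesis cycles.

The segment-mean series from the PELT segmentation is scanned with the
difference method: a peak is a segment whose mean exceeds both neighbours,
a bottom one below both neighbours (equal-mean neighbours are merged
first, so comparisons are strict). The first/last segments are admitted as
candidate bottoms so a season interior to the year can close.

Bottoms and peaks are the minimum and maximum of each *cycle*, not every
sign change of the differences: residual noise in the smoothed curve makes
the means of adjacent plateau segments wiggle by a few tenths of a
g C m⁻² day⁻¹, which would otherwise split one growing season into
several. Alternations whose amplitude falls below a fraction (default
0.25, the method's reliability constant) of the year's full segment-mean
range are therefore merged away before cycles are assembled.

Each (bottom, peak, bottom) triple then forms a full cycle; cycles whose
peak baseline falls below 0.25 of the year's maximum peak are discarded
as unreliable.
"""

from __future__ import annotations

import numpy as np

from .types import ChangePointSet, Cycle, Extremum, SmoothedSeries


def _merged_segments(cps: ChangePointSet) -> list[tuple[int, int, float]]:
    """(start_day, end_day, mean) with equal-mean adjacent segments merged."""
    segs: list[list] = []
    for (a, b), m in zip(cps.segment_bounds, cps.segment_means):
        if segs and segs[-1][2] == m:
            segs[-1][1] = b
        else:
            segs.append([a, b, m])
    return [tuple(s) for s in segs]


def _prune_shallow(extrema: list[Extremum], floor_abs: float) -> list[Extremum]:
    """Merge away alternations shallower than ``floor_abs``.

    Repeatedly removes the adjacent (bottom, peak) or (peak, bottom) pair
    with the smallest mean difference until every remaining alternation
    has amplitude >= ``floor_abs``. Removing an adjacent opposite-kind
    pair preserves the alternating structure.
    """
    ext = list(extrema)
    while len(ext) >= 2:
        amps = [abs(ext[i + 1].value - ext[i].value)
                for i in range(len(ext) - 1)]
        i = int(np.argmin(amps))
        if amps[i] >= floor_abs:
            break
        del ext[i:i + 2]
    return ext


def find_extrema(cps: ChangePointSet, smoothed: SmoothedSeries,
                 min_relative_amplitude: float = 0.25) -> list[Extremum]:
    """Difference-method bottoms and peaks of the segment-mean series.

    The representative day of an extremum is the day on which the smoothed
    series attains its min (bottom) or max (peak) within the segment,
    which guarantees bottom-day < SOS < peak-day orderings downstream.
    Alternations shallower than ``min_relative_amplitude`` times the full
    range of the segment means are merged away (see module docstring).
    The returned list alternates bottom/peak and starts and ends with a
    bottom whenever any peak exists.
    """
    segs = _merged_segments(cps)
    n = len(segs)
    vals = smoothed.values

    def _day(a: int, b: int, kind: str) -> int:
        window = vals[a - 1:b]
        off = int(np.argmin(window) if kind == "bottom" else np.argmax(window))
        return a + off

    extrema: list[Extremum] = []
    for i in range(1, n - 1):
        a, b, m = segs[i]
        if m > segs[i - 1][2] and m > segs[i + 1][2]:
            extrema.append(Extremum("peak", _day(a, b, "peak"), m, a, b))
        elif m < segs[i - 1][2] and m < segs[i + 1][2]:
            extrema.append(Extremum("bottom", _day(a, b, "bottom"), m, a, b))
    # year-edge segments serve as bottoms when the adjacent extremum is a
    # peak (a cycle truncated by the calendar boundary)
    if n >= 2 and (not extrema or extrema[0].kind == "peak"):
        a, b, m = segs[0]
        if m < segs[1][2]:
            extrema.insert(0, Extremum("bottom", _day(a, b, "bottom"), m, a, b))
    if n >= 2 and extrema and extrema[-1].kind == "peak":
        a, b, m = segs[-1]
        if m < segs[-2][2]:
            extrema.append(Extremum("bottom", _day(a, b, "bottom"), m, a, b))
    means = cps.segment_means
    floor_abs = min_relative_amplitude * float(means.max() - means.min())
    return _prune_shallow(extrema, floor_abs)


def assemble_cycles(extrema: list[Extremum]) -> list[Cycle]:
    """Form full cycles from alternating extrema.

    Every (bottom, peak, bottom) triple becomes one cycle; consecutive
    cycles share their common bottom. Peaks without a flanking bottom on
    both sides (truncated at the year edge) are dropped. No peaks → empty
    list.
    """
    cycles: list[Cycle] = []
    for i, ext in enumerate(extrema):
        if ext.kind != "peak" or i == 0 or i == len(extrema) - 1:
            continue
        b1, b2 = extrema[i - 1], extrema[i + 1]
        if b1.kind == "bottom" and b2.kind == "bottom":
            cycles.append(Cycle(bottom1_day=b1.day, bottom1_value=b1.value,
                                peak_day=ext.day, peak_value=ext.value,
                                bottom2_day=b2.day, bottom2_value=b2.value))
    return cycles


#: dormancy-plateau expansion band, as a fraction of the segment-mean
#: range: adjacent segments are part of the same dormancy plateau while
#: their means stay within this band of the running plateau mean. The
#: band must stay below the smallest mean step a true flank segment can
#: take (>= ~0.2 of the range for seasonal pulses at the minimum segment
#: length); 0.15 is the largest value that never swallows a flank
#: segment of a clean seasonal curve while averaging as much dormancy
#: as possible.
PLATEAU_BAND = 0.15


def _plateau_mean(segs: list[tuple[int, int, float]], idx: int,
                  band_abs: float) -> float:
    """Length-weighted mean of the dormancy plateau containing segment idx.

    A single minimum-mean segment understates the dormancy baseline (it
    is selected *because* its noise realization is low); averaging over
    the contiguous plateau removes that selection bias.
    """
    a, b, m = segs[idx]
    total = (b - a + 1) * m
    days = b - a + 1
    for step in (-1, 1):
        j = idx + step
        while 0 <= j < len(segs):
            a2, b2, m2 = segs[j]
            if abs(m2 - total / days) > band_abs:
                break
            total += (b2 - a2 + 1) * m2
            days += b2 - a2 + 1
            j += step
    return total / days


def _bottom_candidates(cps: ChangePointSet,
                       smoothed: SmoothedSeries) -> list[Extremum]:
    """All dormancy-bottom candidates: strict local-min segments plus the
    year-edge segments (which bound dormancy unconditionally)."""
    segs = _merged_segments(cps)
    vals = smoothed.values
    out = []
    for i, (a, b, m) in enumerate(segs):
        is_min = ((i == 0 or m < segs[i - 1][2])
                  and (i == len(segs) - 1 or m < segs[i + 1][2]))
        if is_min or i in (0, len(segs) - 1):
            day = a + int(np.argmin(vals[a - 1:b]))
            out.append(Extremum("bottom", day, m, a, b))
    return out


def detect_cycles(cps: ChangePointSet, smoothed: SmoothedSeries,
                  min_relative_amplitude: float = 0.25) -> list[Cycle]:
    """Extrema → cycles, with outer bottoms tied to the adjacent dormancy.

    The pruned alternation fixes the season structure (which peaks are
    real, which interior bottom two seasons share). On the outer flanks a
    long dormancy may contain several dips; the cycle's baseline is then
    the dip *adjacent* to the season — the nearest candidate bottom whose
    mean sits within the significance floor of the year minimum and at
    least the floor below the peak — rather than the deepest one, which
    can lie months away and misstate the pre-/post-season baseline.
    """
    extrema = find_extrema(cps, smoothed, min_relative_amplitude)
    cycles = assemble_cycles(extrema)
    if not cycles:
        return cycles
    means = cps.segment_means
    floor_abs = min_relative_amplitude * float(means.max() - means.min())
    year_min = float(means.min())
    cands = _bottom_candidates(cps, smoothed)

    def _nearest(peak_day: float, peak_value: float, side: str,
                 bound: int) -> Extremum | None:
        pool = [c for c in cands
                if (c.day < peak_day if side == "left" else c.day > peak_day)
                and (c.day > bound if side == "left" else c.day < bound)
                and peak_value - c.value >= floor_abs
                and c.value - year_min <= floor_abs]
        if not pool:
            return None
        return max(pool, key=lambda c: c.day) if side == "left" \
            else min(pool, key=lambda c: c.day)

    first, last = cycles[0], cycles[-1]
    b1 = _nearest(first.peak_day, first.peak_value, "left", 0)
    if b1 is not None:
        cycles[0] = Cycle(b1.day, b1.value, first.peak_day, first.peak_value,
                          first.bottom2_day, first.bottom2_value)
    last = cycles[-1]
    b2 = _nearest(last.peak_day, last.peak_value, "right", cps.n_days + 1)
    if b2 is not None:
        cycles[-1] = Cycle(last.bottom1_day, last.bottom1_value,
                           last.peak_day, last.peak_value, b2.day, b2.value)

    # de-bias the bottom baselines: average over the dormancy plateau
    segs = _merged_segments(cps)
    band_abs = PLATEAU_BAND * float(means.max() - means.min())

    def _baseline(day: int) -> float:
        idx = next(i for i, (a, b, _) in enumerate(segs) if a <= day <= b)
        return _plateau_mean(segs, idx, band_abs)

    out = []
    for c in cycles:
        b1v = min(_baseline(c.bottom1_day), c.peak_value - floor_abs)
        b2v = min(_baseline(c.bottom2_day), c.peak_value - floor_abs)
        out.append(Cycle(c.bottom1_day, b1v, c.peak_day, c.peak_value,
                         c.bottom2_day, b2v))
    return out


def filter_cycles(cycles: list[Cycle],
                  relative_peak_floor: float = 0.25) -> list[Cycle]:
    """Drop unreliable cycles: peak baseline below ``relative_peak_floor``
    of the maximum peak baseline of the same year.

    Order-preserving; the maximum-peak cycle always survives. The number
    of surviving cycles is the year's growing-season count.
    """
    if not cycles:
        return []
    max_peak = max(c.peak_value for c in cycles)
    return [c for c in cycles if c.peak_value >= relative_peak_floor * max_peak]
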