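"""Known-truth synthetic GPP series and grids.

The seasonal shape is a sum of double-logistic pulses on a baseline:

    GPP(t) = B + Σ_p A_p · [σ(k1_p (t − s1_p)) − σ(k2_p (t − s2_p))]

with σ the standard logistic. Sampling emulates the 8-day composite
cadence (46 values per year, composites stamped on DOY 1, 9, …, 361),
with additive Gaussian noise and optional spike outliers. Truth transition
dates are computed on the noise-free continuous curve by root finding, so
every downstream module can be scored against analytic truth without any
external data.

Default single-season parameters resemble a boreal forest pixel
(baseline 0.5, amplitude 8 g C m⁻² day⁻¹, inflections DOY 130/260,
slopes 0.15 day⁻¹, noise SD 0.5); the double-season default mimics a
double-cropping pixel with pulses centred near DOY 120 and 260.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import brentq

from .types import GppSeries

COMPOSITE_DOYS = np.arange(1, 362, 8)  # 46 composites, MODIS-style


@dataclass(frozen=True)
class Pulse:
    """One growing-season pulse of the double-logistic curve."""

    amplitude: float = 8.0  # g C m-2 day-1
    s1: float = 130.0  # rising inflection (DOY)
    s2: float = 260.0  # falling inflection (DOY)
    k1: float = 0.15  # rising slope (day-1)
    k2: float = 0.15  # falling slope (day-1)


@dataclass(frozen=True)
class SeriesParams:
    baseline: float = 0.5
    pulses: tuple[Pulse, ...] = (Pulse(),)
    noise_sd: float = 0.5
    outlier_days: tuple[int, ...] = ()
    outlier_magnitude: float = 10.0
    cadence: int = 8
    year: int = 2001


#: two pulses centred near DOY 120 and 260, as in double-cropping systems
DOUBLE_SEASON = SeriesParams(pulses=(
    Pulse(amplitude=8.0, s1=95.0, s2=150.0, k1=0.20, k2=0.20),
    Pulse(amplitude=6.0, s1=230.0, s2=290.0, k1=0.20, k2=0.20),
))

SINGLE_SEASON = SeriesParams()


@dataclass
class SyntheticTruth:
    """Analytic truth for one synthetic series."""

    params: SeriesParams
    seed: int
    # per season: peak day/value, bottoms, and {threshold: (sos, eos, los)}
    peak_days: list[float] = field(default_factory=list)
    crossings: list[dict[float, tuple[float, float, float]]] = field(
        default_factory=list)

    @property
    def n_seasons(self) -> int:
        return len(self.peak_days)


def _sigma(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def curve(t, params: SeriesParams):
    """Noise-free GPP at (array of) day ``t``."""
    t = np.asarray(t, dtype=float)
    out = np.full_like(t, params.baseline)
    for p in params.pulses:
        out = out + p.amplitude * (_sigma(p.k1 * (t - p.s1))
                                   - _sigma(p.k2 * (t - p.s2)))
    return out


def _season_windows(params: SeriesParams, n_days: int) -> list[tuple[float, float]]:
    """Per-pulse analysis windows split at midpoints between pulses."""
    pulses = sorted(params.pulses, key=lambda p: p.s1)
    edges = [1.0]
    for a, b in zip(pulses[:-1], pulses[1:]):
        edges.append(0.5 * (a.s2 + b.s1))
    edges.append(float(n_days))
    return list(zip(edges[:-1], edges[1:]))


def truth_crossings(params: SeriesParams,
                    thresholds: tuple[float, ...] = (0.10, 0.25, 0.50),
                    n_days: int = 365) -> SyntheticTruth:
    """Analytic threshold-crossing dates of the noise-free curve.

    Within each pulse's window: peak = curve maximum, bottoms = curve
    minima on either flank; the SOS/EOS at threshold ``thr`` solve
    curve(t) = bottom + thr × (peak − bottom) on the rising/falling flank
    (Brent root finding on a fine bracketing grid). Truth is a property of
    the continuous curve, independent of sampling cadence.
    """
    pulses = sorted(params.pulses, key=lambda p: p.s1)
    for a, b in zip(pulses[:-1], pulses[1:]):
        if a.s2 >= b.s1:
            raise ValueError("pulses overlap; truth windows are undefined")
    truth = SyntheticTruth(params=params, seed=-1)
    for (w0, w1), pulse in zip(_season_windows(params, n_days), pulses):
        grid = np.linspace(w0, w1, int((w1 - w0) * 8) + 2)
        vals = curve(grid, params)
        ipk = int(np.argmax(vals))
        tpk = grid[ipk]
        rise_t, rise_v = grid[:ipk + 1], vals[:ipk + 1]
        fall_t, fall_v = grid[ipk:], vals[ipk:]
        b1 = float(rise_v.min())
        b2 = float(fall_v.min())
        peak = float(vals[ipk])
        crossings: dict[float, tuple[float, float, float]] = {}
        for thr in thresholds:
            sos = _first_root(rise_t, rise_v, b1 + thr * (peak - b1), params)
            eos = _last_root(fall_t, fall_v, b2 + thr * (peak - b2), params)
            crossings[thr] = (sos, eos, eos - sos)
        truth.peak_days.append(float(tpk))
        truth.crossings.append(crossings)
    return truth


def _first_root(tt, vv, level, params):
    above = vv >= level
    i = int(np.argmax(above))  # first sample at/above level
    if i == 0:
        return float(tt[0])
    return brentq(lambda t: float(curve(t, params)) - level, tt[i - 1], tt[i])


def _last_root(tt, vv, level, params):
    above = vv >= level
    i = len(above) - 1 - int(np.argmax(above[::-1]))  # last sample above
    if i == len(tt) - 1:
        return float(tt[-1])
    return brentq(lambda t: float(curve(t, params)) - level, tt[i], tt[i + 1])


def make_series(params: SeriesParams | None = None,
                seed: int = 0,
                thresholds: tuple[float, ...] = (0.10, 0.25, 0.50),
                **overrides) -> tuple[GppSeries, SyntheticTruth]:
    """Sample a synthetic GPP series and its analytic truth.

    ``overrides`` patch fields of ``params`` (e.g. ``noise_sd=0``).
    Deterministic for a fixed seed.
    """
    p = params or SINGLE_SEASON
    if overrides:
        p = replace(p, **overrides)
    doys = COMPOSITE_DOYS if p.cadence == 8 else np.arange(1, 366)
    rng = np.random.default_rng(seed)
    values = curve(doys, p)
    if p.noise_sd > 0:
        values = values + rng.normal(0.0, p.noise_sd, doys.size)
    for day in p.outlier_days:
        idx = int(np.argmin(np.abs(doys - day)))
        values[idx] += p.outlier_magnitude
    values = np.clip(values, 0.0, None)
    series = GppSeries(year=p.year, doy=doys, values=values, cadence=p.cadence)
    truth = truth_crossings(p, thresholds)
    truth.seed = seed
    return series, truth


# ---------------------------------------------------------------------------
# gridded scenarios

SCENARIOS = ("uniform-single", "mixed-single-double", "masked-patches", "trend")


def make_grid(n_lat: int = 5,
              n_lon: int = 5,
              scenario: str = "uniform-single",
              seed: int = 0,
              years: tuple[int, ...] = (2001,),
              noise_sd: float = 0.5,
              trend_slope: float = -0.3,
              lat0: float = 45.025,
              lon0: float = 10.025) -> tuple[xr.Dataset, dict]:
    """Synthetic CF-style GPP cube plus per-pixel truth.

    Scenarios
    ---------
    uniform-single
        Every pixel carries the default single-season curve.
    mixed-single-double
        Alternate pixels (checkerboard) carry the double-season curve.
    masked-patches
        The top-left quadrant is scaled so its record maximum falls below
        the 2.0 g C m⁻² day⁻¹ vegetation floor.
    trend
        Single season whose whole curve shifts by ``trend_slope`` days per
        year across ``years``.

    Returns the cube (``gpp(time, lat, lon)``, 0.05° cell centres,
    ascending coordinates) and a truth dict with per-pixel expected season
    counts, mask flags, first-season crossing dates per year, and the
    IGBP land-cover grid (grasslands everywhere, class 10).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    lats = lat0 + 0.05 * np.arange(n_lat)
    lons = lon0 + 0.05 * np.arange(n_lon)
    times = []
    for yr in years:
        times.extend(np.datetime64(f"{yr}-01-01") + np.timedelta64(1, "D")
                     * (COMPOSITE_DOYS - 1))
    times = np.array(times)
    gpp = np.empty((times.size, n_lat, n_lon))
    season_count = np.ones((n_lat, n_lon), dtype=int)
    masked = np.zeros((n_lat, n_lon), dtype=bool)
    sos_truth = {}  # (year, threshold) -> 2-D array, season 1
    per_pixel_params = np.empty((n_lat, n_lon), dtype=object)
    for i in range(n_lat):
        for j in range(n_lon):
            p = SINGLE_SEASON
            if scenario == "mixed-single-double" and (i + j) % 2 == 1:
                p = DOUBLE_SEASON
                season_count[i, j] = 2
            if scenario == "masked-patches" and i < n_lat // 2 and j < n_lon // 2:
                p = replace(p, baseline=0.1, pulses=(
                    replace(p.pulses[0], amplitude=1.0),))
                masked[i, j] = True
            per_pixel_params[i, j] = replace(p, noise_sd=noise_sd)

    for i in range(n_lat):
        for j in range(n_lon):
            pix_seed = (seed ^ (i * n_lon + j)) & 0x7FFFFFFF
            rng = np.random.default_rng(pix_seed)
            for yi, yr in enumerate(years):
                p = per_pixel_params[i, j]
                if scenario == "trend":
                    shift = trend_slope * yi
                    p = replace(p, pulses=tuple(
                        replace(q, s1=q.s1 + shift, s2=q.s2 + shift)
                        for q in p.pulses))
                vals = curve(COMPOSITE_DOYS, p)
                if noise_sd > 0:
                    vals = vals + rng.normal(0.0, noise_sd, vals.size)
                vals = np.clip(vals, 0.0, None)
                if masked[i, j]:
                    # the drop set is part of the scenario's truth: pin the
                    # record maximum safely below the 2.0 vegetation floor
                    # whatever the noise draw
                    vals *= 1.5 / max(vals.max(), 1e-9)
                gpp[yi * 46:(yi + 1) * 46, i, j] = vals
                if not masked[i, j]:
                    tr = truth_crossings(p)
                    for thr, (sos, eos, los) in tr.crossings[0].items():
                        key = (yr, thr)
                        if key not in sos_truth:
                            sos_truth[key] = np.full((n_lat, n_lon), np.nan)
                        sos_truth[key][i, j] = sos

    cube = xr.Dataset(
        {"gpp": (("time", "lat", "lon"), gpp,
                 {"units": "g C m-2 day-1",
                  "long_name": "gross primary productivity"})},
        coords={"time": times, "lat": ("lat", lats, {"units": "degrees_north"}),
                "lon": ("lon", lons, {"units": "degrees_east"})})
    igbp = xr.DataArray(np.full((n_lat, n_lon), 10, dtype=np.int32),
                        coords={"lat": lats, "lon": lons}, name="igbp")
    truth = {"season_count": season_count, "masked": masked,
             "sos": sos_truth, "igbp": igbp,
             "trend_slope": trend_slope if scenario == "trend" else 0.0,
             "years": tuple(years), "seed": seed}
    return cube, truth


def grid_truth_frame(truth: dict) -> pd.DataFrame:
    """Truth dict flattened to one row per pixel (debug/QA helper)."""
    n_lat, n_lon = truth["season_count"].shape
    rows = []
    for i in range(n_lat):
        for j in range(n_lon):
            rows.append({"ilat": i, "ilon": j,
                         "season_count": int(truth["season_count"][i, j]),
                         "masked": bool(truth["masked"][i, j])})
    return pd.DataFrame(rows)
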