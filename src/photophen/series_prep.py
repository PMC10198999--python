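"""Raw GPP series → daily smoothed series.

Two steps: cubic-spline interpolation of 8-day composites to a daily grid,
then an iterative Savitzky-Golay smoothing loop in which a Grubbs test on
the daily/smooth ratios decides whether to continue and any day whose
ratio deviates from the mean ratio by more than one standard deviation is
replaced by the smooth value (up to 20 iterations).
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter
from scipy.stats import t as student_t

from .types import DailySeries, GppSeries, InsufficientDataError, SmoothedSeries

#: smooth values below this are excluded from the ratio vector — winter
#: zeros would otherwise produce unbounded ratios
RATIO_GUARD = 1e-6

#: more consecutive missing composites than this → pixel-year unusable
MAX_MISSING_RUN = 3


def read_series_csv(path: str | Path, cadence: int = 8) -> list[GppSeries]:
    """Read site series from CSV with columns ``date,gpp`` or ``year,doy,gpp``.

    ``date`` is ISO-8601; missing GPP as empty cell or NaN. Returns one
    :class:`GppSeries` per calendar year present, in year order.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "gpp" not in cols:
        raise ValueError("CSV must have a 'gpp' column")
    if "date" in cols:
        dates = pd.to_datetime(df[cols["date"]])
        df = df.assign(_year=dates.dt.year, _doy=dates.dt.dayofyear)
    elif "year" in cols and "doy" in cols:
        df = df.assign(_year=df[cols["year"]].astype(int),
                       _doy=df[cols["doy"]].astype(int))
    else:
        raise ValueError("CSV must have 'date' or 'year'+'doy' columns")
    out = []
    for year, grp in df.groupby("_year", sort=True):
        grp = grp.sort_values("_doy")
        out.append(GppSeries(year=int(year),
                             doy=grp["_doy"].to_numpy(),
                             values=pd.to_numeric(grp[cols["gpp"]],
                                                  errors="coerce").to_numpy(),
                             cadence=cadence))
    return out


def interpolate_to_daily(series: GppSeries) -> DailySeries:
    """Cubic-spline a composite series onto the daily grid of its year.

    Not-a-knot end conditions; the interpolant passes exactly through the
    observations. Days before the first / after the last observation are
    held at the nearest observed value (no extrapolation). Daily-cadence
    input passes through unchanged (missing days filled by the same
    spline).

    Raises
    ------
    InsufficientDataError
        Fewer than 4 usable observations, or a gap longer than
        ``MAX_MISSING_RUN`` consecutive missing composites.
    """
    ok = np.isfinite(series.values)
    _check_gaps(ok, series.cadence)
    if ok.sum() < 4:
        raise InsufficientDataError(
            f"only {int(ok.sum())} usable observations (need >= 4)")
    x = series.doy[ok].astype(float)
    y = series.values[ok]
    days = np.arange(1, series.n_days + 1)
    if series.cadence == 1 and ok.all() and x.size == days.size:
        return DailySeries(series.year, days, y.copy())
    spline = CubicSpline(x, y, bc_type="not-a-knot")
    vals = spline(days.astype(float))
    vals[days < x[0]] = y[0]
    vals[days > x[-1]] = y[-1]
    return DailySeries(series.year, days, vals)


def _check_gaps(ok: np.ndarray, cadence: int) -> None:
    run = 0
    limit = MAX_MISSING_RUN if cadence == 8 else MAX_MISSING_RUN * 8
    for flag in ok:
        run = 0 if flag else run + 1
        if run > limit:
            raise InsufficientDataError(
                f"gap of more than {limit} consecutive missing observations")


@lru_cache(maxsize=None)
def _grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for a sample of size n."""
    tcrit = student_t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(tcrit**2 / (n - 2 + tcrit**2))


def grubbs_flags_outlier(x: np.ndarray, alpha: float = 0.05) -> bool:
    """Two-sided Grubbs test: does the most extreme value of ``x`` deviate
    significantly from the sample mean?

    Returns False for degenerate input (n < 3 or zero variance), where the
    test is undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return False
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return False
    g = np.abs(x - x.mean()).max() / sd
    return bool(g > _grubbs_critical(x.size, alpha))


def iterative_smooth(daily: DailySeries,
                     window_days: int = 31,
                     polyorder: int = 3,
                     grubbs_alpha: float = 0.05,
                     max_iter: int = 20) -> SmoothedSeries:
    """Iterative Savitzky-Golay smoothing with Grubbs-gated outlier replacement.

    Each iteration: (1) smooth the daily series with a Savitzky-Golay
    filter; (2) form the ratio of each daily value to its smooth value
    (days with near-zero smooth excluded); (3) run a two-sided Grubbs test
    on the ratio vector — if it flags no outlier, stop; otherwise replace
    every day whose ratio lies more than one standard deviation from the
    mean ratio by its smooth value and iterate, up to ``max_iter`` times.

    Returns the Savitzky-Golay smooth of the final (outlier-replaced)
    series. ``n_iterations`` counts smoothing passes performed (a clean
    series terminates after 1); ``replaced`` marks every day ever replaced.
    """
    y = np.asarray(daily.values, dtype=float).copy()
    if window_days >= y.size:
        raise InsufficientDataError("smoothing window exceeds series length")
    replaced = np.zeros(y.size, dtype=bool)
    n_iterations = 0
    smooth = y
    for _ in range(max_iter):
        n_iterations += 1
        smooth = savgol_filter(y, window_days, polyorder, mode="interp")
        valid = smooth > RATIO_GUARD
        ratios = y[valid] / smooth[valid]
        if not grubbs_flags_outlier(ratios, grubbs_alpha):
            break
        dev = np.abs(ratios - ratios.mean())
        out = dev > ratios.std(ddof=1)
        if not out.any():
            break
        idx = np.flatnonzero(valid)[out]
        y[idx] = smooth[idx]
        replaced[idx] = True
    else:
        # hit the iteration cap: return the smooth of the last replacement
        smooth = savgol_filter(y, window_days, polyorder, mode="interp")
    return SmoothedSeries(year=daily.year, doy=daily.doy.copy(), values=smooth,
                          n_iterations=n_iterations, replaced=replaced)
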