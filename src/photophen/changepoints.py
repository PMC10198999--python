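"""Change-point detection on the smoothed daily series.

The segmentation is the exact minimizer of

    sum over segments of SSE(segment)  +  penalty x (number of changepoints)

with SSE the sum of squared deviations from the segment mean (Gaussian
change-in-mean cost), subject to a minimum segment length. The optimum is
found with PELT (Pruned Exact Linear Time): optimal partitioning by
dynamic programming, with candidates pruned once they can no longer be
optimal — pruning that provably preserves the exact optimum for this
cost. Ties are broken toward fewer changepoints, then earlier ones.
"""

from __future__ import annotations

import numpy as np

from .types import ChangePointSet, InsufficientDataError, SmoothedSeries


def _pelt_core(y: np.ndarray, beta: float, msize: int):
    """PELT dynamic program. Returns (F, prev, ncp) arrays over 0..n.

    F[t] is the optimal penalized cost of y[0:t] (with the convention
    F[0] = -beta so that each segment contributes +beta and the total
    equals SSE + beta * n_changepoints). prev[t] is the optimal last
    segment start for y[0:t].
    """
    n = y.size
    csum = np.zeros(n + 1)
    csum2 = np.zeros(n + 1)
    acc = 0.0
    acc2 = 0.0
    for i in range(n):
        acc += y[i]
        acc2 += y[i] * y[i]
        csum[i + 1] = acc
        csum2[i + 1] = acc2
    inf = np.inf
    F = np.full(n + 1, inf)
    F[0] = -beta
    ncp = np.zeros(n + 1, dtype=np.int64)
    prev = np.full(n + 1, -1, dtype=np.int64)
    cands = np.empty(n + 1, dtype=np.int64)
    death = np.empty(n + 1, dtype=np.int64)  # first t at which cand is dead
    cands[0] = 0
    death[0] = np.iinfo(np.int64).max
    ncand = 1
    big = np.iinfo(np.int64).max
    for t in range(msize, n + 1):
        best = inf
        best_ncp = 0
        best_s = -1
        for i in range(ncand):
            s = cands[i]
            if t >= death[i] or t - s < msize:
                continue
            ds = csum[t] - csum[s]
            cost = (csum2[t] - csum2[s]) - ds * ds / (t - s)
            v = F[s] + cost + beta
            if v < best or (v == best and ncp[s] + 1 < best_ncp):
                best = v
                best_ncp = ncp[s] + 1
                best_s = s
        F[t] = best
        prev[t] = best_s
        ncp[t] = best_ncp
        # PELT pruning, delayed by msize: once F[s] + C(s,t) > F[t], the
        # segmentation ending with a changepoint at t dominates s — but only
        # from t + msize onward, when t itself becomes an admissible segment
        # start (SSE subadditivity makes the domination permanent). Pruning
        # therefore schedules the removal rather than applying it at once,
        # which preserves exactness under the minimum-segment constraint.
        kept = 0
        for i in range(ncand):
            s = cands[i]
            d = death[i]
            if t + 1 >= d:
                continue  # dead from now on: drop for good
            if d == big and t - s >= msize:
                ds = csum[t] - csum[s]
                cost = (csum2[t] - csum2[s]) - ds * ds / (t - s)
                if F[s] + cost > F[t]:
                    d = t + msize
            cands[kept] = s
            death[kept] = d
            kept += 1
        ncand = kept
        # y[t:] may start a new segment at t
        cands[ncand] = t
        death[ncand] = big
        ncand += 1
    return F, prev, ncp


try:  # optional JIT: identical semantics, ~50x faster inner loop
    from numba import njit

    _pelt_core = njit(cache=False)(_pelt_core)  # type: ignore[assignment]
except ImportError:  # pragma: no cover - exercised only without numba
    pass


def pelt_segment(y: np.ndarray, penalty: float, min_size: int) -> tuple[np.ndarray, float]:
    """Segment a 1-D array; returns (segment start indices, penalized cost).

    Start indices are 0-based and include 0. The cost is
    SSE_total + penalty * n_changepoints.
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    n = y.size
    if n < 2 * min_size:
        raise InsufficientDataError(
            f"series of length {n} too short for two segments of {min_size}")
    F, prev, _ = _pelt_core(y, float(penalty), int(min_size))
    starts = []
    t = n
    while t > 0:
        s = int(prev[t])
        starts.append(s)
        t = s
    starts.reverse()
    return np.asarray(starts, dtype=int), float(F[n])


def pelt_changepoints(smoothed: SmoothedSeries,
                      penalty: float = 0.5,
                      min_segment_days: int = 14,
                      normalize: bool = False) -> ChangePointSet:
    """Detect change points in a smoothed daily series with PELT.

    ``penalty`` is applied per changepoint to the raw SSE of GPP in native
    units (g C m⁻² day⁻¹)². With ``normalize`` the series is z-scored
    before segmentation (breakpoint days unchanged, means recomputed on
    the native scale).
    """
    y = np.asarray(smoothed.values, dtype=float)
    z = (y - y.mean()) / y.std() if normalize and y.std() > 0 else y
    starts, _ = pelt_segment(z, penalty, min_segment_days)
    bounds = np.append(starts, y.size)
    means = np.array([y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    return ChangePointSet(breakpoints=starts[1:] + 1,  # 1-based start days
                          segment_means=means,
                          penalty=float(penalty),
                          min_segment_days=int(min_segment_days),
                          n_days=int(y.size))


def segment_mean_series(cps: ChangePointSet, smoothed: SmoothedSeries) -> np.ndarray:
    """Stepwise daily series: each day carries its segment's mean GPP."""
    out = np.empty(cps.n_days)
    for (a, b), m in zip(cps.segment_bounds, cps.segment_means):
        out[a - 1:b] = m
    return out
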