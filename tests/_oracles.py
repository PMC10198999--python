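"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity from its mathematical definition with
none of the package's code paths: an exhaustive optimal-partitioning
dynamic program for changepoints, a from-scratch not-a-knot cubic spline
built by solving the full piecewise-polynomial constraint system, and
definition-level agreement statistics.
"""

from __future__ import annotations

import numpy as np


def exhaustive_partition(y: np.ndarray, penalty: float,
                         min_size: int) -> tuple[float, tuple[int, ...]]:
    """Exact optimal partitioning by dynamic programming, no pruning.

    Returns (penalized cost, segment start indices incl. 0). Cost of a
    segmentation is sum of segment SSEs about their means plus
    ``penalty`` per changepoint. Ties break toward fewer changepoints,
    then earlier segment starts.
    """
    y = np.asarray(y, dtype=float)
    n = y.size

    def sse(a: int, b: int) -> float:
        seg = y[a:b]
        return float(((seg - seg.mean()) ** 2).sum())

    # best[t] = (cost, n_segments, starts) for y[:t]
    best: dict[int, tuple[float, int, tuple[int, ...]]] = {
        0: (-penalty, 0, ())}
    for t in range(min_size, n + 1):
        cands = []
        for s in range(0, t - min_size + 1):
            if s not in best:
                continue
            c0, k0, starts0 = best[s]
            cands.append((c0 + sse(s, t) + penalty, k0 + 1, starts0 + (s,)))
        if cands:
            best[t] = min(cands)
    cost, _, starts = best[n]
    return cost, starts


def notaknot_spline_eval(x: np.ndarray, y: np.ndarray,
                         xx: np.ndarray) -> np.ndarray:
    """Not-a-knot cubic interpolating spline built from first principles.

    Solves the full 4(n-1)-unknown constraint system (interpolation,
    C1/C2 continuity, third-derivative continuity at the second and
    second-to-last knots) with a dense linear solve, then evaluates the
    piecewise cubics at ``xx``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    m = n - 1  # intervals; cubic i: sum_k coef[i,k] * (t - x[i])**k
    A = np.zeros((4 * m, 4 * m))
    b = np.zeros(4 * m)
    row = 0

    def _basis(i: int, t: float, deriv: int) -> np.ndarray:
        out = np.zeros(4)
        dt = t - x[i]
        for k in range(deriv, 4):
            fac = 1.0
            for j in range(deriv):
                fac *= (k - j)
            out[k] = fac * dt ** (k - deriv)
        return out

    for i in range(m):  # interpolation at both ends of every interval
        A[row, 4 * i:4 * i + 4] = _basis(i, x[i], 0)
        b[row] = y[i]
        row += 1
        A[row, 4 * i:4 * i + 4] = _basis(i, x[i + 1], 0)
        b[row] = y[i + 1]
        row += 1
    for i in range(m - 1):  # C1 and C2 at interior knots
        for d in (1, 2):
            A[row, 4 * i:4 * i + 4] = _basis(i, x[i + 1], d)
            A[row, 4 * (i + 1):4 * (i + 1) + 4] = -_basis(i + 1, x[i + 1], d)
            row += 1
    for i in (0, m - 2):  # not-a-knot: C3 at x[1] and x[n-2]
        A[row, 4 * i:4 * i + 4] = _basis(i, x[i + 1], 3)
        A[row, 4 * (i + 1):4 * (i + 1) + 4] = -_basis(i + 1, x[i + 1], 3)
        row += 1
    coef = np.linalg.solve(A, b).reshape(m, 4)

    xx = np.asarray(xx, dtype=float)
    idx = np.clip(np.searchsorted(x, xx, side="right") - 1, 0, m - 1)
    dt = xx - x[idx]
    return (coef[idx, 0] + coef[idx, 1] * dt + coef[idx, 2] * dt**2
            + coef[idx, 3] * dt**3)


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form least-squares slope from the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc**2).sum())


def agreement_oracle(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(R, RMSE, bias) straight from the definitions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    am, bm = a - a.mean(), b - b.mean()
    r = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
    rmse = np.sqrt(((a - b) ** 2).mean())
    return float(r), float(rmse), float((a - b).mean())
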