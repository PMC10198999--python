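"""Agreement statistics between two phenology products.

Matched site-year-season records are compared per metric and threshold
with Pearson correlation, RMSE and mean bias. Sign convention: bias is
evaluated-product minus reference, so negative SOS bias means the
evaluated product starts the season *earlier* than the reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

MIN_MATCHED = 3


def agreement_stats(a, b) -> dict:
    """Pearson R, RMSE (days) and mean bias (days) between matched values.

    ``a`` is the evaluated product, ``b`` the reference (e.g. tower-based)
    product. Rows with a missing value on either side are refused: the
    caller matches records first. R is NaN when either column has zero
    variance (RMSE and bias are still reported).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("columns must have equal length")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("matched table must not contain missing values")
    n = a.size
    if n < MIN_MATCHED:
        raise ValueError(f"need at least {MIN_MATCHED} matched rows, got {n}")
    diff = a - b
    rmse = float(np.sqrt(np.mean(diff**2)))
    bias = float(np.mean(diff))
    if a.std() == 0 or b.std() == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(a, b).statistic)
    return {"R": r, "RMSE": rmse, "Bias": bias, "n": n}


def stratified_stats(table: pd.DataFrame,
                     value_a: str = "value_a",
                     value_b: str = "value_b",
                     strata: str | list[str] = "metric") -> pd.DataFrame:
    """Agreement statistics per stratum (e.g. per metric × threshold group,
    or per vegetation class).

    Strata with fewer than three matched rows are omitted with a note
    column rather than reported.
    """
    strata = [strata] if isinstance(strata, str) else list(strata)
    rows = []
    for keys, grp in table.groupby(strata):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(strata, keys))
        grp = grp.dropna(subset=[value_a, value_b])
        if len(grp) < MIN_MATCHED:
            row.update({"R": np.nan, "RMSE": np.nan, "Bias": np.nan,
                        "n": len(grp), "note": "too few matched rows"})
        else:
            row.update(agreement_stats(grp[value_a], grp[value_b]))
            row["note"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def match_products(a: pd.DataFrame, b: pd.DataFrame,
                   keys: list[str] | None = None,
                   metrics: list[str] | None = None) -> pd.DataFrame:
    """Join two product exports into a long matched table.

    Both frames carry identifier columns (default ``site, year, season``)
    plus metric columns (``sos10`` … ``los50``). The result has one row
    per matched identifier and metric with ``value_a``/``value_b``;
    rows where either side is missing are dropped. Matching is at
    identical thresholds only.
    """
    keys = keys or ["site", "year", "season"]
    metrics = metrics or [c for c in a.columns
                          if c not in keys and c in b.columns]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    parts = []
    for m in metrics:
        part = merged[keys].copy()
        part["metric"] = m
        part["value_a"] = merged[f"{m}_a"]
        part["value_b"] = merged[f"{m}_b"]
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    return out.dropna(subset=["value_a", "value_b"]).reset_index(drop=True)
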