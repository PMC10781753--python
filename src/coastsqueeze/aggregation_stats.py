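"""Summary aggregates: medians, below-threshold fractions, regional groupings.

Conventions (fixed for reproducibility):

* median = lower median for even counts (``sorted[(n-1)//2]``);
* percentiles are nearest-rank (``sorted[ceil(q·n)-1]``);
* "below threshold" is strict (``width < t``);
* censored records enter order statistics at their censor limit; a median
  is reported as a value only when it falls below the limit, otherwise it
  is flagged as a lower bound (``median > limit``).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .squeeze_measurement import effective_width

GROUP_GLOBAL = "global"
GROUP_COUNTRY = "country"
GROUP_CONTINENT = "continent"
GROUP_LAT_BAND = "lat_band"


def lower_median(values: np.ndarray) -> float:
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return float("nan")
    return float(v[(v.size - 1) // 2])


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return float("nan")
    rank = max(int(math.ceil(q * v.size)), 1)
    return float(v[rank - 1])


def censored_median(values: np.ndarray, limit: float) -> tuple[float, bool]:
    """Lower median of ``values`` (censored entries already at ``limit``).

    Returns ``(median, is_lower_bound)``: when the median reaches the
    censor limit the true median exceeds the limit and only a bound can be
    reported.
    """
    m = lower_median(values)
    return m, bool(np.isfinite(m) and m >= limit)


def _group_row(widths: np.ndarray, limit: float, thresholds: list[float]) -> dict:
    med, bound = censored_median(widths, limit)
    row = {
        "n": int(widths.size),
        "median_m": med,
        "median_is_lower_bound": bound,
        "p75_m": nearest_rank_percentile(widths, 0.75),
    }
    for t in thresholds:
        row[f"frac_below_{t:g}m"] = float(np.mean(widths < t)) if widths.size else float("nan")
    return row


def summarize(
    records: pd.DataFrame,
    assignment: pd.DataFrame | None = None,
    group_by: str = GROUP_GLOBAL,
    thresholds_m: list[float] = (100.0, 300.0),
    category: str = "all",
    band_deg: float = 1.0,
) -> pd.DataFrame:
    """Per-group n, median, 75th percentile and below-threshold fractions.

    ``records`` should already carry exclusion labels; only records with
    ``exclusion == 'none'`` (for the chosen category) are summarised.
    ``assignment`` (transect_id, country, continent, latitude_deg, …) is
    required for non-global groupings.
    """
    thresholds = list(thresholds_m)
    excl_col = "exclusion" if category == "all" else "exclusion_heavy"
    kept = records[records[excl_col] == "none"].reset_index(drop=True)
    if assignment is not None:
        kept = kept.merge(
            assignment, on="transect_id", how="left", suffixes=("", "_assign")
        )
    widths = effective_width(kept, category)
    limit = float(kept["censor_limit_m"].max()) if len(kept) else float("nan")

    if group_by == GROUP_GLOBAL:
        keys = pd.Series(["global"] * len(kept), name="group")
    elif group_by == GROUP_COUNTRY:
        keys = kept["country"].rename("group")
    elif group_by == GROUP_CONTINENT:
        keys = kept["continent"].rename("group")
    elif group_by == GROUP_LAT_BAND:
        lat = kept["latitude_deg"] if "latitude_deg" in kept else kept["latitude_deg_assign"]
        keys = (np.floor(lat / band_deg) * band_deg).rename("group")
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    rows = []
    for label, idx in pd.Series(np.arange(len(kept))).groupby(keys.values):
        w = widths[idx.to_numpy()]
        row = {"group": label}
        row.update(_group_row(w, limit, thresholds))
        rows.append(row)
    if not rows:
        rows = [{"group": "global", "n": 0, "median_m": float("nan"),
                 "median_is_lower_bound": False, "p75_m": float("nan"),
                 **{f"frac_below_{t:g}m": float("nan") for t in thresholds}}]
    return pd.DataFrame(rows)


def lat_band_profile(
    records: pd.DataFrame,
    assignment: pd.DataFrame | None = None,
    band_deg: float = 1.0,
    category: str = "all",
) -> pd.DataFrame:
    """Per latitude band (half-open ``[b, b + band)``) mean and median width.

    Both statistics are exposed because zonal bar summaries conventionally
    use the mean while squeeze comparisons use the median.
    """
    excl_col = "exclusion" if category == "all" else "exclusion_heavy"
    kept = records[records[excl_col] == "none"].reset_index(drop=True)
    if assignment is not None and "latitude_deg" not in kept:
        kept = kept.merge(assignment, on="transect_id", how="left")
    lat = kept["latitude_deg"].to_numpy(float)
    widths = effective_width(kept, category)
    bands = np.floor(lat / band_deg) * band_deg
    rows = []
    for b in np.unique(bands[np.isfinite(bands)]):
        w = widths[bands == b]
        rows.append(
            {
                "band_start_deg": float(b),
                "n": int(w.size),
                "mean_m": float(np.mean(w)),
                "median_m": lower_median(w),
            }
        )
    return pd.DataFrame(rows, columns=["band_start_deg", "n", "mean_m", "median_m"])
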