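"""Sea-level-rise exposure: projected retreat vs infrastructure-free width.

Each transect is matched to the nearest point of a shoreline-retreat
projection field (scenarios RCP 4.5 / RCP 8.5, 2100, positive values =
landward retreat).  The residual accommodation space is the
infrastructure-free width minus the projected retreat; a residual equal
to or smaller than zero means the infrastructure-free space is fully
consumed ("lost").  Matching tolerance defaults to 0.05 degrees
(~5.6 km): great-circle distance in the geographic frame, its
equatorial-meter equivalent (plain Euclidean) in the planar frame.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .squeeze_measurement import effective_width
from .transect_engine import GEOGRAPHIC, M_PER_DEG, Transect

SCENARIOS = ("rcp45", "rcp85")
MATCH_TOL_DEG = 0.05


def _unit_vectors(lon_deg: np.ndarray, lat_deg: np.ndarray) -> np.ndarray:
    lon = np.radians(lon_deg)
    lat = np.radians(lat_deg)
    return np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )


def match_retreat(
    transects: list[Transect],
    field: pd.DataFrame,
    tol_deg: float = MATCH_TOL_DEG,
    frame: str | None = None,
    metric: str = "great_circle",
) -> pd.DataFrame:
    """Nearest retreat-projection point per transect, within tolerance.

    ``field`` needs columns ``point_id, x, y, retreat_rcp45_m,
    retreat_rcp85_m`` (x/y are lon/lat in the geographic frame, meters in
    the planar one).  Ties in distance are broken toward the lowest point
    id.  ``metric='box'`` matches within a per-axis ±tol box instead of
    the great-circle/Euclidean disc.  Returns a DataFrame with one row per
    transect; unmatched transects have ``matched=False``.
    """
    if field.empty:
        raise ValueError("empty retreat field")
    if frame is None:
        frame = transects[0].frame if transects else GEOGRAPHIC
    origins = np.array([t.point_at(0.0) for t in transects], dtype=float)
    px = field["x"].to_numpy(float)
    py = field["y"].to_numpy(float)
    ids = field["point_id"].to_numpy()

    if frame == GEOGRAPHIC:
        tree = cKDTree(_unit_vectors(px, py))
        q = _unit_vectors(origins[:, 0], origins[:, 1])
        k = min(4, len(field))
        chord, idx = tree.query(q, k=k)
        chord = np.atleast_2d(chord.T).T
        idx = np.atleast_2d(idx.T).T
        ang = 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
        dist_deg = np.degrees(ang)
    else:
        tree = cKDTree(np.column_stack([px, py]))
        k = min(4, len(field))
        d, idx = tree.query(origins, k=k)
        d = np.atleast_2d(d.T).T
        idx = np.atleast_2d(idx.T).T
        dist_deg = d / M_PER_DEG

    rows = []
    for i, t in enumerate(transects):
        # tie-break among equal distances toward the lowest point id
        dd = dist_deg[i]
        order = np.lexsort((ids[idx[i]], np.round(dd / 1e-12)))
        j = idx[i][order[0]]
        d_best = float(dd[order[0]])
        if metric == "box":
            if frame == GEOGRAPHIC:
                sep = np.abs(origins[i] - np.array([px[j], py[j]]))
            else:
                sep = np.abs(origins[i] - np.array([px[j], py[j]])) / M_PER_DEG
            matched = bool(np.all(sep <= tol_deg))
        else:
            matched = d_best <= tol_deg
        row = {
            "transect_id": t.id,
            "matched": matched,
            "point_id": ids[j] if matched else -1,
            "match_distance_deg": d_best,
        }
        for sc in SCENARIOS:
            row[f"retreat_{sc}_m"] = float(field[f"retreat_{sc}_m"].iloc[j]) if matched else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def attach_residuals(records: pd.DataFrame, matches: pd.DataFrame,
                     category: str = "all") -> pd.DataFrame:
    """Join widths and matched retreats; residual = width − retreat,
    ``lost`` iff residual <= 0.  Censored widths stand at their censor
    limit, so they are never lost under any retreat below that limit.
    Negative retreat (shoreline advance) is not clamped."""
    merged = records.merge(matches, on="transect_id", how="left")
    w = effective_width(merged, category)
    for sc in SCENARIOS:
        merged[f"residual_{sc}_m"] = w - merged[f"retreat_{sc}_m"]
        merged[f"lost_{sc}"] = merged[f"residual_{sc}_m"] <= 0
    return merged


def exposure_fractions(
    records: pd.DataFrame,
    matches: pd.DataFrame,
    assignment: pd.DataFrame | None = None,
    group_by: str = "global",
    category: str = "all",
) -> pd.DataFrame:
    """Fraction of matched, non-excluded transects losing all
    infrastructure-free space, per scenario and group.  Unmatched
    transects are excluded from the denominator and counted."""
    excl_col = "exclusion" if category == "all" else "exclusion_heavy"
    kept = records[records[excl_col] == "none"]
    merged = attach_residuals(kept, matches, category)
    if group_by == "continent":
        if assignment is None:
            raise ValueError("continent grouping needs an assignment table")
        merged = merged.merge(assignment[["transect_id", "continent"]], on="transect_id")
        key = merged["continent"]
    else:
        key = pd.Series(["global"] * len(merged), index=merged.index)
    rows = []
    for label, grp in merged.groupby(key.values):
        m = grp["matched"].fillna(False).astype(bool)
        sub = grp[m]
        row = {
            "group": label,
            "n_matched": int(m.sum()),
            "n_unmatched": int((~m).sum()),
        }
        for sc in SCENARIOS:
            row[f"frac_lost_{sc}"] = (
                float(sub[f"lost_{sc}"].mean()) if len(sub) else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
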