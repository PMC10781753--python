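"""Natural-obstruction exclusions: cliffs, shoreline re-intersection, DEM limit.

A transect is excluded from the squeeze statistics when a natural barrier
occurs before the first structure:

* a slope steeper than the angle of repose of dry sand (34°, strict)
  seaward of the structure, read from an elevation model;
* a re-crossing of the shoreline (narrow strip or island) before the
  structure;
* latitude beyond the elevation model's northern validity limit (60°N),
  where slopes cannot be evaluated at all.

Precedence: DEM limit > shoreline re-intersection > cliff.  The cliff test
is evaluated independently per width category: a cliff between the first
paved path and the first building excludes the record for the ``all``
category but leaves the ``heavy`` one standing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .raster import Raster
from .squeeze_measurement import effective_width
from .transect_engine import Shoreline, Transect

logger = logging.getLogger(__name__)

ANGLE_OF_REPOSE_DEG = 34.0
DEM_LAT_MAX_DEG = 60.0

EXCL_NONE = "none"
EXCL_CLIFF = "cliff"
EXCL_REINTERSECT = "shoreline_reintersect"
EXCL_DEM = "beyond_dem_limit"

#: crossings closer to the origin than this are the transect's own shoreline
ORIGIN_TOL_M = 1.0

#: guard for the strict "steeper than" comparison: a ramp at exactly the
#: threshold angle must not be flagged despite float rounding in atan/tan
SLOPE_EPS_DEG = 1e-9


@dataclass
class SlopeProfile:
    """Along-transect elevation profile and finite-difference slopes.

    Slopes are ``atan(Δelevation / step)`` per station interval, positive
    when the terrain rises landward (a seaward-facing slope).
    ``first_steep_station_m`` is the along-transect start of the first
    interval strictly steeper than the threshold used to build the profile.
    """

    transect_id: int
    step_m: float
    elevations_m: np.ndarray
    slopes_deg: np.ndarray
    max_seaward_slope_deg: float
    first_steep_station_m: float | None
    valid: bool


def slope_profile(
    transect: Transect,
    dem: Raster,
    step_m: float = 30.0,
    steep_deg: float = ANGLE_OF_REPOSE_DEG,
) -> SlopeProfile:
    """Sample the DEM bilinearly along the transect and locate steep slopes."""
    if step_m <= 0:
        raise ValueError("step_m must be positive")
    pts = transect.stations(step_m)
    elev = dem.sample_bilinear(pts)
    if np.all(np.isnan(elev)):
        return SlopeProfile(
            transect_id=transect.id,
            step_m=step_m,
            elevations_m=elev,
            slopes_deg=np.full(max(len(elev) - 1, 0), np.nan),
            max_seaward_slope_deg=float("nan"),
            first_steep_station_m=None,
            valid=False,
        )
    rise = np.diff(elev)
    slopes = np.degrees(np.arctan(rise / step_m))
    finite = slopes[~np.isnan(slopes)]
    max_slope = float(finite.max()) if finite.size else float("nan")
    steep = np.nonzero(slopes > steep_deg + SLOPE_EPS_DEG)[0]
    first = float(steep[0] * step_m) if steep.size else None
    return SlopeProfile(
        transect_id=transect.id,
        step_m=step_m,
        elevations_m=elev,
        slopes_deg=slopes,
        max_seaward_slope_deg=max_slope,
        first_steep_station_m=first,
        valid=True,
    )


def reintersection_distance(transect: Transect, shoreline: Shoreline) -> float | None:
    """Smallest strictly positive distance at which the transect re-crosses
    any shoreline part; ``None`` if it never does within its length.
    Crossings within 1 m of the origin (the transect's own start on the
    shoreline) are ignored."""
    line = transect.line
    best = math.inf
    for part_line in shoreline.part_lines():
        inter = line.intersection(part_line)
        if inter.is_empty:
            continue
        coords = shapely.get_coordinates(inter)
        d = transect.metric_distance(coords)
        d = d[d > ORIGIN_TOL_M]
        if d.size:
            best = min(best, float(d.min()))
    return None if not np.isfinite(best) else best


def apply_exclusions(
    records: pd.DataFrame,
    profiles: dict[int, SlopeProfile],
    shoreline: Shoreline,
    transects: list[Transect],
    lat_max_deg: float = DEM_LAT_MAX_DEG,
    symmetric_lat_limit: bool = False,
) -> pd.DataFrame:
    """Fill the per-category ``exclusion`` columns of the width records.

    ``profiles`` maps transect id to its :class:`SlopeProfile`; a missing
    profile for a transect that is not already excluded by latitude is an
    error.  ``symmetric_lat_limit`` extends the DEM limit to |lat| (the
    stated limit is northern-hemisphere only).
    """
    out = records.copy()
    by_id = {t.id: t for t in transects}
    w_all = effective_width(out, "all")
    w_heavy = effective_width(out, "heavy")
    excl_all = []
    excl_heavy = []
    for i, row in enumerate(out.itertuples(index=False)):
        tid = row.transect_id
        lat = row.latitude_deg
        beyond = False
        if np.isfinite(lat):
            beyond = abs(lat) > lat_max_deg if symmetric_lat_limit else lat > lat_max_deg
        prof = profiles.get(tid)
        if not beyond and prof is not None and not prof.valid:
            beyond = True  # no usable elevation data along the transect
        if beyond:
            excl_all.append(EXCL_DEM)
            excl_heavy.append(EXCL_DEM)
            continue
        if prof is None:
            raise KeyError(f"missing slope profile for transect {tid}")
        tr = by_id[tid]
        re_d = reintersection_distance(tr, shoreline)
        ea = eh = EXCL_NONE
        if re_d is not None and re_d < w_all[i]:
            ea = EXCL_REINTERSECT
        elif prof.first_steep_station_m is not None and prof.first_steep_station_m < w_all[i]:
            ea = EXCL_CLIFF
        if re_d is not None and re_d < w_heavy[i]:
            eh = EXCL_REINTERSECT
        elif prof.first_steep_station_m is not None and prof.first_steep_station_m < w_heavy[i]:
            eh = EXCL_CLIFF
        excl_all.append(ea)
        excl_heavy.append(eh)
    out["exclusion"] = excl_all
    out["exclusion_heavy"] = excl_heavy
    return out


def exclusion_summary(records: pd.DataFrame, category: str = "all") -> pd.DataFrame:
    """Counts and fractions of transects per exclusion reason."""
    col = "exclusion" if category == "all" else "exclusion_heavy"
    counts = records[col].value_counts()
    total = len(records)
    return pd.DataFrame(
        {"reason": counts.index, "n": counts.values, "fraction": counts.values / total}
    )
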