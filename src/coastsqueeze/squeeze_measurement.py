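"""Infrastructure-free width: first structure intersection per transect.

Two squeeze proxies are measured along each transect:

* ``all`` — distance to the first hard human-made structure of any class
  (building, freeway, car road, paved bike/pedestrian path);
* ``heavy`` — distance to the first building or freeway only.

Distance is measured along the transect line; a feature that does not
cross the transect contributes nothing even if nearby.  Buildings are
polygons whose interiors count (a transect starting inside a building has
width 0); roads are centerline polylines crossed at the centerline.  A
transect with no qualifying structure within its length is censored at
the transect length, recorded as an explicit flag, never a sentinel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .transect_engine import Transect

logger = logging.getLogger(__name__)

ALL_CLASSES = ("building", "freeway", "car_road", "paved_path")
HEAVY_CLASSES = ("building", "freeway")
CATEGORY_CLASSES = {"all": frozenset(ALL_CLASSES), "heavy": frozenset(HEAVY_CLASSES)}

#: value used for the ``exclusion`` column before the obstruction filter runs
NO_EXCLUSION = "none"


@dataclass
class InfrastructureLayer:
    """Classed infrastructure features with a spatial index.

    ``features`` is a list of ``(geometry, class)`` pairs; classes must be
    one of ``ALL_CLASSES``.  Invalid geometries are skipped with a logged
    warning at query time.
    """

    features: list[tuple[BaseGeometry, str]]
    _tree: STRtree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for _, cls in self.features:
            if cls not in ALL_CLASSES:
                raise ValueError(f"unknown infrastructure class {cls!r}")

    @property
    def tree(self) -> STRtree | None:
        if self._tree is None and self.features:
            self._tree = STRtree([g for g, _ in self.features])
        return self._tree

    def __len__(self) -> int:
        return len(self.features)


def first_intersection_distance(
    transect: Transect, layer: InfrastructureLayer, category: str = "all"
) -> float | None:
    """Meters from the shore to the first selected structure, or ``None``
    if the transect is censored (no structure within its length)."""
    classes = CATEGORY_CLASSES[category]
    line = transect.line
    best = np.inf
    tree = layer.tree
    if tree is None:
        return None
    for idx in tree.query(line):
        geom, cls = layer.features[idx]
        if cls not in classes:
            continue
        if not geom.is_valid:
            logger.warning("skipping invalid %s geometry at index %d", cls, idx)
            continue
        inter = line.intersection(geom)
        if inter.is_empty:
            continue
        coords = shapely.get_coordinates(inter)
        d = transect.metric_distance(coords).min()
        best = min(best, d)
    if not np.isfinite(best):
        return None
    return float(min(best, transect.length_m))


def measure_all(
    transects: list[Transect],
    layer: InfrastructureLayer,
    latitudes: np.ndarray | None = None,
) -> pd.DataFrame:
    """One width record per transect (both categories), exclusion unset.

    Returns a DataFrame with columns ``transect_id, width_all_m,
    width_heavy_m, censored_all, censored_heavy, censor_limit_m,
    exclusion, exclusion_heavy, latitude_deg``.  Censored widths are NaN
    with the corresponding flag set.
    """
    rows = []
    for i, tr in enumerate(transects):
        lat = latitudes[i] if latitudes is not None else tr.latitude_deg
        w_all = first_intersection_distance(tr, layer, "all")
        w_heavy = first_intersection_distance(tr, layer, "heavy")
        rows.append(
            {
                "transect_id": tr.id,
                "width_all_m": np.nan if w_all is None else w_all,
                "width_heavy_m": np.nan if w_heavy is None else w_heavy,
                "censored_all": w_all is None,
                "censored_heavy": w_heavy is None,
                "censor_limit_m": tr.length_m,
                "exclusion": NO_EXCLUSION,
                "exclusion_heavy": NO_EXCLUSION,
                "latitude_deg": lat,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "transect_id",
            "width_all_m",
            "width_heavy_m",
            "censored_all",
            "censored_heavy",
            "censor_limit_m",
            "exclusion",
            "exclusion_heavy",
            "latitude_deg",
        ],
    )
    return df


def effective_width(records: pd.DataFrame, category: str = "all") -> np.ndarray:
    """Widths with censored records set to their censor limit.

    This is the working value for ordering comparisons (exclusion logic,
    below-threshold fractions); medians additionally apply the explicit
    censoring rule in :mod:`coastsqueeze.aggregation_stats`.
    """
    col = f"width_{category}_m"
    cen = records[f"censored_{category}"].to_numpy(bool)
    w = records[col].to_numpy(float).copy()
    w[cen] = records["censor_limit_m"].to_numpy(float)[cen]
    return w
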