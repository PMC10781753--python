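"""Shore-perpendicular transect casting.

Transects are fixed-length straight sampling lines cast landward from a
shoreline polyline at fixed arc-length interspacing (defaults: 25 km long,
1 km apart).  Only stations on segments classified as sandy receive a
transect.  Two coordinate frames are supported:

``planar_m``
    Cartesian coordinates in meters; all geometry is Euclidean.
``geographic_deg``
    Longitude/latitude in decimal degrees.  Each transect is cast in a
    local equirectangular frame centered on its origin (east/north axes
    scaled by ``cos(latitude)``), which keeps distortion over a 25-km
    transect negligible.  Distances are always expressed in meters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString

logger = logging.getLogger(__name__)

#: meters per degree of latitude (mean Earth radius 6 371 008.8 m)
M_PER_DEG = 111_194.92664455873

PLANAR = "planar_m"
GEOGRAPHIC = "geographic_deg"

_ANGLE_TOL = 1e-9


@dataclass
class ShorePart:
    """One continuous shoreline polyline with per-segment sandy flags.

    Parameters
    ----------
    vertices : (n, 2) array of vertex coordinates in the shoreline frame.
    sandy : (n - 1,) boolean array, one flag per segment; a scalar bool is
        broadcast over all segments.
    land_side : 'left' or 'right' of the vertex travel direction.
    """

    vertices: np.ndarray
    sandy: np.ndarray
    land_side: str = "left"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 2:
            raise ValueError("a shoreline part needs at least 2 vertices")
        if np.any(np.all(np.diff(self.vertices, axis=0) == 0, axis=1)):
            raise ValueError("consecutive duplicate vertices are forbidden")
        if self.land_side not in ("left", "right"):
            raise ValueError("land_side must be 'left' or 'right'")
        sandy = np.asarray(self.sandy)
        if sandy.ndim == 0:
            sandy = np.full(len(self.vertices) - 1, bool(sandy))
        if len(sandy) != len(self.vertices) - 1:
            raise ValueError("need one sandy flag per segment")
        self.sandy = sandy.astype(bool)


@dataclass
class Shoreline:
    """A collection of shoreline parts sharing one coordinate frame."""

    parts: list[ShorePart]
    frame: str = PLANAR

    def __post_init__(self) -> None:
        if self.frame not in (PLANAR, GEOGRAPHIC):
            raise ValueError(f"unknown frame {self.frame!r}")

    def part_lines(self) -> list[LineString]:
        """Shapely LineStrings of the parts, in native frame coordinates."""
        return [LineString(p.vertices) for p in self.parts]


@dataclass
class Transect:
    """A straight landward sampling line.

    ``origin`` is in the shoreline's native frame; ``azimuth`` is a unit
    vector in the local metric (east/north meters) frame.  ``point_at``
    maps an along-transect distance in meters back to native coordinates.
    """

    id: int
    origin: np.ndarray
    azimuth: np.ndarray
    length_m: float
    station_arc_m: float
    part_index: int = 0
    frame: str = PLANAR
    lat_ref: float = 0.0
    latitude_deg: float = field(default=float("nan"))

    def point_at(self, dist_m) -> np.ndarray:
        """Native-frame coordinates of the point(s) ``dist_m`` along the line."""
        d = np.asarray(dist_m, dtype=float)
        if self.frame == PLANAR:
            return self.origin + np.multiply.outer(d, self.azimuth)
        cos = math.cos(math.radians(self.lat_ref))
        step = np.multiply.outer(d, self.azimuth / np.array([M_PER_DEG * cos, M_PER_DEG]))
        return self.origin + step

    def stations(self, step_m: float) -> np.ndarray:
        """Station coordinates at ``0, step, 2·step, …`` up to the length."""
        n = int(math.floor(self.length_m / step_m + 1e-9))
        return self.point_at(np.arange(n + 1) * step_m)

    @property
    def line(self) -> LineString:
        return LineString([self.point_at(0.0), self.point_at(self.length_m)])

    def metric_distance(self, points: np.ndarray) -> np.ndarray:
        """Meters from the origin to native-frame ``points`` (n, 2)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        delta = pts - self.origin
        if self.frame == GEOGRAPHIC:
            cos = math.cos(math.radians(self.lat_ref))
            delta = delta * np.array([M_PER_DEG * cos, M_PER_DEG])
        return np.hypot(delta[:, 0], delta[:, 1])

    @property
    def azimuth_deg(self) -> float:
        """Compass azimuth (degrees clockwise from north/+y)."""
        return math.degrees(math.atan2(self.azimuth[0], self.azimuth[1])) % 360.0


def _segment_metric(part: ShorePart, frame: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment direction unit vectors and metric lengths (meters)."""
    diff = np.diff(part.vertices, axis=0)
    if frame == GEOGRAPHIC:
        mid_lat = 0.5 * (part.vertices[:-1, 1] + part.vertices[1:, 1])
        diff = diff * np.column_stack(
            [M_PER_DEG * np.cos(np.radians(mid_lat)), np.full(len(diff), M_PER_DEG)]
        )
    lengths = np.hypot(diff[:, 0], diff[:, 1])
    if np.any(lengths <= 0):
        raise ValueError("zero-length segment tangent")
    return diff / lengths[:, None], lengths


def local_tangent(shoreline: Shoreline, arc_m: float, part_index: int = 0) -> np.ndarray:
    """Unit tangent of a part at arc-length position ``arc_m`` (meters).

    Inside a segment the tangent is the segment direction.  At an interior
    vertex it is the angle bisector of the adjacent segment directions; for
    a 180-degree reversal (bisector undefined) the preceding segment's
    direction is used.  At the part's end the last segment's direction
    applies.
    """
    part = shoreline.parts[part_index]
    dirs, lengths = _segment_metric(part, shoreline.frame)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    total = cum[-1]
    if arc_m < -_ANGLE_TOL or arc_m > total + _ANGLE_TOL:
        raise ValueError(f"arc {arc_m} outside part length {total}")
    arc = min(max(arc_m, 0.0), total)
    # interior vertex hit (within tolerance): bisector convention
    hits = np.nonzero(np.abs(cum[1:-1] - arc) < 1e-6)[0]
    if hits.size:
        i = hits[0]  # vertex between segments i and i+1
        s = dirs[i] + dirs[i + 1]
        norm = np.hypot(*s)
        if norm < _ANGLE_TOL:  # 180° reversal: keep preceding direction
            return dirs[i]
        return s / norm
    seg = min(int(np.searchsorted(cum, arc, side="right")) - 1, len(dirs) - 1)
    return dirs[seg]


def _landward_normal(tangent: np.ndarray, land_side: str) -> np.ndarray:
    if land_side == "left":
        return np.array([-tangent[1], tangent[0]])
    return np.array([tangent[1], -tangent[0]])


def cast_transects(
    shoreline: Shoreline,
    spacing_m: float = 1000.0,
    length_m: float = 25_000.0,
) -> list[Transect]:
    """Cast fixed-length landward transects at fixed arc interspacing.

    Origins sit at arc-length multiples of ``spacing_m`` from each part's
    start (both endpoints included); only origins on sandy segments yield a
    transect.  Azimuths are the landward normal of the local tangent.
    """
    if spacing_m <= 0 or length_m <= 0:
        raise ValueError("spacing_m and length_m must be positive")
    transects: list[Transect] = []
    tid = 0
    for pi, part in enumerate(shoreline.parts):
        try:
            dirs, lengths = _segment_metric(part, shoreline.frame)
        except ValueError as exc:
            logger.warning("skipping shoreline part %d: %s", pi, exc)
            continue
        cum = np.concatenate([[0.0], np.cumsum(lengths)])
        total = cum[-1]
        n_stations = int(math.floor(total / spacing_m + 1e-9)) + 1
        for k in range(n_stations):
            arc = k * spacing_m
            seg = min(int(np.searchsorted(cum, arc + 1e-9, side="right")) - 1, len(dirs) - 1)
            seg = max(seg, 0)
            if not part.sandy[seg]:
                continue
            frac = (arc - cum[seg]) / lengths[seg]
            origin = part.vertices[seg] + frac * (part.vertices[seg + 1] - part.vertices[seg])
            tangent = local_tangent(shoreline, arc, pi)
            azimuth = _landward_normal(tangent, part.land_side)
            lat_ref = origin[1] if shoreline.frame == GEOGRAPHIC else 0.0
            transects.append(
                Transect(
                    id=tid,
                    origin=origin,
                    azimuth=azimuth,
                    length_m=length_m,
                    station_arc_m=arc,
                    part_index=pi,
                    frame=shoreline.frame,
                    lat_ref=lat_ref,
                    latitude_deg=origin[1] if shoreline.frame == GEOGRAPHIC else float("nan"),
                )
            )
            tid += 1
    return transects
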