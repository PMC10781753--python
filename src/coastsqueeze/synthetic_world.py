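"""Synthetic coastal worlds with known ground truth.

The generator builds every input layer the squeeze pipeline consumes — a
sandy shoreline, classed infrastructure features, an elevation model with
optional cliff ramps, a population-density raster with urban patches,
protected-area polygons, a shoreline-retreat field and a per-country GDP
table — and records, per 1-km shoreline station, the truth the pipeline
should recover: the placed infrastructure-free widths of both categories
(with explicit censoring flags, never sentinels), cliff/re-intersection
exclusion status, protection and urban labels.

Infrastructure is placed on the landward side only, at a perpendicular
offset drawn from the configured width distribution, so the true width
equals the placed offset by construction.  Worlds live in a planar
Cartesian frame in meters; a pseudo-geographic mode maps the alongshore
axis to latitude for exercising the DEM latitude limit and degree-based
retreat matching.

Placement exactness by coastline shape:

* ``straight`` — all truth columns exact; the only shape on which cliff
  ramps, urban patches and protected areas are generated (alongshore
  bands cannot interfere across shore-perpendicular transects).
* ``sinusoidal`` — infrastructure widths exact (gentle curvature keeps
  neighbouring transects from converging within 25 km); no cliffs,
  protection or urban variation.
* ``island`` / ``peninsula`` — shoreline re-intersection geometry with a
  known crossing distance; no infrastructure is placed (a structure on
  one shore could be nearer to a transect from the opposite shore, which
  would break placed-offset truth).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

from .raster import Raster
from .squeeze_measurement import ALL_CLASSES, HEAVY_CLASSES, InfrastructureLayer
from .transect_engine import (
    GEOGRAPHIC,
    M_PER_DEG,
    PLANAR,
    ShorePart,
    Shoreline,
    Transect,
    cast_transects,
)
from . import vectorio

CONTINENTS = ("Europe", "Asia", "Africa", "North America", "South America", "Oceania")


@dataclass(frozen=True)
class DistSpec:
    """A one-dimensional distribution: log-normal (median, log-sd sigma)
    or degenerate (fixed value)."""

    kind: str
    median: float = float("nan")
    sigma: float = float("nan")
    value: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind == "lognormal":
            if not (self.median > 0) or not (self.sigma >= 0):
                raise ValueError("lognormal needs median > 0 and sigma >= 0")
        elif self.kind == "fixed":
            if not np.isfinite(self.value):
                raise ValueError("fixed distribution needs a finite value")
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, float(self.value))
        return np.exp(rng.normal(np.log(self.median), self.sigma, size=n))

    @staticmethod
    def lognormal(median: float, sigma: float) -> "DistSpec":
        return DistSpec("lognormal", median=median, sigma=sigma)

    @staticmethod
    def fixed(value: float) -> "DistSpec":
        return DistSpec("fixed", value=value)


def _default_class_mix() -> dict[str, float]:
    return {"building": 0.40, "freeway": 0.10, "car_road": 0.35, "paved_path": 0.15}


@dataclass
class WorldSpec:
    """Parameters of a synthetic coastal world.

    Width and density defaults emulate the global study conditions: a
    positively skewed (log-normal) infrastructure-free width with median
    392 m, 7% of stations with no structure within reach, 4% cliff-limited
    stations, a 16% protected shore fraction whose widths are 4× larger,
    and the 300 persons/km² urban threshold straddled by the urban
    (1500/km²) and rural (50/km²) densities.
    """

    seed: int = 0
    coastline_shape: str = "straight"  # straight | sinusoidal | island | peninsula
    shore_length_km: float = 100.0
    land_side: str = "left"
    frame: str = PLANAR
    lat0_deg: float = 20.0
    lon0_deg: float = 0.0
    spacing_m: float = 1000.0
    transect_length_m: float = 25_000.0
    infra_width_distribution: DistSpec = field(
        default_factory=lambda: DistSpec.lognormal(392.0, 1.2)
    )
    infra_missing_fraction: float = 0.07
    infra_class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    heavy_gap_distribution: DistSpec = field(
        default_factory=lambda: DistSpec.lognormal(4.0, 0.5)
    )
    cliff_fraction: float = 0.04
    cliff_slope_deg: float = 45.0
    pop_urban_density: float = 1500.0
    pop_rural_density: float = 50.0
    urban_patch_fraction: float = 0.3
    urban_block_stations: int = 10
    protected_fraction: float = 0.16
    protected_width_multiplier: float = 4.0
    retreat_rcp45: DistSpec = field(default_factory=lambda: DistSpec.fixed(161.0))
    retreat_rcp85: DistSpec = field(default_factory=lambda: DistSpec.fixed(209.0))
    n_countries: int = 12
    gdp_per_capita: list[float] | None = None
    # geometry details
    feature_halfwidth_m: float = 40.0
    building_depth_m: float = 30.0
    sinusoid_amplitude_m: float = 300.0
    sinusoid_wavelength_m: float = 20_000.0
    strip_width_m: float = 3000.0
    dem_cellsize_m: float = 30.0
    dem_depth_m: float = 2940.0
    pop_cellsize_m: float = 1000.0

    def __post_init__(self) -> None:
        if self.coastline_shape not in ("straight", "sinusoidal", "island", "peninsula"):
            raise ValueError(f"unknown coastline_shape {self.coastline_shape!r}")
        if self.frame not in (PLANAR, GEOGRAPHIC):
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.frame == GEOGRAPHIC and self.coastline_shape != "straight":
            raise ValueError("the pseudo-geographic frame supports only a straight coast")
        mix_sum = sum(self.infra_class_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"infra_class_mix must sum to 1, got {mix_sum}")
        if set(self.infra_class_mix) - set(ALL_CLASSES):
            raise ValueError("infra_class_mix has unknown classes")
        for name in ("shore_length_km", "spacing_m", "transect_length_m",
                     "pop_urban_density", "pop_rural_density",
                     "protected_width_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("infra_missing_fraction", "cliff_fraction",
                     "urban_patch_fraction", "protected_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cliff_fraction > 0 and self.coastline_shape != "straight":
            raise ValueError("cliff ramps are only generated on a straight coast "
                             "(set cliff_fraction=0 for other shapes)")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SyntheticWorld:
    spec: WorldSpec
    shoreline: Shoreline
    transects: list[Transect]
    infrastructure: InfrastructureLayer
    dem: Raster
    population: Raster
    protected_areas: list[Polygon]
    retreat_points: pd.DataFrame
    truth: pd.DataFrame
    assignment: pd.DataFrame
    gdp: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Serialize every layer as text (GeoJSON / ESRI ASCII / CSV)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        vectorio.write_shoreline(self.shoreline, out / "shoreline.geojson")
        vectorio.write_infrastructure(self.infrastructure, out / "infrastructure.geojson")
        vectorio.write_protected_areas(self.protected_areas, out / "protected_areas.geojson")
        self.dem.write_ascii(out / "dem.asc")
        self.population.write_ascii(out / "population.asc")
        self.retreat_points.to_csv(out / "retreat_points.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        self.assignment.to_csv(out / "assignment.csv", index=False)
        self.gdp.to_csv(out / "gdp.csv", index=False)
        (out / "world_spec.json").write_text(self.spec.to_json())


# ---------------------------------------------------------------- geometry

def _planar_to_world(spec: WorldSpec, x_along: np.ndarray, y_cross: np.ndarray):
    """Map internal (alongshore, cross-shore) meters to world coordinates."""
    if spec.frame == PLANAR:
        return np.column_stack([x_along, y_cross])
    lat = spec.lat0_deg + np.asarray(x_along) / M_PER_DEG
    lon = spec.lon0_deg + np.asarray(y_cross) / (M_PER_DEG * np.cos(np.radians(lat)))
    return np.column_stack([lon, lat])


def _build_shoreline(spec: WorldSpec) -> Shoreline:
    length = spec.shore_length_km * 1000.0
    if spec.coastline_shape == "straight":
        xs = np.array([0.0, length])
        pts = _planar_to_world(spec, xs, np.zeros_like(xs))
        land_side = spec.land_side if spec.frame == PLANAR else "right"
        return Shoreline([ShorePart(pts, np.array([True]), land_side)], spec.frame)
    if spec.coastline_shape == "sinusoidal":
        xs = np.arange(0.0, length + 1.0, 100.0)
        ys = spec.sinusoid_amplitude_m * np.sin(2 * np.pi * xs / spec.sinusoid_wavelength_m)
        return Shoreline(
            [ShorePart(np.column_stack([xs, ys]), np.array(True), spec.land_side)],
            spec.frame,
        )
    if spec.coastline_shape == "island":
        radius = length / (2 * np.pi)
        n = max(int(round(length / 20.0)), 16)
        theta = np.linspace(0.0, 2 * np.pi, n + 1)  # CCW: land (interior) on left
        pts = radius * np.column_stack([np.cos(theta), np.sin(theta)])
        return Shoreline([ShorePart(pts, np.array(True), "left")], spec.frame)
    # peninsula: a strip of fixed width, both long shores sandy
    half = (length - 2 * spec.strip_width_m) / 2.0
    half = max(half, spec.spacing_m)
    bottom = np.array([[0.0, 0.0], [half, 0.0]])
    top = np.array([[half, spec.strip_width_m], [0.0, spec.strip_width_m]])
    return Shoreline(
        [
            ShorePart(bottom, np.array(True), "left"),
            ShorePart(top, np.array(True), "left"),
        ],
        spec.frame,
    )


def _offset_point(tr: Transect, d_along: float, d_perp: float) -> np.ndarray:
    """World coordinates of a point offset from a transect origin, given in
    along-transect / cross-transect meters."""
    az = tr.azimuth
    perp = np.array([-az[1], az[0]])
    vec = d_along * az + d_perp * perp
    if tr.frame == GEOGRAPHIC:
        cos = np.cos(np.radians(tr.lat_ref))
        vec = vec / np.array([M_PER_DEG * cos, M_PER_DEG])
    return tr.origin + vec


def _building_polygon(tr: Transect, dist: float, half: float, depth: float) -> Polygon:
    c = [
        _offset_point(tr, dist, -half),
        _offset_point(tr, dist, half),
        _offset_point(tr, dist + depth, half),
        _offset_point(tr, dist + depth, -half),
    ]
    return Polygon(c)


def _road_line(tr: Transect, dist: float, half: float) -> LineString:
    return LineString([_offset_point(tr, dist, -half), _offset_point(tr, dist, half)])


# ---------------------------------------------------------------- generator

def generate_world(spec: WorldSpec) -> SyntheticWorld:
    """Generate a synthetic world; identical specs give identical worlds."""
    rng = np.random.default_rng(spec.seed)
    shoreline = _build_shoreline(spec)
    transects = cast_transects(shoreline, spec.spacing_m, spec.transect_length_m)
    n = len(transects)
    length_m = spec.transect_length_m
    shape = spec.coastline_shape
    with_infra = shape in ("straight", "sinusoidal")
    with_labels = shape == "straight"  # cliffs / protection / urban bands

    arc = np.array([t.station_arc_m for t in transects])
    part_idx = np.array([t.part_index for t in transects])
    origins = np.array([t.point_at(0.0) for t in transects])
    if spec.frame == GEOGRAPHIC:
        lon = origins[:, 0]
        lat = origins[:, 1]
    else:
        lat = spec.lat0_deg + arc / M_PER_DEG
        lon = np.full(n, spec.lon0_deg)

    # ---- per-station draws (order fixed for determinism)
    missing = rng.random(n) < spec.infra_missing_fraction
    w_all = spec.infra_width_distribution.draw(rng, n)
    classes = np.array(list(spec.infra_class_mix))
    probs = np.array([spec.infra_class_mix[c] for c in classes])
    first_class = rng.choice(classes, size=n, p=probs)
    gap = spec.heavy_gap_distribution.draw(rng, n)
    protected = rng.random(n) < spec.protected_fraction
    heavy_probs = np.array(
        [spec.infra_class_mix.get("building", 0.0), spec.infra_class_mix.get("freeway", 0.0)]
    )
    heavy_probs = heavy_probs / heavy_probs.sum() if heavy_probs.sum() > 0 else np.array([1.0, 0.0])
    heavy_pick = rng.choice(np.array(HEAVY_CLASSES), size=n, p=heavy_probs)
    cliff_draw = rng.random(n) < spec.cliff_fraction
    # urban blocks: contiguous runs of stations share the urban label
    blocks = (arc / spec.spacing_m).astype(int) // max(spec.urban_block_stations, 1)
    blocks = blocks + part_idx * (blocks.max() + 1 if n else 1)
    uniq = np.unique(blocks)
    block_urban = dict(zip(uniq, rng.random(len(uniq)) < spec.urban_patch_fraction))
    urban = np.array([block_urban[b] for b in blocks]) if n else np.zeros(0, bool)
    r45 = spec.retreat_rcp45.draw(rng, n)
    r85 = spec.retreat_rcp85.draw(rng, n)
    if spec.gdp_per_capita is not None:
        gdp_values = np.asarray(spec.gdp_per_capita, dtype=float)
        if len(gdp_values) != spec.n_countries:
            raise ValueError("gdp_per_capita must list one value per country")
    else:
        gdp_values = 10 ** rng.uniform(3.0, 5.0, size=spec.n_countries)
    if np.any(gdp_values <= 0):
        raise ValueError("gdp_per_capita must be strictly positive")

    if not with_labels:
        protected[:] = False
        urban[:] = False
        cliff_draw[:] = False
    if spec.frame == GEOGRAPHIC:
        # degree-grid rasters cannot carry exact per-station bands; the
        # pseudo-geographic mode exists for latitude/degree-matching tests
        urban[:] = False
        cliff_draw[:] = False
    if not with_infra:
        missing[:] = True

    w_all = np.where(protected, w_all * spec.protected_width_multiplier, w_all)
    is_heavy_first = np.isin(first_class, HEAVY_CLASSES)
    # the heavy structure can never precede the first structure of any class
    gap = np.maximum(gap, 1.0)
    w_heavy = np.where(is_heavy_first, w_all, w_all * gap)
    censored_all = missing | (w_all > length_m)
    censored_heavy = missing | (w_heavy > length_m)
    w_eff_all = np.where(censored_all, length_m, w_all)
    w_eff_heavy = np.where(censored_heavy, length_m, w_heavy)

    # ---- infrastructure features
    features: list[tuple] = []
    half = spec.feature_halfwidth_m
    for i, tr in enumerate(transects):
        if missing[i]:
            continue
        if not censored_all[i]:
            cls = first_class[i]
            if cls == "building":
                features.append((_building_polygon(tr, w_all[i], half, spec.building_depth_m), cls))
            else:
                features.append((_road_line(tr, w_all[i], half), cls))
        if not is_heavy_first[i] and not censored_heavy[i]:
            cls = heavy_pick[i]
            if cls == "building":
                features.append(
                    (_building_polygon(tr, w_heavy[i], half, spec.building_depth_m), cls)
                )
            else:
                features.append((_road_line(tr, w_heavy[i], half), cls))
    layer = InfrastructureLayer(features)

    # ---- cliffs and DEM
    cliff = cliff_draw & (w_eff_all >= 400.0)
    cliff_start = np.full(n, np.nan)
    c0 = np.minimum(0.5 * w_eff_all, 2000.0)
    c0 = 15.0 + 30.0 * np.round((c0 - 15.0) / 30.0)  # snap to DEM cell centers
    cliff_start[cliff] = c0[cliff]
    dem = _build_dem(spec, arc, cliff, cliff_start)
    population = _build_population(spec, arc, urban)

    # ---- protected-area polygons (first 1.5 km of the transect, ±400 m)
    areas: list[Polygon] = []
    for i, tr in enumerate(transects):
        if protected[i]:
            areas.append(
                Polygon(
                    [
                        _offset_point(tr, 10.0, -400.0),
                        _offset_point(tr, 10.0, 400.0),
                        _offset_point(tr, 1500.0, 400.0),
                        _offset_point(tr, 1500.0, -400.0),
                    ]
                )
            )

    # ---- retreat field at station origins
    retreat_points = pd.DataFrame(
        {
            "point_id": np.arange(n),
            "x": origins[:, 0],
            "y": origins[:, 1],
            "retreat_rcp45_m": r45,
            "retreat_rcp85_m": r85,
        }
    )

    # ---- true natural-obstruction status
    if shape == "island":
        radius = spec.shore_length_km * 1000.0 / (2 * np.pi)
        reintersect = np.full(n, 2 * radius)
        reintersect[reintersect > length_m] = np.nan
    elif shape == "peninsula":
        reintersect = np.full(n, spec.strip_width_m)
    else:
        reintersect = np.full(n, np.nan)

    excl_all = np.full(n, "none", dtype=object)
    excl_heavy = np.full(n, "none", dtype=object)
    for arr, weff in ((excl_all, w_eff_all), (excl_heavy, w_eff_heavy)):
        cliff_hit = cliff & (cliff_start < weff)
        re_hit = np.isfinite(reintersect) & (reintersect < weff)
        arr[cliff_hit] = "cliff"
        arr[re_hit] = "shoreline_reintersect"  # precedence over cliff
        arr[lat > 60.0] = "beyond_dem_limit"

    country_idx = np.minimum(
        (np.arange(n) * spec.n_countries) // max(n, 1), spec.n_countries - 1
    )
    countries = np.array([f"C{k:02d}" for k in country_idx])
    continents = np.array([CONTINENTS[k % len(CONTINENTS)] for k in country_idx])

    truth = pd.DataFrame(
        {
            "transect_id": [t.id for t in transects],
            "part_index": part_idx,
            "station_arc_m": arc,
            "x": origins[:, 0],
            "y": origins[:, 1],
            "longitude_deg": lon,
            "latitude_deg": lat,
            "width_all_m": np.where(censored_all, np.nan, w_all),
            "width_heavy_m": np.where(censored_heavy, np.nan, w_heavy),
            "censored_all": censored_all,
            "censored_heavy": censored_heavy,
            "first_class": first_class,
            "cliff": cliff,
            "cliff_start_m": cliff_start,
            "reintersect_m": reintersect,
            "exclusion_true": excl_all,
            "exclusion_heavy_true": excl_heavy,
            "protected": protected,
            "urban": urban,
            "pop_density": np.where(urban, spec.pop_urban_density, spec.pop_rural_density),
            "country": countries,
            "continent": continents,
            "retreat_rcp45_m": r45,
            "retreat_rcp85_m": r85,
        }
    )
    assignment = truth[
        ["transect_id", "country", "continent", "latitude_deg", "longitude_deg"]
    ].copy()
    gdp = pd.DataFrame(
        {"country": [f"C{k:02d}" for k in range(spec.n_countries)],
         "gdp_per_capita": gdp_values}
    )
    return SyntheticWorld(
        spec=spec,
        shoreline=shoreline,
        transects=transects,
        infrastructure=layer,
        dem=dem,
        population=population,
        protected_areas=areas,
        retreat_points=retreat_points,
        truth=truth,
        assignment=assignment,
        gdp=gdp,
    )


def _build_dem(spec: WorldSpec, arc: np.ndarray, cliff: np.ndarray,
               cliff_start: np.ndarray) -> Raster:
    """Flat (0 m) DEM with per-station cliff ramps on a straight coast.

    A cliff at station i is a 150-m-long linear ramp starting ``c0`` meters
    landward, rising at the configured slope, occupying the alongshore band
    x ∈ [x_i − 480, x_i + 480].  Ramp breakpoints are snapped to cell
    centers so bilinear sampling reproduces the ramp exactly."""
    cs = spec.dem_cellsize_m
    if spec.frame == GEOGRAPHIC:
        # degree grid: rows span the coast latitudes, columns the first
        # dem_depth meters of longitude east of the (meridional) coast
        cs_deg = cs / M_PER_DEG
        lat_min = spec.lat0_deg - 2 * cs_deg
        lat_max = spec.lat0_deg + (arc.max() if len(arc) else 0.0) / M_PER_DEG + 2 * cs_deg
        ny = int(np.ceil((lat_max - lat_min) / cs_deg))
        nx = int(np.ceil(spec.dem_depth_m / cs)) + 4
        data = np.zeros((ny, nx))
        return Raster(data, xll=spec.lon0_deg - 2 * cs_deg, yll=lat_min, cellsize=cs_deg)
    x_min = -480.0
    x_max = (arc.max() if len(arc) else 0.0) + 480.0
    nx = int(np.ceil((x_max - x_min) / cs))
    ny = int(np.ceil((spec.dem_depth_m + 60.0) / cs))
    yll = -60.0
    data = np.zeros((ny, nx))
    if np.any(cliff):
        x_centers = x_min + (np.arange(nx) + 0.5) * cs
        y_centers = yll + (np.arange(ny) + 0.5) * cs  # south→north
        rise = 150.0 * np.tan(np.radians(spec.cliff_slope_deg))
        for xi, c0 in zip(arc[cliff], cliff_start[cliff]):
            cols = np.nonzero(np.abs(x_centers - xi) <= 480.0)[0]
            ramp = np.clip((y_centers - c0) / 150.0, 0.0, 1.0) * rise
            rows = ny - 1 - np.arange(ny)  # row 0 is north
            data[rows[:, None], cols[None, :]] = np.maximum(
                data[rows[:, None], cols[None, :]], ramp[:, None]
            )
    return Raster(data, xll=x_min, yll=yll, cellsize=cs)


def _build_population(spec: WorldSpec, arc: np.ndarray, urban: np.ndarray) -> Raster:
    """Density raster constant along each station's alongshore band."""
    cs = spec.pop_cellsize_m
    n_cols = len(arc) if len(arc) else 1
    dens = np.where(urban, spec.pop_urban_density, spec.pop_rural_density) if len(arc) else \
        np.array([spec.pop_rural_density])
    ny = int(np.ceil(spec.transect_length_m / cs)) + 2
    if spec.frame == GEOGRAPHIC:
        # rows = latitude bands (one per station, north first), columns =
        # longitude; density is uniform rural in this frame, the grid only
        # needs to cover the transects
        cs_deg = cs / M_PER_DEG
        n_lon = 2 * ny  # generous east extent (cos(lat) shortens lon cells)
        grid = np.tile(dens[::-1][:, None], (1, n_lon))
        return Raster(grid, xll=spec.lon0_deg - cs_deg / 2,
                      yll=spec.lat0_deg - cs_deg / 2, cellsize=cs_deg)
    grid = np.tile(dens[None, :], (ny, 1))
    return Raster(grid, xll=-cs / 2.0, yll=-cs / 2.0, cellsize=cs)


def generate_null_groups(
    n_per_group: int,
    seed: int,
    median: float = 392.0,
    sigma: float = 1.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent samples from one log-normal width distribution
    (for type-I-error checks of the group tests)."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    a = np.exp(rng.normal(np.log(median), sigma, size=n_per_group))
    b = np.exp(rng.normal(np.log(median), sigma, size=n_per_group))
    return a, b
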