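"""Cliff slopes, shoreline re-intersection, DEM latitude limit."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

from coastsqueeze import (
    InfrastructureLayer,
    Raster,
    ShorePart,
    Shoreline,
    apply_exclusions,
    cast_transects,
    measure_all,
    reintersection_distance,
    slope_profile,
)
from conftest import make_transect, straight_shoreline


def ramp_dem(gradient, start_m=0.0, cellsize=30.0, depth=6000.0, width=4000.0,
             center_x=0.0):
    """DEM rising landward (+y) at a constant gradient from ``start_m``."""
    yll = -2 * cellsize
    ny = int((depth - yll) / cellsize)
    nx = int(width / cellsize)
    y = yll + (np.arange(ny) + 0.5) * cellsize  # south→north centers
    elev = np.clip(y - start_m, 0.0, None) * gradient
    data = np.tile(elev[::-1][:, None], (1, nx))  # row 0 = north
    return Raster(data, xll=center_x - width / 2, yll=yll, cellsize=cellsize)


class TestSlopeProfile:
    def test_flat_dem_has_zero_slope(self):
        dem = ramp_dem(0.0)
        prof = slope_profile(make_transect((0, 0), (0, 1), 2000.0), dem)
        assert prof.max_seaward_slope_deg == pytest.approx(0.0)
        assert prof.first_steep_station_m is None
        assert prof.valid

    def test_unit_ramp_is_45_degrees(self):
        dem = ramp_dem(1.0, start_m=210.0)  # kink at a cell center (210=15+195)
        prof = slope_profile(make_transect((0, 0), (0, 1), 2000.0), dem)
        assert prof.max_seaward_slope_deg == pytest.approx(45.0, abs=1e-6)
        # first interval strictly steeper than 34° starts near the ramp foot
        assert prof.first_steep_station_m == pytest.approx(210.0, abs=30.0)

    def test_exact_angle_of_repose_not_steep(self):
        dem = ramp_dem(np.tan(np.radians(34.0)))
        prof = slope_profile(make_transect((0, 0), (0, 1), 2000.0), dem)
        assert prof.max_seaward_slope_deg == pytest.approx(34.0, abs=1e-9)
        assert prof.first_steep_station_m is None  # strict "steeper than"

    def test_slightly_above_angle_of_repose_is_steep(self):
        dem = ramp_dem(np.tan(np.radians(34.01)))
        prof = slope_profile(make_transect((0, 0), (0, 1), 2000.0), dem)
        assert prof.first_steep_station_m is not None

    def test_linear_ramp_matches_analytic_atan(self):
        for g in (0.1, 0.3, 0.6745, 1.5):
            dem = ramp_dem(g)
            prof = slope_profile(make_transect((0, 0), (0, 1), 2000.0), dem)
            assert prof.max_seaward_slope_deg == pytest.approx(
                np.degrees(np.arctan(g)), abs=1e-6
            )

    def test_threshold_monotonicity(self):
        """Lowering the slope threshold never un-flags a transect."""
        dem = ramp_dem(0.8, start_m=300.0)
        t = make_transect((0, 0), (0, 1), 2000.0)
        flagged_at = [
            slope_profile(t, dem, steep_deg=s).first_steep_station_m is not None
            for s in (45.0, 38.66, 30.0, 20.0)  # atan(0.8)=38.66°
        ]
        assert flagged_at == sorted(flagged_at)  # once flagged, stays flagged

    def test_all_nodata_marks_profile_invalid(self):
        dem = Raster(np.zeros((10, 10)), xll=1e6, yll=1e6, cellsize=30.0)
        prof = slope_profile(make_transect((0, 0), (0, 1), 2000.0), dem)
        assert not prof.valid


class TestReintersection:
    def test_wide_mainland_never_recrosses(self):
        shore = straight_shoreline(10_000.0)
        t = make_transect((5000, 0), (0, 1))
        assert reintersection_distance(t, shore) is None

    def test_parallel_strip_recrosses_at_width(self):
        shore = Shoreline(
            [
                ShorePart(np.array([[0.0, 0.0], [10_000.0, 0.0]]), np.array(True), "left"),
                ShorePart(np.array([[10_000.0, 2000.0], [0.0, 2000.0]]), np.array(True), "left"),
            ]
        )
        t = make_transect((5000, 0), (0, 1))
        assert reintersection_distance(t, shore) == pytest.approx(2000.0)

    def test_island_truth_distance(self):
        from coastsqueeze import WorldSpec, generate_world

        world = generate_world(
            WorldSpec(seed=5, coastline_shape="island", shore_length_km=18.85,
                      cliff_fraction=0.0)
        )
        radius = 18.85e3 / (2 * np.pi)
        for t in world.transects[::5]:
            d = reintersection_distance(t, world.shoreline)
            assert d == pytest.approx(2 * radius, abs=0.1)

    def test_stepping_oracle_on_random_rings(self):
        """Random convex-ish island rings vs a 0.1-m stepping oracle."""
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = rng.integers(8, 30)
            theta = np.sort(rng.uniform(0, 2 * np.pi, n))
            r = rng.uniform(500, 1500, n)
            verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            verts = np.vstack([verts, verts[0]])
            ring = shapely.LineString(verts)
            shore = Shoreline([ShorePart(verts, np.array(True), "left")])
            origin = verts[0]
            inward = -origin / np.hypot(*origin)
            t = make_transect(origin, inward, length_m=4000.0)
            got = reintersection_distance(t, shore)
            # oracle: crossing of 0.1-m sub-segments with the ring
            d = np.arange(0, 4000.1, 0.1)
            coords = t.point_at(d)
            segs = shapely.linestrings(np.stack([coords[:-1], coords[1:]], axis=1))
            hit = np.nonzero(shapely.intersects(ring, segs))[0]
            hit = hit[d[hit] > 1.0]
            want = d[hit[0]] if hit.size else None
            if want is None:
                assert got is None
            else:
                assert got is not None and abs(got - want) <= 0.1


class TestApplyExclusions:
    def _records(self, widths, lats=None):
        n = len(widths)
        return pd.DataFrame(
            {
                "transect_id": np.arange(n),
                "width_all_m": widths,
                "width_heavy_m": widths,
                "censored_all": [w is None or np.isnan(w) for w in widths],
                "censored_heavy": [w is None or np.isnan(w) for w in widths],
                "censor_limit_m": 25_000.0,
                "exclusion": "none",
                "exclusion_heavy": "none",
                "latitude_deg": lats if lats is not None else np.nan,
            }
        )

    def test_cliff_before_structure_excludes(self):
        dem = ramp_dem(1.0, start_m=195.0, center_x=1000.0)
        shore = straight_shoreline(2000.0)
        trs = [make_transect((1000, 0), (0, 1), tid=0)]
        rec = self._records([500.0])
        prof = {0: slope_profile(trs[0], dem)}
        out = apply_exclusions(rec, prof, shore, trs)
        assert out["exclusion"].iloc[0] == "cliff"

    def test_structure_before_cliff_stands(self):
        dem = ramp_dem(1.0, start_m=195.0, center_x=1000.0)
        shore = straight_shoreline(2000.0)
        trs = [make_transect((1000, 0), (0, 1), tid=0)]
        rec = self._records([100.0])
        out = apply_exclusions(rec, {0: slope_profile(trs[0], dem)}, shore, trs)
        assert out["exclusion"].iloc[0] == "none"
        assert out["width_all_m"].iloc[0] == pytest.approx(100.0)

    def test_island_strip_excludes_for_distant_structure(self):
        # 3-km strip; only structure on the far shore at 10 km
        shore = Shoreline(
            [
                ShorePart(np.array([[0.0, 0.0], [10_000.0, 0.0]]), np.array(True), "left"),
                ShorePart(np.array([[10_000.0, 3000.0], [0.0, 3000.0]]), np.array(True), "left"),
            ]
        )
        trs = [make_transect((5000, 0), (0, 1), tid=0)]
        layer = InfrastructureLayer([(box(4950, 10_000, 5050, 10_050), "building")])
        rec = measure_all(trs, layer)
        dem = ramp_dem(0.0, depth=26_000.0, center_x=5000.0)
        out = apply_exclusions(rec, {0: slope_profile(trs[0], dem)}, shore, trs)
        assert out["exclusion"].iloc[0] == "shoreline_reintersect"

    def test_per_category_cliff_evaluation(self):
        # path at 100 m, cliff at ~200 m, building at 1600 m: the 'all'
        # record stands (structure first) but 'heavy' is cliff-limited
        dem = ramp_dem(1.0, start_m=195.0, center_x=1000.0)
        shore = straight_shoreline(2000.0)
        trs = [make_transect((1000, 0), (0, 1), tid=0)]
        layer = InfrastructureLayer(
            [
                (shapely.LineString([(960, 100.0), (1040, 100.0)]), "paved_path"),
                (box(960, 1600.0, 1040, 1650.0), "building"),
            ]
        )
        rec = measure_all(trs, layer)
        out = apply_exclusions(rec, {0: slope_profile(trs[0], dem)}, shore, trs)
        assert out["exclusion"].iloc[0] == "none"
        assert out["exclusion_heavy"].iloc[0] == "cliff"

    def test_latitude_limit_takes_precedence(self):
        shore = straight_shoreline(2000.0)
        trs = [make_transect((1000, 0), (0, 1), tid=0, latitude_deg=61.0)]
        rec = self._records([500.0], lats=[61.0])
        out = apply_exclusions(rec, {}, shore, trs)
        assert out["exclusion"].iloc[0] == "beyond_dem_limit"
        # southern hemisphere is not limited unless symmetric mode is on
        trs2 = [make_transect((1000, 0), (0, 1), tid=0, latitude_deg=-61.0)]
        rec2 = self._records([500.0], lats=[-61.0])
        dem = ramp_dem(0.0)
        out2 = apply_exclusions(rec2, {0: slope_profile(trs2[0], dem)}, shore, trs2)
        assert out2["exclusion"].iloc[0] == "none"
        out3 = apply_exclusions(
            rec2, {0: slope_profile(trs2[0], dem)}, shore, trs2, symmetric_lat_limit=True
        )
        assert out3["exclusion"].iloc[0] == "beyond_dem_limit"

    def test_missing_profile_raises(self):
        shore = straight_shoreline(2000.0)
        trs = [make_transect((1000, 0), (0, 1), tid=0)]
        rec = self._records([500.0])
        with pytest.raises(KeyError):
            apply_exclusions(rec, {}, shore, trs)

    def test_world_exclusion_truth(self, small_world):
        from coastsqueeze import run_world

        res = run_world(small_world)
        t = small_world.truth
        assert (res.records["exclusion"].to_numpy() == t["exclusion_true"].to_numpy()).all()
        assert (
            res.records["exclusion_heavy"].to_numpy() == t["exclusion_heavy_true"].to_numpy()
        ).all()
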