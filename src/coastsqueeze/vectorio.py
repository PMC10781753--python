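"""GeoJSON read/write for the pipeline's vector layers.

Shorelines are FeatureCollections of LineStrings with properties
``sandy`` (boolean), ``land_side`` and ``frame``; infrastructure features
carry a ``class`` property (building / freeway / car_road / paved_path);
protected areas are plain polygons.  Transects are written as two-point
LineStrings with ``id``, ``station_arc_m`` and ``azimuth_deg``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape

from .squeeze_measurement import InfrastructureLayer
from .transect_engine import PLANAR, ShorePart, Shoreline, Transect


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _write(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj))


def _read(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_shoreline(shoreline: Shoreline, path: str | Path) -> None:
    feats = []
    for part in shoreline.parts:
        sandy = part.sandy
        # split into maximal runs of constant sandy flag, one feature each
        breaks = np.nonzero(np.diff(sandy.astype(int)))[0] + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [len(sandy)]])
        for s, e in zip(starts, ends):
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping_from_coords(part.vertices[s : e + 1]),
                    "properties": {
                        "sandy": bool(sandy[s]),
                        "land_side": part.land_side,
                        "frame": shoreline.frame,
                    },
                }
            )
    _write(_feature_collection(feats), path)


def mapping_from_coords(coords: np.ndarray) -> dict:
    return {"type": "LineString", "coordinates": [list(map(float, c)) for c in coords]}


def read_shoreline(path: str | Path) -> Shoreline:
    obj = _read(path)
    parts = []
    frame = PLANAR
    for feat in obj["features"]:
        props = feat.get("properties") or {}
        frame = props.get("frame", PLANAR)
        coords = np.asarray(feat["geometry"]["coordinates"], dtype=float)
        parts.append(
            ShorePart(
                coords,
                np.array(bool(props.get("sandy", True))),
                props.get("land_side", "left"),
            )
        )
    return Shoreline(parts, frame)


def write_infrastructure(layer: InfrastructureLayer, path: str | Path) -> None:
    feats = [
        {"type": "Feature", "geometry": mapping(geom), "properties": {"class": cls}}
        for geom, cls in layer.features
    ]
    _write(_feature_collection(feats), path)


def read_infrastructure(path: str | Path) -> InfrastructureLayer:
    obj = _read(path)
    features = [
        (shape(f["geometry"]), f["properties"]["class"]) for f in obj["features"]
    ]
    return InfrastructureLayer(features)


def write_protected_areas(areas, path: str | Path) -> None:
    feats = [
        {"type": "Feature", "geometry": mapping(geom), "properties": {}}
        for geom in areas
    ]
    _write(_feature_collection(feats), path)


def read_protected_areas(path: str | Path) -> list:
    obj = _read(path)
    return [shape(f["geometry"]) for f in obj["features"]]


def write_transects(transects: list[Transect], path: str | Path) -> None:
    feats = []
    for t in transects:
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(t.line),
                "properties": {
                    "id": int(t.id),
                    "station_arc_m": float(t.station_arc_m),
                    "azimuth_deg": float(t.azimuth_deg),
                    "length_m": float(t.length_m),
                    "part_index": int(t.part_index),
                    "frame": t.frame,
                    "lat_ref": float(t.lat_ref),
                    "latitude_deg": float(t.latitude_deg),
                },
            }
        )
    _write(_feature_collection(feats), path)


def read_transects(path: str | Path) -> list[Transect]:
    obj = _read(path)
    out = []
    for f in obj["features"]:
        p = f["properties"]
        coords = np.asarray(f["geometry"]["coordinates"], dtype=float)
        origin = coords[0]
        frame = p.get("frame", PLANAR)
        lat_ref = float(p.get("lat_ref", 0.0))
        delta = coords[-1] - origin
        if frame != PLANAR:
            from .transect_engine import M_PER_DEG
            import math

            delta = delta * np.array([M_PER_DEG * math.cos(math.radians(lat_ref)), M_PER_DEG])
        norm = np.hypot(*delta)
        out.append(
            Transect(
                id=int(p["id"]),
                origin=origin,
                azimuth=delta / norm,
                length_m=float(p["length_m"]),
                station_arc_m=float(p["station_arc_m"]),
                part_index=int(p.get("part_index", 0)),
                frame=frame,
                lat_ref=lat_ref,
                latitude_deg=float(p.get("latitude_deg", "nan")),
            )
        )
    return out
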