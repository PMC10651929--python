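"""Great-circle distance and small GeoJSON helpers shared across the pipeline.

The same haversine is used by the synthetic generator, the stay detector and
the POI attribution step, so distances agree between the world that is
simulated and the world that is measured.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters between WGS84 points (vectorized).

    Accepts scalars or broadcastable arrays of degrees.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def write_geojson(path: str | Path, geometries, properties) -> None:
    """Write shapely geometries + per-feature property dicts as a FeatureCollection."""
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for geom, props in zip(geometries, properties, strict=True)
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_geojson(path: str | Path):
    """Read a FeatureCollection into (list of shapely geometries, list of property dicts)."""
    doc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    props = [f.get("properties", {}) for f in doc["features"]]
    return geoms, props


def locate_points(lats, lons, geometries) -> np.ndarray:
    """Index of the first geometry containing each point, -1 if none.

    Containment uses shapely `covers`, so points exactly on a shared grid edge
    resolve deterministically to the lowest-index polygon.
    """
    import shapely

    pts = shapely.points(np.asarray(lons, dtype=float), np.asarray(lats, dtype=float))
    out = np.full(len(pts), -1, dtype=int)
    for i, geom in enumerate(geometries):
        mask = (out == -1) & shapely.covers(geom, pts)
        out[mask] = i
    return out
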