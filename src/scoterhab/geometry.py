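"""Planar projection and GeoJSON helpers.

All survey geometry is computed on a metric plane. Geographic inputs
(lon/lat degrees) are projected with a local equirectangular transform
anchored at a reference point: x = R cos(lat0) Δlon, y = R Δlat (radians).
Over a study area a few degrees across this is meter-true to well under a
percent, which is ample for 1 km grid cells, and it is exactly invertible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import mapping, shape

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular projection centred on (lon0, lat0), units meters."""

    lon0: float
    lat0: float

    def forward(self, lon, lat):
        """lon/lat degrees -> planar (x, y) meters."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        k = math.pi / 180.0 * EARTH_RADIUS_M
        x = (lon - self.lon0) * k * math.cos(math.radians(self.lat0))
        y = (lat - self.lat0) * k
        return x, y

    def inverse(self, x, y):
        """Planar meters -> lon/lat degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        k = math.pi / 180.0 * EARTH_RADIUS_M
        lon = self.lon0 + x / (k * math.cos(math.radians(self.lat0)))
        lat = self.lat0 + y / k
        return lon, lat


def read_geojson_features(path):
    """Return a list of (shapely geometry, properties dict) from a GeoJSON file."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        feats = gj["features"]
    elif gj.get("type") == "Feature":
        feats = [gj]
    else:  # bare geometry
        return [(shape(gj), {})]
    return [(shape(f["geometry"]), f.get("properties") or {}) for f in feats]


def write_geojson_features(path, geoms_and_props):
    feats = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in geoms_and_props
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
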