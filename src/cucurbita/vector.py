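"""GeoJSON/CSV export of detections and yield grids."""

from __future__ import annotations

import json
import math

import numpy as np

from .gridmap import GridCellSet
from .quantify import FruitRecord
from .raster import RasterTransform

__all__ = ["detections_to_geojson", "grid_to_geojson", "write_geojson"]


def _ellipse_ring(fit, transform: RasterTransform, n_vertices: int = 64):
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    a = fit.major_px / 2.0
    b = fit.minor_px / 2.0
    th = math.radians(fit.orientation_deg)
    cols = fit.center_col + a * np.cos(t) * math.cos(th) - b * np.sin(t) * math.sin(th)
    rows = fit.center_row + a * np.cos(t) * math.sin(th) + b * np.sin(t) * math.cos(th)
    x, y = transform.pixel_to_world(rows, cols)
    ring = [[float(xi), float(yi)] for xi, yi in zip(x, y)]
    ring.append(ring[0])
    return ring


def detections_to_geojson(detections, transform: RasterTransform,
                          records: list[FruitRecord] | None = None) -> dict:
    """Detections as GeoJSON polygons (fitted ellipses at 64 vertices)."""
    features = []
    for i, (obj, fit) in enumerate(detections):
        props = {
            "major_px": fit.major_px,
            "minor_px": fit.minor_px,
            "major_cm": fit.major_px * transform.gsd_cm,
            "minor_cm": fit.minor_px * transform.gsd_cm,
            "orientation_deg": fit.orientation_deg,
            "area_px": obj.area,
        }
        if records is not None:
            rec = records[i]
            props.update(weight_g=rec.weight_g, volume_cm3=rec.volume_cm3,
                         weight_class=rec.weight_class, marketable=rec.marketable)
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon",
                         "coordinates": [_ellipse_ring(fit, transform)]},
            "properties": props,
        })
    return {"type": "FeatureCollection", "features": features}


def grid_to_geojson(grid: GridCellSet) -> dict:
    """Yield-map cells as GeoJSON square polygons with count/weight."""
    x0, y0 = grid.origin
    cs = grid.cell_size_m
    features = []
    ny, nx = grid.counts.shape
    for iy in range(ny):
        for ix in range(nx):
            if not grid.inside[iy, ix]:
                continue
            xa, ya = x0 + ix * cs, y0 + iy * cs
            ring = [[xa, ya], [xa + cs, ya], [xa + cs, ya + cs],
                    [xa, ya + cs], [xa, ya]]
            features.append({
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"count": int(grid.counts[iy, ix]),
                               "weight_kg": float(grid.weights_kg[iy, ix])},
            })
    return {"type": "FeatureCollection", "features": features}


def write_geojson(doc: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
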