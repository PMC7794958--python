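"""Grid aggregation of fruit records into yield maps.

Detected fruits are binned into square cells (default 3 m, i.e. 9 m^2)
anchored at the corner of the field boundary's bounding box.  Per cell
the fruit count and summed weight are kept; field-level summaries
(fruits per m^2, kg per m^2, mean fruit weight) and the count-weight
cell correlation quantify the spatial yield structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon, box

from .quantify import FruitRecord

__all__ = ["GridCellSet", "FieldSummary", "aggregate_grid", "field_summary",
           "count_weight_correlation"]


@dataclass
class GridCellSet:
    """Regular grid over the field with per-cell count and weight (kg)."""

    cell_size_m: float
    origin: tuple[float, float]
    counts: np.ndarray          # (ny, nx) int
    weights_kg: np.ndarray      # (ny, nx) float
    inside: np.ndarray          # (ny, nx) bool — cell intersects the boundary
    boundary: Polygon
    outside_records: list[FruitRecord] = field(default_factory=list)

    @property
    def area_m2(self) -> float:
        return float(self.boundary.area)

    def to_frame(self) -> pd.DataFrame:
        ny, nx = self.counts.shape
        iy, ix = np.mgrid[0:ny, 0:nx]
        cs = self.cell_size_m
        return pd.DataFrame({
            "cell_x": self.origin[0] + ix.ravel() * cs,
            "cell_y": self.origin[1] + iy.ravel() * cs,
            "count": self.counts.ravel(),
            "weight_kg": self.weights_kg.ravel(),
            "inside": self.inside.ravel(),
        })


@dataclass(frozen=True)
class FieldSummary:
    fruits_per_m2: float
    kg_per_m2: float
    sd_fruits_per_m2: float
    sd_kg_per_m2: float
    mean_fruit_weight_g: float
    total_count: int
    total_weight_kg: float
    area_m2: float


def aggregate_grid(records: list[FruitRecord], cell_size_m: float = 3.0,
                   boundary: Polygon | None = None) -> GridCellSet:
    """Bin records into cells; cell edges are lower-inclusive.

    Without an explicit field boundary, the bounding box of the records
    (expanded to whole cells) is used.  Records outside the boundary are
    kept on ``outside_records`` and reported with a warning rather than
    silently dropped; they are not binned.
    """
    if cell_size_m <= 0:
        raise ValueError("cell size must be positive")
    xs = np.array([r.x for r in records], float)
    ys = np.array([r.y for r in records], float)
    if boundary is None:
        if not records:
            raise ValueError("need records or an explicit boundary")
        pad = 1e-9
        boundary = box(xs.min() - pad, ys.min() - pad,
                       xs.max() + cell_size_m, ys.max() + cell_size_m)
    x0, y0, x1, y1 = boundary.bounds
    nx = max(int(np.ceil((x1 - x0) / cell_size_m)), 1)
    ny = max(int(np.ceil((y1 - y0) / cell_size_m)), 1)

    counts = np.zeros((ny, nx), int)
    weights = np.zeros((ny, nx), float)
    outside = []
    for rec, x, y in zip(records, xs, ys):
        p = Point(x, y)
        if not (boundary.contains(p) or boundary.touches(p)):
            outside.append(rec)
            continue
        ix = int((x - x0) // cell_size_m)
        iy = int((y - y0) // cell_size_m)
        # points exactly on the boundary's upper edge go to the last cell
        ix = min(ix, nx - 1)
        iy = min(iy, ny - 1)
        counts[iy, ix] += 1
        weights[iy, ix] += rec.weight_g / 1000.0
    if outside:
        warnings.warn(f"{len(outside)} record(s) fall outside the field "
                      "boundary and were not binned", stacklevel=2)

    inside = np.zeros((ny, nx), bool)
    for iy in range(ny):
        for ix in range(nx):
            cell = box(x0 + ix * cell_size_m, y0 + iy * cell_size_m,
                       x0 + (ix + 1) * cell_size_m, y0 + (iy + 1) * cell_size_m)
            inside[iy, ix] = cell.intersects(boundary)
    return GridCellSet(cell_size_m=cell_size_m, origin=(x0, y0),
                       counts=counts, weights_kg=weights, inside=inside,
                       boundary=boundary, outside_records=outside)


def field_summary(grid: GridCellSet) -> FieldSummary:
    """Field-level densities; per-cell SDs are scaled to per-m^2 units."""
    area = grid.area_m2
    if area <= 0:
        raise ValueError("field area must be positive")
    cell_area = grid.cell_size_m ** 2
    total_count = int(grid.counts.sum()) + len(grid.outside_records)
    total_weight = float(grid.weights_kg.sum()) + sum(
        r.weight_g for r in grid.outside_records) / 1000.0
    c = grid.counts[grid.inside] / cell_area
    w = grid.weights_kg[grid.inside] / cell_area
    return FieldSummary(
        fruits_per_m2=total_count / area,
        kg_per_m2=total_weight / area,
        sd_fruits_per_m2=float(np.std(c, ddof=1)) if c.size > 1 else 0.0,
        sd_kg_per_m2=float(np.std(w, ddof=1)) if w.size > 1 else 0.0,
        mean_fruit_weight_g=(1000.0 * total_weight / total_count
                             if total_count else float("nan")),
        total_count=total_count,
        total_weight_kg=total_weight,
        area_m2=area,
    )


def count_weight_correlation(grid: GridCellSet) -> float:
    """Pearson r between per-cell fruit counts and summed weights."""
    nonempty = grid.counts > 0
    if nonempty.sum() < 3:
        raise ValueError("need at least 3 non-empty cells")
    c = grid.counts[nonempty].astype(float)
    w = grid.weights_kg[nonempty]
    if np.ptp(c) == 0 or np.ptp(w) == 0:
        raise ValueError("zero variance in counts or weights")
    return float(stats.pearsonr(c, w).statistic)
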