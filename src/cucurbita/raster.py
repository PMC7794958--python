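"""Minimal georeferenced raster I/O: TIFF images with ESRI world files.

The field imagery this package targets is an orthomosaic with a uniform
ground sampling distance (GSD), so the full generality of a GDAL-style
affine is not needed: pixel (row, col) maps to world (x, y) through an
origin and the GSD.  Rasters are written as plain TIFF plus a world file
(``.tfw``-style, six lines of text) holding that mapping, which any GIS
can read back.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = ["RasterTransform", "read_raster", "write_raster", "world_file_path"]


@dataclass(frozen=True)
class RasterTransform:
    """Pixel-to-world mapping for a north-up raster at uniform GSD.

    Parameters
    ----------
    x_origin, y_origin:
        World coordinates (metres, local or projected) of the *outer corner*
        of pixel (0, 0).
    gsd_cm:
        Ground sampling distance in cm per pixel (both axes).
    """

    x_origin: float = 0.0
    y_origin: float = 0.0
    gsd_cm: float = 1.0

    @property
    def gsd_m(self) -> float:
        return self.gsd_cm / 100.0

    def pixel_to_world(self, row, col):
        """World coordinates of pixel centres."""
        g = self.gsd_m
        x = self.x_origin + (np.asarray(col, float) + 0.5) * g
        y = self.y_origin + (np.asarray(row, float) + 0.5) * g
        return x, y

    def world_to_pixel(self, x, y):
        """Integer pixel indices containing world points."""
        g = self.gsd_m
        col = np.floor((np.asarray(x, float) - self.x_origin) / g).astype(int)
        row = np.floor((np.asarray(y, float) - self.y_origin) / g).astype(int)
        return row, col


def world_file_path(raster_path: str) -> str:
    base, _ = os.path.splitext(raster_path)
    return base + ".tfw"


def write_raster(path: str, array: np.ndarray, transform: RasterTransform) -> None:
    """Write ``array`` as TIFF and its transform as a world file.

    The world file follows the ESRI convention (pixel-centre anchored);
    the y pixel size is written positive because this package uses local
    row-aligned coordinates rather than a north-up CRS.
    """
    tifffile.imwrite(path, np.asarray(array))
    g = transform.gsd_m
    cx, cy = transform.pixel_to_world(0, 0)
    lines = [g, 0.0, 0.0, g, float(cx), float(cy)]
    with open(world_file_path(path), "w") as fh:
        fh.write("\n".join(f"{v:.10g}" for v in lines) + "\n")


def read_raster(path: str) -> tuple[np.ndarray, RasterTransform]:
    """Read a TIFF written by :func:`write_raster` (world file optional)."""
    array = tifffile.imread(path)
    wf = world_file_path(path)
    transform = RasterTransform()
    if os.path.exists(wf):
        with open(wf) as fh:
            vals = [float(line.strip()) for line in fh if line.strip()]
        gx, _, _, gy, cx, cy = vals[:6]
        if not np.isclose(abs(gx), abs(gy)):
            raise ValueError("anisotropic pixel sizes are not supported")
        g = abs(gx)
        transform = RasterTransform(cx - 0.5 * g, cy - 0.5 * g, g * 100.0)
    return array, transform
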