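"""Minimal single-band raster container with an affine grid transform.

Rasters here are plain numpy grids georeferenced by a north-up affine
transform (no rotation/shear), which is all a plot-level zonal-statistics
pipeline needs.  GeoTIFF-style persistence uses :mod:`tifffile` with the
grid transform and band metadata serialised into the ImageDescription tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """North-up affine transform mapping pixel indices to world coordinates.

    ``x0, y0`` is the world coordinate of the raster's top-left corner;
    ``dx > 0`` and ``dy < 0`` are the pixel sizes (world units per pixel)
    in x and y.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy >= 0:
            raise ValueError("expected dx > 0 and dy < 0 (north-up raster)")

    def pixel_center(self, row, col):
        """World coordinates of pixel centers for (row, col) indices."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.dx
        y = self.y0 + (np.asarray(row) + 0.5) * self.dy
        return x, y

    def center_grids(self, shape: tuple[int, int]):
        """Arrays of x and y center coordinates for every pixel of ``shape``."""
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.pixel_center(rows, cols)


@dataclass
class RasterLayer:
    """One reflectance (or index) band on a regular grid.

    Parameters
    ----------
    values : 2-D float array; ``nodata`` marks invalid pixels.
    transform : the grid-to-world affine transform.
    band_center_nm : nominal band center in nm (780 for NIR, 700 for the
        red edge), or ``None`` for derived layers such as a vegetation index.
    nodata : sentinel for invalid pixels (default -9999).
    """

    values: np.ndarray
    transform: GridTransform
    band_center_nm: int | None = None
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values) & (self.values != self.nodata)

    def same_grid(self, other: "RasterLayer") -> bool:
        return self.shape == other.shape and self.transform == other.transform


def write_raster_pair(path, nir: RasterLayer, red_edge: RasterLayer) -> None:
    """Write a two-band (NIR, red edge) float32 TIFF with grid metadata."""
    import tifffile

    if not nir.same_grid(red_edge):
        raise ValueError("bands must share shape and transform")
    t = nir.transform
    meta = {
        "transform": [t.x0, t.y0, t.dx, t.dy],
        "band_center_nm": [nir.band_center_nm, red_edge.band_center_nm],
        "nodata": nir.nodata,
    }
    stack = np.stack([nir.values, red_edge.values]).astype(np.float32)
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def read_raster_pair(path) -> tuple[RasterLayer, RasterLayer]:
    """Read a two-band TIFF written by :func:`write_raster_pair`."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].tags["ImageDescription"].value
    meta = json.loads(desc)
    transform = GridTransform(*meta["transform"])
    nodata = meta.get("nodata", DEFAULT_NODATA)
    centers = meta.get("band_center_nm", [None, None])
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"expected a 2-band raster, got shape {stack.shape}")
    nir = RasterLayer(stack[0], transform, centers[0], nodata)
    red_edge = RasterLayer(stack[1], transform, centers[1], nodata)
    return nir, red_edge
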