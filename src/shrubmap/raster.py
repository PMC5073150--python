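"""Lightweight georeferenced raster container.

All layers in a pipeline run share one projected metric CRS with a
pixel-is-area convention: the grid origin is the top-left corner of the
top-left pixel, x increases eastward, y increases *southward* down rows,
and a pixel spans the half-open interval [x0, x0 + w) x (y0 - h, y0].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RasterGrid", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two rasters that must share a grid do not."""


@dataclass
class RasterGrid:
    """A single-band 2-D raster with an affine north-up geotransform.

    Parameters
    ----------
    data:
        2-D array (rows = north to south). Float layers use ``nan`` as
        nodata; categorical layers use an integer sentinel.
    origin:
        ``(x0, y0)`` map coordinate of the *top-left corner* of the grid.
    cell_size:
        Square pixel edge length in metres.
    nodata:
        Nodata sentinel. ``nan`` for float rasters by default.
    crs:
        Free-form CRS tag; layers are only ever compared for equality.
    """

    data: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    nodata: float = np.nan
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got {self.data.ndim}-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the gridded area."""
        nrow, ncol = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nrow * self.cell_size, x0 + ncol * self.cell_size, y0)

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
            and self.crs == other.crs
        )

    def require_same_grid(self, other: "RasterGrid", names=("left", "right")) -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch between {names[0]} "
                f"(shape={self.shape}, origin={self.origin}, cell={self.cell_size}) "
                f"and {names[1]} "
                f"(shape={other.shape}, origin={other.origin}, cell={other.cell_size})"
            )

    def world_to_pixel(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates -> (row, col) integer indices, half-open pixels."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(np.int64)
        row = np.floor((self.origin[1] - y) / self.cell_size).astype(np.int64)
        return row, col

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) map coordinates of every pixel center as 2-D arrays."""
        nrow, ncol = self.shape
        xs = self.origin[0] + (np.arange(ncol) + 0.5) * self.cell_size
        ys = self.origin[1] - (np.arange(nrow) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    # -- sampling ----------------------------------------------------------
    def value_at(self, x, y):
        """Nearest (containing-pixel) value at map coordinates."""
        row, col = self.world_to_pixel(x, y)
        if np.any((row < 0) | (row >= self.shape[0]) | (col < 0) | (col >= self.shape[1])):
            raise ValueError("coordinates fall outside the raster extent")
        return self.data[row, col]

    def sample_bilinear(self, x, y) -> np.ndarray:
        """Bilinear interpolation between pixel centers; edges are clamped."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(self.contains(x, y)):
            raise ValueError("coordinates fall outside the raster extent")
        # fractional pixel-center coordinates
        fc = (x - self.origin[0]) / self.cell_size - 0.5
        fr = (self.origin[1] - y) / self.cell_size - 0.5
        nrow, ncol = self.shape
        c0 = np.clip(np.floor(fc).astype(np.int64), 0, ncol - 1)
        r0 = np.clip(np.floor(fr).astype(np.int64), 0, nrow - 1)
        c1 = np.clip(c0 + 1, 0, ncol - 1)
        r1 = np.clip(r0 + 1, 0, nrow - 1)
        wc = np.clip(fc - c0, 0.0, 1.0)
        wr = np.clip(fr - r0, 0.0, 1.0)
        d = self.data.astype(float)
        top = d[r0, c0] * (1 - wc) + d[r0, c1] * wc
        bot = d[r1, c0] * (1 - wc) + d[r1, c1] * wc
        return top * (1 - wr) + bot * wr

    # -- resampling --------------------------------------------------------
    def block_aggregate(self, factor: int, how: str = "mean") -> "RasterGrid":
        """Aggregate ``factor`` x ``factor`` pixel blocks (e.g. 1 m -> 3 m)."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        nrow, ncol = self.shape
        data = self.data.astype(float)
        if nrow % factor or ncol % factor:  # pad partial edge blocks with nan
            pr = (-nrow) % factor
            pc = (-ncol) % factor
            data = np.pad(data, ((0, pr), (0, pc)), constant_values=np.nan)
            nrow, ncol = data.shape
        blocks = data.reshape(nrow // factor, factor, ncol // factor, factor)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            if how == "mean":
                out = np.nanmean(blocks.astype(float), axis=(1, 3))
            elif how == "max":
                out = np.nanmax(blocks.astype(float), axis=(1, 3))
            elif how == "min":
                out = np.nanmin(blocks.astype(float), axis=(1, 3))
            else:
                raise ValueError(f"unknown aggregation {how!r}")
        return RasterGrid(out, self.origin, self.cell_size * factor, crs=self.crs)

    def upsample(self, factor: int) -> "RasterGrid":
        """Repeat each pixel ``factor`` x ``factor`` times (e.g. 3 m -> 1 m)."""
        out = np.repeat(np.repeat(self.data, factor, axis=0), factor, axis=1)
        return RasterGrid(out, self.origin, self.cell_size / factor,
                          nodata=self.nodata, crs=self.crs)

    def like(self, data: np.ndarray, nodata=None) -> "RasterGrid":
        """A new raster on this grid carrying ``data``."""
        if np.shape(data) != self.shape:
            raise ValueError("data shape does not match grid")
        return replace(self, data=np.asarray(data),
                       nodata=self.nodata if nodata is None else nodata)

    def mask_where(self, mask: np.ndarray) -> "RasterGrid":
        out = self.data.astype(float).copy()
        out[np.asarray(mask, bool)] = np.nan
        return self.like(out, nodata=np.nan)
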