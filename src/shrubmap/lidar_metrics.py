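"""Structural canopy rasters gridded from the classified point cloud.

Every return is assigned to exactly one 1 m pixel (half-open intervals).
Per pixel the module computes ground (DEM) and first-surface (DSM)
elevation, height percentiles (P75/P90/P95, linear interpolation between
order statistics), population skewness, excess kurtosis and the
coefficient of variation of return heights, and the complementary canopy
cover / penetration fractions around a 2.5 m height break. "Open areas"
are pixels whose penetration (fraction of returns at or below the break)
exceeds 90%; a Euclidean distance-to-open raster supports the detection
models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .pointcloud import PointCloud
from .raster import RasterGrid

__all__ = ["StructuralStack", "grid_metrics", "open_area_mask"]

#: returns within this height of the ground model count as ground returns
GROUND_HEIGHT_TOL = 0.1
#: minimum returns for skewness/kurtosis
MIN_RETURNS_MOMENTS = 4


@dataclass
class StructuralStack:
    dem: RasterGrid
    dsm: RasterGrid
    p75: RasterGrid
    p90: RasterGrid
    p95: RasterGrid
    kurtosis: RasterGrid
    skewness: RasterGrid
    cv_height: RasterGrid
    cover_below_2p5: RasterGrid
    penetration: RasterGrid
    canopy_cover_above_2p5: RasterGrid
    distance_to_open: RasterGrid | None = None

    def as_dict(self) -> dict[str, RasterGrid]:
        out = {
            "dem": self.dem,
            "dsm": self.dsm,
            "p75": self.p75,
            "p90": self.p90,
            "p95": self.p95,
            "kurtosis": self.kurtosis,
            "skewness": self.skewness,
            "cv_height": self.cv_height,
            "cover_below_2p5": self.cover_below_2p5,
            "penetration": self.penetration,
            "canopy_cover_above_2p5": self.canopy_cover_above_2p5,
        }
        if self.distance_to_open is not None:
            out["distance_to_open"] = self.distance_to_open
        return out


def _group_percentile(sorted_h, starts, counts, q):
    """Vectorized per-group percentile (linear interpolation) on presorted data."""
    pos = (counts - 1) * (q / 100.0)
    lo = np.floor(pos).astype(np.int64)
    hi = np.ceil(pos).astype(np.int64)
    frac = pos - lo
    vlo = sorted_h[starts + lo]
    vhi = sorted_h[starts + hi]
    return vlo + frac * (vhi - vlo)


def grid_metrics(
    cloud: PointCloud,
    cell_size: float = 1.0,
    height_break: float = 2.5,
    grid: RasterGrid | None = None,
    ground_tol: float = GROUND_HEIGHT_TOL,
    fill_dem: bool = True,
) -> StructuralStack:
    """Grid the normalized cloud into the structural raster stack.

    Parameters
    ----------
    grid:
        Template grid; derived from the cloud's bounding box when omitted.
    fill_dem:
        Fill pixels without ground returns from the nearest pixel that has
        one (nearest-neighbour), so terrain derivatives stay defined.
    """
    if cloud.height_above_ground is None:
        raise ValueError("cloud heights not normalized; run normalize_heights first")
    if grid is None:
        if len(cloud) == 0:
            raise ValueError("cannot infer a grid from an empty cloud")
        x0 = np.floor(cloud.x.min() / cell_size) * cell_size
        y1 = np.ceil(cloud.y.max() / cell_size) * cell_size
        ncol = int(np.ceil((cloud.x.max() - x0) / cell_size)) or 1
        nrow = int(np.ceil((y1 - cloud.y.min()) / cell_size)) or 1
        grid = RasterGrid(np.zeros((nrow, ncol)), (x0, y1), cell_size)
    nrow, ncol = grid.shape
    npix = nrow * ncol
    nan = np.full(npix, np.nan)

    def stack_from(flat_arrays):
        return StructuralStack(*[grid.like(a.reshape(nrow, ncol)) for a in flat_arrays])

    if len(cloud) == 0:
        warnings.warn("empty point cloud: all-nodata structural stack", stacklevel=2)
        return stack_from([nan.copy() for _ in range(11)])

    row, col = grid.world_to_pixel(cloud.x, cloud.y)
    inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    cloud = cloud.subset(inside)
    pid = (row[inside] * ncol + col[inside]).astype(np.int64)
    h = cloud.height_above_ground
    z = cloud.z

    counts = np.bincount(pid, minlength=npix).astype(np.int64)
    has = counts > 0

    # surfaces
    dsm = np.full(npix, -np.inf)
    np.maximum.at(dsm, pid, z)
    dsm[~has] = np.nan
    dem = np.full(npix, np.inf)
    g = cloud.is_ground
    np.minimum.at(dem, pid[g], z[g])
    dem[np.isinf(dem)] = np.nan
    if fill_dem and np.any(np.isnan(dem)) and np.any(~np.isnan(dem)):
        dem2 = dem.reshape(nrow, ncol)
        missing = np.isnan(dem2)
        _, (ir, ic) = ndimage.distance_transform_edt(missing, return_indices=True)
        dem = np.where(missing, dem2[ir, ic], dem2).ravel()
    dsm = np.where(has, np.fmax(dsm, dem), np.nan)  # dsm >= dem

    # height moments
    s1 = np.bincount(pid, weights=h, minlength=npix)
    with np.errstate(invalid="ignore"):
        mean = np.where(has, s1 / np.where(has, counts, 1), np.nan)
    dev = h - mean[pid]
    m2 = np.bincount(pid, weights=dev**2, minlength=npix) / np.where(has, counts, 1)
    m3 = np.bincount(pid, weights=dev**3, minlength=npix) / np.where(has, counts, 1)
    m4 = np.bincount(pid, weights=dev**4, minlength=npix) / np.where(has, counts, 1)
    sd = np.sqrt(m2)
    nz = sd > 0
    cv = np.where(has, 0.0, np.nan)
    cv[has & nz] = sd[has & nz] / mean[has & nz]
    okm = has & nz & (counts >= MIN_RETURNS_MOMENTS)
    skew = np.where(okm, m3 / np.where(okm, sd**3, 1), np.nan)
    kurt = np.where(okm, m4 / np.where(okm, m2**2, 1) - 3.0, np.nan)  # excess

    # percentiles via per-pixel sorted heights
    order = np.lexsort((h, pid))
    sorted_h = h[order]
    starts = np.zeros(npix, dtype=np.int64)
    starts[1:] = np.cumsum(counts)[:-1]
    p75 = nan.copy()
    p90 = nan.copy()
    p95 = nan.copy()
    hs, hst, hc = has, starts[has], counts[has]
    p75[hs] = _group_percentile(sorted_h, hst, hc, 75)
    p90[hs] = _group_percentile(sorted_h, hst, hc, 90)
    p95[hs] = _group_percentile(sorted_h, hst, hc, 95)

    # cover fractions around the height break
    above = h >= height_break
    low = (h > ground_tol) & (h < height_break)
    n_above = np.bincount(pid, weights=above.astype(float), minlength=npix)
    n_low = np.bincount(pid, weights=low.astype(float), minlength=npix)
    denom = np.where(has, counts, 1)
    cover_above = np.where(has, n_above / denom, np.nan)
    cover_below = np.where(has, n_low / denom, np.nan)
    penetration = np.where(has, 1.0 - cover_above, np.nan)

    return stack_from(
        [dem, dsm, p75, p90, p95, kurt, skew, cv, cover_below, penetration, cover_above]
    )


def open_area_mask(
    stack: StructuralStack, threshold: float = 0.9
) -> tuple[RasterGrid, RasterGrid]:
    """Open-area boolean raster and Euclidean distance (m) to the nearest open pixel.

    Open means penetration (fraction of returns at or below 2.5 m) above
    ``threshold``, i.e. less than 10% canopy cover by default. Distance is
    measured between pixel centers and is 0 inside open areas.
    """
    pen = stack.penetration.data.astype(float)
    grid = stack.penetration
    is_open = np.nan_to_num(pen, nan=-1.0) > threshold
    open_raster = grid.like(is_open, nodata=0)
    if not is_open.any():
        warnings.warn("no open pixels: distance-to-open is all nodata", stacklevel=2)
        return open_raster, grid.like(np.full(grid.shape, np.nan))
    dist = ndimage.distance_transform_edt(~is_open, sampling=grid.cell_size)
    return open_raster, grid.like(dist.astype(float))
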