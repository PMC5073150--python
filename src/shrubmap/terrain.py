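"""Orographic predictors from the DEM.

Slope and aspect use Horn's 3x3 weighted finite differences; aspect is
reported as "northness" (cosine of the downslope azimuth: +1 facing north,
-1 facing south). Curvatures come from second-order finite differences of
the 3x3 window (Zevenbergen-Thorne quadratic surface) with the sign
convention *positive = concave* and units of 1/(100 m). The topographic
wetness index is ln(a / tan(beta)) with the specific contributing area a
from D8 single-flow-direction accumulation over a pit-filled DEM.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np

from .raster import RasterGrid

__all__ = [
    "OrographicStack",
    "slope_aspect",
    "curvatures",
    "fill_pits",
    "topographic_wetness",
    "compute_orographic_stack",
]

TAN_SLOPE_FLOOR = 1e-6


@dataclass
class OrographicStack:
    slope: RasterGrid            # degrees
    northness: RasterGrid        # [-1, 1]
    curvature: RasterGrid        # 1/(100 m), positive = concave
    plan_curvature: RasterGrid
    profile_curvature: RasterGrid
    twi: RasterGrid

    def as_dict(self) -> dict[str, RasterGrid]:
        return {
            "slope": self.slope,
            "northness": self.northness,
            "curvature": self.curvature,
            "plan_curvature": self.plan_curvature,
            "profile_curvature": self.profile_curvature,
            "twi": self.twi,
        }


def _gradients(dem: RasterGrid):
    """Horn first derivatives and central second derivatives, edge-padded."""
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3")
    z = np.pad(dem.data.astype(float), 1, mode="edge")
    L = dem.cell_size
    c = z[1:-1, 1:-1]
    n, s = z[:-2, 1:-1], z[2:, 1:-1]
    w, e = z[1:-1, :-2], z[1:-1, 2:]
    nw, ne = z[:-2, :-2], z[:-2, 2:]
    sw, se = z[2:, :-2], z[2:, 2:]
    # Horn weights; x east, y north (rows run southward)
    zx = ((ne + 2 * e + se) - (nw + 2 * w + sw)) / (8 * L)
    zy = ((nw + 2 * n + ne) - (sw + 2 * s + se)) / (8 * L)
    zxx = (e - 2 * c + w) / L**2
    zyy = (n - 2 * c + s) / L**2
    zxy = (ne - nw - se + sw) / (4 * L**2)
    return zx, zy, zxx, zyy, zxy


def slope_aspect(dem: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Slope (degrees) and northness rasters.

    Flat pixels (zero gradient) get slope 0 and northness 0.
    """
    zx, zy, *_ = _gradients(dem)
    g = np.hypot(zx, zy)
    slope = np.degrees(np.arctan(g))
    with np.errstate(invalid="ignore", divide="ignore"):
        northness = np.where(g > 0, -zy / np.where(g > 0, g, 1.0), 0.0)
    return dem.like(slope), dem.like(northness)


def curvatures(dem: RasterGrid) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """General, plan, and profile curvature (1/(100 m), positive = concave)."""
    zx, zy, zxx, zyy, zxy = _gradients(dem)
    g2 = zx**2 + zy**2
    general = (zxx + zyy) * 100.0
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(
            g2 > 0,
            (zxx * zx**2 + 2 * zxy * zx * zy + zyy * zy**2)
            / (np.where(g2 > 0, g2, 1.0) * (1 + g2) ** 1.5) * 100.0,
            0.0,
        )
        plan = np.where(
            g2 > 0,
            (zxx * zy**2 - 2 * zxy * zx * zy + zyy * zx**2)
            / np.where(g2 > 0, g2, 1.0) ** 1.5 * 100.0,
            0.0,
        )
    return dem.like(general), dem.like(plan), dem.like(profile)


def fill_pits(dem: RasterGrid, epsilon: float = 1e-6) -> RasterGrid:
    """Priority-flood depression filling with a tiny drainage gradient."""
    z = dem.data.astype(float).copy()
    nrow, ncol = z.shape
    filled = np.full_like(z, np.inf)
    visited = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for r in range(nrow):
        for c in (0, ncol - 1):
            heapq.heappush(heap, (z[r, c], r, c))
            visited[r, c] = True
    for c in range(1, ncol - 1):
        for r in (0, nrow - 1):
            heapq.heappush(heap, (z[r, c], r, c))
            visited[r, c] = True
    nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    while heap:
        elev, r, c = heapq.heappop(heap)
        filled[r, c] = elev
        for dr, dc in nbrs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol and not visited[rr, cc]:
                visited[rr, cc] = True
                heapq.heappush(heap, (max(z[rr, cc], elev + epsilon), rr, cc))
    return dem.like(filled)


_D8_OFFSETS = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)
_D8_DIST = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0, np.sqrt(2)])


def d8_flow_accumulation(dem: RasterGrid) -> np.ndarray:
    """Number of cells draining through each cell (including itself), D8.

    Flow goes to the single neighbor with the steepest distance-weighted
    drop; boundary cells with no downslope neighbor drain off-grid.
    """
    z = dem.data.astype(float)
    nrow, ncol = z.shape
    best_drop = np.full(z.shape, 0.0)
    target = np.full(z.shape, -1, dtype=np.int64)
    idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    for k, (dr, dc) in enumerate(_D8_OFFSETS):
        rs = slice(max(0, -dr), nrow - max(0, dr))
        cs = slice(max(0, -dc), ncol - max(0, dc))
        nrs = slice(rs.start + dr, rs.stop + dr)
        ncs = slice(cs.start + dc, cs.stop + dc)
        drop = (z[rs, cs] - z[nrs, ncs]) / (_D8_DIST[k] * dem.cell_size)
        better = drop > best_drop[rs, cs]
        best_drop[rs, cs] = np.where(better, drop, best_drop[rs, cs])
        target_block = target[rs, cs]
        target[rs, cs] = np.where(better, idx[nrs, ncs], target_block)
    acc = np.ones(nrow * ncol)
    order = np.argsort(z, axis=None)[::-1]  # high to low
    flat_target = target.ravel()
    for i in order:
        t = flat_target[i]
        if t >= 0:
            acc[t] += acc[i]
    return acc.reshape(nrow, ncol)


def topographic_wetness(dem: RasterGrid, slope: RasterGrid | None = None) -> RasterGrid:
    """TWI = ln(a / tan(beta)) from pit-filled D8 accumulation.

    ``a`` is the specific contributing area (accumulated cell area divided
    by the cell width as contour length); ``tan(beta)`` is floored at 1e-6.
    An all-flat DEM yields an all-nodata raster with a warning.
    """
    if np.nanmax(dem.data) - np.nanmin(dem.data) == 0:
        warnings.warn("DEM is flat; TWI undefined", stacklevel=2)
        return dem.like(np.full(dem.shape, np.nan))
    filled = fill_pits(dem)
    acc = d8_flow_accumulation(filled)
    a = acc * dem.cell_size  # (cells * cell_area) / cell_size
    if slope is None:
        slope, _ = slope_aspect(filled)
    tanb = np.maximum(np.tan(np.radians(slope.data.astype(float))), TAN_SLOPE_FLOOR)
    return dem.like(np.log(a / tanb))


def compute_orographic_stack(dem: RasterGrid) -> OrographicStack:
    slope, northness = slope_aspect(dem)
    general, plan, profile = curvatures(dem)
    twi = topographic_wetness(dem, slope=None)
    return OrographicStack(slope, northness, general, plan, profile, twi)
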