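"""Post-map spatial ecology: LISA clustering, composition, distances.

Species abundance is tabulated on a coarse grid (default 100 m cells) as
the count of 1 m presence pixels per cell. Anselin's Local Moran's I with
row-standardized queen-contiguity weights and conditional permutation
significance labels each cell a high-high/low-low cluster or a
high-low/low-high outlier. Distance profiles relate invaded area to the
Euclidean distance from roads or impervious surfaces, and composition
summaries report invaded area per land-cover class and per park polygon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .detection import SpeciesMap
from .raster import RasterGrid
from .synthetic_scene import LANDCOVER_NAMES, PERVIOUS_CLASSES

__all__ = [
    "AbundanceGrid",
    "LisaResult",
    "abundance_grid",
    "local_morans_i",
    "distance_profile",
    "composition_summary",
]

LISA_CATEGORIES = ("HH", "LL", "HL", "LH", "ns")


@dataclass
class AbundanceGrid:
    counts: np.ndarray        # (nrow, ncol) invaded-pixel counts per cell
    cell_size: float
    origin: tuple[float, float]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class LisaResult:
    local_i: np.ndarray
    p_value: np.ndarray       # pseudo p from conditional permutation
    category: np.ndarray      # strings from LISA_CATEGORIES
    pct_in_clusters: float    # % of significant invaded cells in HH/LL
    pct_in_outliers: float    # % in HL/LH


def abundance_grid(species_map: SpeciesMap, cell_size: float = 100.0) -> AbundanceGrid:
    """Exact per-cell presence-pixel counts (conserves the map total)."""
    presence = species_map.presence
    data = np.nan_to_num(presence.data.astype(float), nan=0.0) > 0
    fine = presence.cell_size
    factor = cell_size / fine
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("cell_size must be a multiple of the map resolution")
    factor = int(round(factor))
    nrow, ncol = data.shape
    crow = int(np.ceil(nrow / factor))
    ccol = int(np.ceil(ncol / factor))
    padded = np.zeros((crow * factor, ccol * factor), dtype=float)
    padded[:nrow, :ncol] = data
    counts = padded.reshape(crow, factor, ccol, factor).sum(axis=(1, 3))
    return AbundanceGrid(counts.astype(np.int64), cell_size, presence.origin)


def _queen_neighbors(nrow, ncol):
    """List of (flat neighbor indices) per cell, queen contiguity."""
    out = []
    for r in range(nrow):
        for c in range(ncol):
            nbr = [
                rr * ncol + cc
                for rr in range(max(0, r - 1), min(nrow, r + 2))
                for cc in range(max(0, c - 1), min(ncol, c + 2))
                if (rr, cc) != (r, c)
            ]
            out.append(np.asarray(nbr, dtype=np.int64))
    return out


def local_morans_i(
    grid: AbundanceGrid,
    alpha: float = 0.05,
    permutations: int = 999,
    seed: int = 0,
) -> LisaResult:
    """Anselin Local Moran's I with conditional-permutation significance.

    ``I_i = (z_i / m2) * sum_j w_ij z_j`` on deviations ``z`` from the
    grid mean, with row-standardized queen weights and
    ``m2 = sum(z^2)/n``. Each cell's pseudo p-value compares its observed
    spatial lag with lags of ``permutations`` random draws of its
    neighbors from the remaining cells (one-sided on the observed tail).
    Cells are labelled HH/LL (clusters) or HL/LH (outliers) when
    ``p <= alpha``; summary percentages cover significant invaded cells
    only.
    """
    counts = grid.counts.astype(float)
    nrow, ncol = counts.shape
    n = counts.size
    if n < 9:
        raise ValueError("need at least 9 cells")
    x = counts.ravel()
    if np.ptp(x) == 0:
        raise ValueError("constant abundance grid: Local Moran's I undefined")
    z = x - x.mean()
    m2 = float((z**2).sum()) / n
    neighbors = _queen_neighbors(nrow, ncol)
    lag = np.array([z[nb].mean() for nb in neighbors])
    local_i = z / m2 * lag

    rng = np.random.default_rng(seed)
    p = np.ones(n)
    for i in range(n):
        nb = neighbors[i]
        k = nb.size
        others = np.delete(z, i)
        # sample k pseudo-neighbors from the other n-1 cells, without replacement
        idx = np.argpartition(rng.random((permutations, others.size)), k, axis=1)[:, :k]
        sim_lag = others[idx].mean(axis=1)
        sim_i = z[i] / m2 * sim_lag
        if local_i[i] >= 0:
            larger = int(np.sum(sim_i >= local_i[i]))
        else:
            larger = int(np.sum(sim_i <= local_i[i]))
        p[i] = (larger + 1) / (permutations + 1)

    cat = np.full(n, "ns", dtype=object)
    sig = p <= alpha
    hi = z > 0
    lag_hi = lag > 0
    cat[sig & hi & lag_hi] = "HH"
    cat[sig & ~hi & ~lag_hi] = "LL"
    cat[sig & hi & ~lag_hi] = "HL"
    cat[sig & ~hi & lag_hi] = "LH"

    invaded = x > 0
    sig_invaded = invaded & sig
    n_sig = int(sig_invaded.sum())
    if n_sig:
        in_clusters = np.isin(cat, ("HH", "LL")) & sig_invaded
        in_outliers = np.isin(cat, ("HL", "LH")) & sig_invaded
        pct_clusters = 100.0 * in_clusters.sum() / n_sig
        pct_outliers = 100.0 * in_outliers.sum() / n_sig
    else:
        pct_clusters = pct_outliers = float("nan")
    return LisaResult(
        local_i.reshape(nrow, ncol),
        p.reshape(nrow, ncol),
        cat.reshape(nrow, ncol),
        pct_clusters,
        pct_outliers,
    )


def distance_profile(
    species_map: SpeciesMap,
    feature: RasterGrid,
    bin_width: float = 50.0,
    land_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Invaded area and invaded proportion by distance from a feature.

    ``feature`` is a boolean raster (e.g. roads). Distances are Euclidean
    from pixel centers to the nearest feature pixel. The proportion
    denominator is the (optionally masked, e.g. pervious) land area in
    each bin. Bin areas sum exactly to the total presence area.
    """
    species_map.presence.require_same_grid(feature, ("map", "feature"))
    feat = np.nan_to_num(feature.data.astype(float), nan=0.0) > 0
    if not feat.any():
        raise ValueError("feature raster has no feature pixels")
    cell = feature.cell_size
    dist = ndimage.distance_transform_edt(~feat, sampling=cell)
    presence = np.nan_to_num(species_map.presence.data.astype(float), nan=0.0) > 0
    land = np.ones_like(presence) if land_mask is None else np.asarray(land_mask, bool)
    nbins = int(np.ceil(dist.max() / bin_width)) + 1
    idx = np.minimum((dist / bin_width).astype(int), nbins - 1)
    area_per_pixel_km2 = cell * cell * 1e-6
    pres_area = np.bincount(idx[presence], minlength=nbins) * area_per_pixel_km2
    land_area = np.bincount(idx[land], minlength=nbins) * area_per_pixel_km2
    with np.errstate(invalid="ignore", divide="ignore"):
        proportion = np.where(land_area > 0, pres_area / land_area, np.nan)
    return pd.DataFrame(
        {
            "distance_lo_m": np.arange(nbins) * bin_width,
            "distance_hi_m": (np.arange(nbins) + 1) * bin_width,
            "invaded_area_km2": pres_area,
            "land_area_km2": land_area,
            "invaded_proportion": proportion,
        }
    )


def composition_summary(
    species_map: SpeciesMap,
    landcover: RasterGrid,
    parks: list | None = None,
) -> dict:
    """Presence area per land-cover class; per-park occurrence flags.

    ``parks`` is an optional list of shapely polygons. Areas are km2
    (pixel count x cell area). The parks summary reports, per polygon,
    the invaded area inside it and whether any presence pixel occurs.
    """
    species_map.presence.require_same_grid(landcover, ("map", "landcover"))
    presence = np.nan_to_num(species_map.presence.data.astype(float), nan=0.0) > 0
    cell = landcover.cell_size
    px_km2 = cell * cell * 1e-6
    per_class = {}
    lc = landcover.data.astype(int)
    for code, name in LANDCOVER_NAMES.items():
        per_class[name] = float(np.sum(presence & (lc == code)) * px_km2)
    out = {
        "total_area_km2": float(presence.sum() * px_km2),
        "area_by_class_km2": per_class,
        "pervious_area_km2": float(np.isin(lc, PERVIOUS_CLASSES).sum() * px_km2),
    }
    if parks is not None:
        xs, ys = landcover.pixel_centers()
        flags = []
        areas = []
        px = xs[presence]
        py = ys[presence]
        for poly in parks:
            inside = shapely.contains_xy(poly, px, py)
            areas.append(float(inside.sum() * px_km2))
            flags.append(bool(inside.any()))
        out["parks"] = {
            "occurrence_flags": flags,
            "invaded_area_km2": areas,
            "proportion_with_occurrence": float(np.mean(flags)) if flags else float("nan"),
        }
    return out
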