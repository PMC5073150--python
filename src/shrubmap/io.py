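"""File formats: GeoTIFF rasters/cubes, ASCII point clouds, CSV tables.

Rasters round-trip through GeoTIFF with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GDAL_NODATA) so external GIS tools read
them directly. Point clouds use the whitespace ASCII interchange format
``x y z class return``. Spectra and field plots are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .pointcloud import PointCloud
from .raster import RasterGrid
from .spectral import SpectralLibrary, Spectrum
from .synthetic_scene import PlotRecord

__all__ = [
    "write_raster", "read_raster",
    "write_cube", "read_cube",
    "write_point_cloud", "read_point_cloud",
    "write_spectra_csv", "read_spectra_csv",
    "write_plots_csv", "read_plots_csv",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _geo_tags(raster: RasterGrid):
    cs = float(raster.cell_size)
    x0, y0 = raster.origin
    nodata = raster.nodata
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]


def write_raster(path, raster: RasterGrid, dtype=np.float32) -> None:
    meta = {"crs": raster.crs}
    tifffile.imwrite(
        path,
        raster.data.astype(dtype),
        extratags=_geo_tags(raster),
        description=json.dumps(meta),
    )


def _parse_geo(page):
    scale = page.tags[_TAG_PIXEL_SCALE].value
    tie = page.tags[_TAG_TIEPOINT].value
    nod = page.tags.get(_TAG_GDAL_NODATA)
    nodata = float(nod.value) if nod is not None else np.nan
    crs = "local-metric"
    desc = page.tags.get("ImageDescription")
    meta = {}
    if desc is not None:
        try:
            meta = json.loads(desc.value)
            crs = meta.get("crs", crs)
        except (json.JSONDecodeError, TypeError):
            pass
    return float(scale[0]), (float(tie[3]), float(tie[4])), nodata, crs, meta


def read_raster(path) -> RasterGrid:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        cell, origin, nodata, crs, _ = _parse_geo(page)
    return RasterGrid(data, origin, cell, nodata=nodata, crs=crs)


def write_cube(path, cube: np.ndarray, grid: RasterGrid,
               wavelengths_nm: np.ndarray) -> None:
    """Multi-band GeoTIFF with band-center wavelengths in the metadata."""
    if cube.shape[0] != len(wavelengths_nm):
        raise ValueError("wavelength count does not match cube bands")
    meta = {"crs": grid.crs, "wavelength_nm": [float(w) for w in wavelengths_nm]}
    tifffile.imwrite(
        path,
        cube.astype(np.float32),
        extratags=_geo_tags(grid),
        description=json.dumps(meta),
        metadata=None,
    )


def read_cube(path) -> tuple[np.ndarray, RasterGrid, np.ndarray]:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        cell, origin, nodata, crs, meta = _parse_geo(tif.pages[0])
    wl = np.asarray(meta.get("wavelength_nm", []), dtype=float)
    grid = RasterGrid(np.zeros(data.shape[-2:]), origin, cell, nodata=nodata, crs=crs)
    return data, grid, wl


def write_point_cloud(path, cloud: PointCloud) -> None:
    arr = np.column_stack(
        [cloud.x, cloud.y, cloud.z, cloud.classification, cloud.return_number]
    )
    np.savetxt(path, arr, fmt="%.3f %.3f %.3f %d %d")


def read_point_cloud(path) -> PointCloud:
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] < 4:
        raise ValueError("point cloud file needs at least x y z class columns")
    ret = arr[:, 4].astype(int) if arr.shape[1] > 4 else None
    return PointCloud(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3].astype(int), ret)


def write_spectra_csv(path, library: SpectralLibrary) -> None:
    frames = []
    for sp in library.species():
        for spec in library[sp]:
            frames.append(pd.DataFrame({
                "wavelength_nm": spec.wavelength_nm,
                "reflectance_pct": spec.reflectance_pct,
                "species": sp,
                "sample_id": spec.sample_id,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_csv(path) -> SpectralLibrary:
    df = pd.read_csv(path)
    lib = SpectralLibrary()
    for (sp, sid), g in df.groupby(["species", "sample_id"], sort=True):
        g = g.sort_values("wavelength_nm")
        lib.add(Spectrum(g["wavelength_nm"].to_numpy(),
                         g["reflectance_pct"].to_numpy(),
                         species=sp, sample_id=str(sid)))
    return lib


_PLOT_COLUMNS = ["x", "y", "true_x", "true_y", "species", "presence", "role", "stratum"]


def write_plots_csv(path, plots: list[PlotRecord]) -> None:
    pd.DataFrame([
        {c: getattr(p, c) for c in _PLOT_COLUMNS} for p in plots
    ]).to_csv(path, index=False)


def read_plots_csv(path) -> list[PlotRecord]:
    df = pd.read_csv(path)
    if "true_x" not in df.columns:
        df["true_x"] = df["x"]
        df["true_y"] = df["y"]
    out = []
    for _, r in df.iterrows():
        out.append(PlotRecord(
            float(r["x"]), float(r["y"]), float(r["true_x"]), float(r["true_y"]),
            str(r["species"]), bool(r["presence"]), str(r["role"]), str(r["stratum"]),
        ))
    return out
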