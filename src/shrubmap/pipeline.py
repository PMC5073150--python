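"""End-to-end pipeline: scene -> predictors -> detection -> assessment -> spatial.

Stages run in dependency order on a single shared 1 m grid (irradiance is
computed at 3 m — an exact 3x block aggregation — and repeated back onto
the 1 m grid). Every stage logs its parameters and a digest of its
outputs; the run returns (and optionally writes) a JSON metrics report
whose serialization is byte-stable under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import assessment as assess_mod
from . import spatial_analysis as spatial_mod
from .config import PipelineConfig
from .detection import (
    FeatureStack, SpeciesMap, build_masks, fit_and_predict, merge_strata,
)
from .irradiance import compute_irradiance, fit_canopy_profile_grid, horizon_and_svf
from .lidar_metrics import grid_metrics, open_area_mask
from .pointcloud import normalize_heights
from .raster import RasterGrid
from .spectral import CHANNEL_SUBSETS, sam_rule_image
from .synthetic_scene import LANDCOVER_CODES, Scene, generate_scene
from .terrain import compute_orographic_stack

logger = logging.getLogger("shrubmap")

__all__ = ["PipelineResult", "run_pipeline", "StageError"]

SPECIES = ("blackberry", "ivy")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    scene: Scene
    structural: object
    orographic: object
    irradiance: object
    rule_images: dict
    maps: dict                    # species -> {open, closed, merged} SpeciesMap
    report: dict

    def report_json(self) -> str:
        return json.dumps(self.report, sort_keys=True, indent=1)


def _digest(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                logger.info("stage %s start", name)
                return fn(*a, **k)
            except Exception as exc:  # noqa: BLE001 - named-stage abort
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def _distance_to(landcover: RasterGrid, codes) -> RasterGrid:
    from scipy import ndimage

    target = np.isin(landcover.data.astype(int), codes)
    if not target.any():
        return landcover.like(np.full(landcover.shape, np.nan))
    d = ndimage.distance_transform_edt(~target, sampling=landcover.cell_size)
    return landcover.like(d.astype(float))


def _image_references(scene: Scene, species: str, open_mask: np.ndarray) -> np.ndarray:
    """Pixel spectra extracted at open-area training presence plots."""
    grid = scene.grid
    refs = []
    for p in scene.plots:
        if p.species != species or p.role != "train" or p.stratum != "open":
            continue
        r, c = grid.world_to_pixel(p.x, p.y)
        if 0 <= r < grid.shape[0] and 0 <= c < grid.shape[1] and open_mask[r, c]:
            refs.append(scene.cube[:, r, c].astype(float))
    if not refs:
        raise ValueError(f"no open training plots to extract {species} references")
    return np.vstack(refs)


def run_pipeline(config: PipelineConfig | None = None,
                 output_dir: str | Path | None = None) -> PipelineResult:
    """Execute every stage on the synthetic scene defined by ``config``.

    When ``output_dir`` is given, rasters, maps, tables and the JSON
    metrics report are written there.
    """
    config = config or PipelineConfig()
    scene_cfg = config.scene.to_scene_config(config.seed)

    scene = _stage("scene")(generate_scene)(scene_cfg)
    grid = scene.grid

    @_stage("structural")
    def _structural():
        cloud = normalize_heights(scene.cloud, scene.truth.dem)
        stack = grid_metrics(cloud, scene_cfg.cell_size_m, grid=grid)
        open_r, dist_open = open_area_mask(stack)
        stack.distance_to_open = dist_open
        return cloud, stack, open_r

    cloud, structural, open_raster = _structural()

    orographic = _stage("terrain")(compute_orographic_stack)(structural.dem)

    @_stage("irradiance")
    def _irradiance():
        f = config.irradiance.resolution_factor
        dem3 = structural.dem.block_aggregate(f, "mean")
        dsm3 = structural.dsm.block_aggregate(f, "max")
        dsm3 = dsm3.like(np.fmax(dsm3.data, dem3.data))
        icfg = config.irradiance.to_irradiance_config()
        profiles = fit_canopy_profile_grid(cloud, dem3,
                                           icfg.extinction_height_m,
                                           icfg.min_canopy_returns)
        result = compute_irradiance(dem3, dsm3, profiles, icfg)

        def back(r):
            up = r.upsample(f)
            return grid.like(up.data[: grid.shape[0], : grid.shape[1]])

        return result, back(result.direct_mean_daily), back(result.diffuse_mean_daily)

    irr_result, direct1, diffuse1 = _irradiance()

    cover_above = structural.canopy_cover_above_2p5
    open_mask = np.nan_to_num(cover_above.data.astype(float), nan=1.0) < config.detection.cover_break

    @_stage("sam")
    def _sam():
        if not config.detection.use_spectral or scene.cube is None:
            warnings.warn("no reflectance cube: spectral stage skipped")
            return {}
        rules = {}
        for sp in SPECIES:
            refs = _image_references(scene, sp, open_mask)
            rules[f"rule_{sp}_all"] = sam_rule_image(
                scene.cube, refs, scene.bands, grid, None, open_mask)
            rules[f"rule_{sp}_subset"] = sam_rule_image(
                scene.cube, refs, scene.bands, grid, CHANNEL_SUBSETS[sp], open_mask)
        return rules

    rule_images = _sam()

    landcover = scene.truth.cover_type
    mask = _stage("masks")(build_masks)(structural, landcover)

    base_layers = {
        **structural.as_dict(),
        **orographic.as_dict(),
        "landcover": landcover,
        "distance_to_grass": _distance_to(landcover, [LANDCOVER_CODES["grass"]]),
        "distance_to_impervious": _distance_to(
            landcover, [LANDCOVER_CODES["paved"], LANDCOVER_CODES["building"]]),
        "direct_irradiance": direct1,
        "diffuse_irradiance": diffuse1,
    }
    # moment layers can be nodata on sparse pixels; give the forest a neutral fill
    for name in ("kurtosis", "skewness"):
        lyr = base_layers[name]
        base_layers[name] = lyr.like(np.nan_to_num(lyr.data.astype(float), nan=0.0))

    @_stage("detection")
    def _detect():
        maps = {}
        models = {}
        det = config.detection
        for sp in SPECIES:
            per = {}
            if rule_images:
                open_layers = dict(base_layers)
                open_layers.update(rule_images)
                open_stack = FeatureStack(open_layers, "open", sp)
                per["open"], models[(sp, "open")] = fit_and_predict(
                    open_stack, scene.plots, mask, open_mask,
                    det.n_trees, det.corr_threshold, config.seed, det.select_variables)
            closed_stack = FeatureStack(dict(base_layers), "closed", sp)
            per["closed"], models[(sp, "closed")] = fit_and_predict(
                closed_stack, scene.plots, mask, ~open_mask,
                det.n_trees, det.corr_threshold, config.seed, det.select_variables)
            if "open" in per:
                per["merged"] = merge_strata(per["open"], per["closed"],
                                             cover_above, det.cover_break)
            else:
                per["merged"] = SpeciesMap(per["closed"].presence,
                                           per["closed"].p_presence,
                                           per["closed"].uncertainty, sp, "merged")
            maps[sp] = per
        return maps, models

    maps, models = _detect()

    @_stage("assessment")
    def _assess():
        out = {}
        radius = config.assessment.mmu_radius_m
        for sp in SPECIES:
            per = {}
            for stratum in ("open", "closed"):
                cm = assess_mod.mmu_evaluate(maps[sp]["merged"], scene.plots,
                                             radius, stratum=stratum)
                rep = assess_mod.metrics(cm)
                u = assess_mod.uncertainty_at_plots(maps[sp]["merged"], scene.plots,
                                                    radius, stratum=stratum)
                per[stratum] = {
                    "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
                    "overall_accuracy_pct": round(rep.overall_accuracy, 1),
                    "sensitivity_pct": round(rep.sensitivity, 1),
                    "specificity_pct": round(rep.specificity, 1),
                    "kappa": round(rep.kappa, 2),
                    "tss": round(rep.tss, 2),
                    "uncertainty_below_0p25": round(float(np.mean(u < 0.25)), 3)
                    if u.size else None,
                }
            out[sp] = per
        return out

    accuracy = _assess()

    @_stage("spatial")
    def _spatial():
        out = {}
        roads = landcover.like(
            (landcover.data.astype(int) == LANDCOVER_CODES["paved"]).astype(float))
        pervious = np.isin(landcover.data.astype(int), (1, 2, 3, 4))
        for sp in SPECIES:
            merged = maps[sp]["merged"]
            grid_ab = spatial_mod.abundance_grid(merged, config.spatial.cell_size_m)
            entry = {"total_presence_pixels": grid_ab.total,
                     "total_area_km2": round(grid_ab.total * 1e-6, 6)}
            try:
                lisa = spatial_mod.local_morans_i(
                    grid_ab, config.spatial.alpha,
                    config.spatial.permutations, config.seed)
                entry["pct_in_clusters"] = round(float(lisa.pct_in_clusters), 1)
                entry["pct_in_outliers"] = round(float(lisa.pct_in_outliers), 1)
            except ValueError as exc:
                entry["lisa_note"] = str(exc)
            profile = spatial_mod.distance_profile(
                merged, roads, config.spatial.distance_bin_m, pervious)
            entry["road_distance_invaded_km2"] = [
                round(float(v), 6) for v in profile["invaded_area_km2"]]
            comp = spatial_mod.composition_summary(merged, landcover)
            entry["area_by_class_km2"] = {
                k: round(v, 6) for k, v in comp["area_by_class_km2"].items()}
            out[sp] = entry
        return out

    spatial = _spatial()

    report = {
        "seed": config.seed,
        "scene": {
            "extent_m": list(scene_cfg.extent_m),
            "n_points": len(scene.cloud),
            "n_plots": len(scene.plots),
        },
        "digests": {
            "species_truth": _digest(scene.truth.species_map.data),
            "dem": _digest(scene.truth.dem.data),
            **{f"map_{sp}": _digest(
                np.nan_to_num(maps[sp]["merged"].presence.data.astype(float), nan=-1))
               for sp in SPECIES},
        },
        "variables": {
            f"{sp}_{stratum}": models[(sp, stratum)].variables
            for (sp, stratum) in sorted(models)
        },
        "accuracy": accuracy,
        "spatial": spatial,
    }

    result = PipelineResult(scene, structural, orographic, irr_result,
                            rule_images, maps, report)
    if output_dir is not None:
        _write_outputs(result, Path(output_dir), config)
    return result


def _write_outputs(result: PipelineResult, outdir: Path, config: PipelineConfig):
    from . import io as io_mod

    outdir.mkdir(parents=True, exist_ok=True)
    scene = result.scene
    io_mod.write_raster(outdir / "dem.tif", result.structural.dem)
    io_mod.write_raster(outdir / "dsm.tif", result.structural.dsm)
    for name, lyr in result.orographic.as_dict().items():
        io_mod.write_raster(outdir / f"{name}.tif", lyr)
    io_mod.write_raster(outdir / "direct_irradiance.tif",
                        result.irradiance.direct_mean_daily)
    io_mod.write_raster(outdir / "diffuse_irradiance.tif",
                        result.irradiance.diffuse_mean_daily)
    for name, lyr in result.rule_images.items():
        io_mod.write_raster(outdir / f"{name}.tif", lyr)
    for sp, per in result.maps.items():
        io_mod.write_raster(outdir / f"presence_{sp}.tif", per["merged"].presence)
        io_mod.write_raster(outdir / f"uncertainty_{sp}.tif", per["merged"].uncertainty)
    io_mod.write_plots_csv(outdir / "plots.csv", scene.plots)
    io_mod.write_point_cloud(outdir / "points.xyz", scene.cloud)
    (outdir / "report.json").write_text(result.report_json())
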