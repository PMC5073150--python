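"""Validated pipeline configuration (YAML round-trip, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .synthetic_scene import SceneConfig
from .irradiance import IrradianceConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SceneBlock(_Block):
    extent_m: tuple[float, float] = (300.0, 300.0)
    cell_size_m: float = 1.0
    point_density: float = 25.0
    band_count: int = 72
    band_start_nm: float = 363.0
    band_width_nm: float = 9.6
    species_prevalence: dict[str, float] = {"blackberry": 0.18, "ivy": 0.18}
    presence_plots_per_stratum: int = 30
    absence_plots_per_stratum: int = 64
    min_plot_separation_m: float = 10.0
    plot_patch_area_m2: float = 40.0
    gps_jitter_m: float = 3.0
    train_fraction: float = 646.0 / 1142.0
    noise_sd_pct: float = 0.6
    terrain_relief_m: float = 12.0
    road_spacing_m: float = 140.0

    def to_scene_config(self, seed: int) -> SceneConfig:
        return SceneConfig(seed=seed, **self.model_dump())


class DetectionBlock(_Block):
    n_trees: int = 2000
    corr_threshold: float = 0.7
    select_variables: bool = True
    use_spectral: bool = True
    cover_break: float = 0.20


class IrradianceBlock(_Block):
    latitude: float = 49.19
    longitude: float = -122.85
    utc_offset_hours: float = -8.0
    turbidity: float = 3.0
    clearness: float = 0.5
    resolution_factor: int = 3   # 1 m -> 3 m aggregation

    def to_irradiance_config(self) -> IrradianceConfig:
        return IrradianceConfig(
            latitude=self.latitude, longitude=self.longitude,
            utc_offset_hours=self.utc_offset_hours,
            turbidity=self.turbidity, clearness=self.clearness,
        )


class AssessmentBlock(_Block):
    mmu_radius_m: float = 3.0


class SpatialBlock(_Block):
    cell_size_m: float = 100.0
    alpha: float = 0.05
    permutations: int = 999
    distance_bin_m: float = 50.0


class PipelineConfig(_Block):
    seed: int = 0
    output_dir: str = "outputs"
    scene: SceneBlock = SceneBlock()
    detection: DetectionBlock = DetectionBlock()
    irradiance: IrradianceBlock = IrradianceBlock()
    assessment: AssessmentBlock = AssessmentBlock()
    spatial: SpatialBlock = SpatialBlock()


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
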