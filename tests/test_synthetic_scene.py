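import numpy as np
import pytest
from scipy import stats

from shrubmap.pointcloud import GROUND
from shrubmap.raster import RasterGrid
from shrubmap.spectral import spectral_angle
from shrubmap.synthetic_scene import (
    InvalidConfigError,
    LANDCOVER_CODES,
    PlotPlacementError,
    SPECIES_CODES,
    SceneConfig,
    SceneTruth,
    VEGETATED_CLASSES,
    draw_canopy_heights,
    endmember,
    generate_cube,
    generate_plots,
    generate_point_cloud,
    generate_terrain,
    generate_truth,
)
from .conftest import small_scene_config


class TestConfig:
    def test_rejects_nonpositive_extent(self):
        with pytest.raises(InvalidConfigError):
            SceneConfig(extent_m=(-10.0, 100.0))

    def test_rejects_extent_not_divisible_by_cell(self):
        with pytest.raises(InvalidConfigError):
            SceneConfig(extent_m=(100.5, 100.0), cell_size_m=1.0)

    def test_rejects_prevalence_outside_unit_interval(self):
        with pytest.raises(InvalidConfigError):
            SceneConfig(species_prevalence={"blackberry": 1.5})


class TestTerrain:
    def test_seeded_determinism(self):
        cfg = small_scene_config(seed=7)
        a = generate_terrain(cfg)
        b = generate_terrain(cfg)
        assert a.data.tobytes() == b.data.tobytes()

    def test_zero_relief_gives_constant_dem(self):
        dem = generate_terrain(small_scene_config(seed=1, terrain_relief_m=0.0))
        assert np.ptp(dem.data) == 0.0

    def test_shape_follows_extent_and_cell(self):
        dem = generate_terrain(SceneConfig(extent_m=(100.0, 100.0)))
        assert dem.shape == (100, 100)


class TestPointCloud:
    def test_flat_bare_truth_gives_all_ground_returns(self):
        cfg = SceneConfig(extent_m=(20.0, 20.0))
        grid = cfg.blank_grid()
        zeros = grid.like(np.zeros(cfg.shape))
        truth = SceneTruth(
            dem=grid.like(np.full(cfg.shape, 5.0)),
            cover_type=grid.like(np.full(cfg.shape, LANDCOVER_CODES["bare"])),
            species_map=grid.like(np.zeros(cfg.shape, dtype=int)),
            canopy_height=zeros, canopy_cover=zeros,
            understory_fraction=zeros, weibull_scale=zeros, weibull_shape=zeros,
        )
        cloud = generate_point_cloud(truth, cfg)
        assert np.all(cloud.classification == GROUND)
        assert np.allclose(cloud.z, 5.0)

    def test_weibull_draws_match_analytic_cdf(self):
        rng = np.random.default_rng(11)
        draws = draw_canopy_heights(10.0, 2.0, 100_000, rng)
        d, p = stats.kstest(draws, stats.weibull_min(2.0, scale=10.0).cdf)
        assert d < 0.01

    def test_return_density_matches_config(self, scene):
        area = scene.config.extent_m[0] * scene.config.extent_m[1]
        expected = scene.config.point_density * area
        assert abs(len(scene.cloud) - expected) < 5 * np.sqrt(expected)

    def test_missing_truth_layer_rejected(self, truth):
        cfg = small_scene_config(seed=2)
        broken = SceneTruth(**{**truth.__dict__, "weibull_scale": None})
        with pytest.raises(ValueError, match="weibull_scale"):
            generate_point_cloud(broken, cfg)


class TestCube:
    def test_noise_free_pure_pixel_equals_endmember(self, truth):
        cfg = small_scene_config(seed=2)
        cube = generate_cube(truth, config=cfg, noise_sd_pct=0.0)
        centers = cfg.bands.centers
        cover = truth.cover_type.data
        spmap = truth.species_map.data
        r, c = np.argwhere((cover == LANDCOVER_CODES["grass"]) & (spmap == 0))[0]
        assert np.allclose(cube[:, r, c], endmember("grass", centers), atol=1e-5)

    def test_species_pixel_is_mixture(self, truth):
        cfg = small_scene_config(seed=2)
        cube = generate_cube(truth, config=cfg, noise_sd_pct=0.0)
        centers = cfg.bands.centers
        spmap = truth.species_map.data
        cc = truth.canopy_cover.data
        cover = truth.cover_type.data
        sel = (spmap == SPECIES_CODES["blackberry"]) & (cc < 0.2) & (
            cover == LANDCOVER_CODES["grass"])
        r, c = np.argwhere(sel)[0]
        expected = 0.92 * endmember("blackberry", centers) + 0.08 * endmember(
            "grass", centers)
        assert np.allclose(cube[:, r, c], expected, atol=1e-5)

    def test_sam_self_angle_zero_on_pure_pixel(self, truth):
        cfg = small_scene_config(seed=2)
        cube = generate_cube(truth, config=cfg, noise_sd_pct=0.0)
        cover = truth.cover_type.data
        spmap = truth.species_map.data
        r, c = np.argwhere((cover == LANDCOVER_CODES["coniferous"]) & (spmap == 0))[0]
        em = endmember("coniferous", cfg.bands.centers)
        assert spectral_angle(cube[:, r, c], em) == pytest.approx(0.0, abs=1e-6)

    def test_values_clipped_to_reflectance_range(self, scene):
        assert scene.cube.min() >= 0.0 and scene.cube.max() <= 100.0


class TestSpeciesTruth:
    def test_species_only_on_vegetated_classes(self, truth):
        cover = truth.cover_type.data
        present = truth.species_map.data > 0
        assert np.isin(cover[present], VEGETATED_CLASSES).all()

    def test_blackberry_closed_sites_are_deciduous(self, truth):
        sp = truth.species_map.data
        cover = truth.cover_type.data
        bb_closed = (sp == SPECIES_CODES["blackberry"]) & (
            truth.canopy_cover.data > 0.2)
        decid_share = (cover[bb_closed] == LANDCOVER_CODES["deciduous"]).mean()
        assert decid_share > 0.9

    def test_blackberry_open_sites_are_sunnier_than_ivy(self, truth):
        sp = truth.species_map.data
        cc = truth.canopy_cover.data
        bb = sp == SPECIES_CODES["blackberry"]
        ivy = sp == SPECIES_CODES["ivy"]
        assert cc[bb].mean() < cc[ivy].mean()

    def test_ivy_favours_closed_coniferous(self, truth):
        sp = truth.species_map.data
        cover = truth.cover_type.data
        ivy_closed = (sp == SPECIES_CODES["ivy"]) & (truth.canopy_cover.data > 0.2)
        conif_share = (cover[ivy_closed] == LANDCOVER_CODES["coniferous"]).mean()
        assert conif_share > 0.9


class TestPlots:
    def test_pairwise_separation(self, truth):
        cfg = small_scene_config(seed=2)
        plots = generate_plots(truth, cfg)
        xy = np.array([(p.true_x, p.true_y) for p in plots])
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert np.sqrt(d2.min()) >= cfg.min_plot_separation_m - 1e-9

    def test_zero_jitter_records_true_coordinates(self, truth):
        cfg = small_scene_config(seed=2, gps_jitter_m=0.0)
        plots = generate_plots(truth, cfg)
        for p in plots:
            assert (p.x, p.y) == (p.true_x, p.true_y)

    def test_jitter_bounded_by_radius(self, truth):
        cfg = small_scene_config(seed=2)
        for p in generate_plots(truth, cfg):
            d = np.hypot(p.x - p.true_x, p.y - p.true_y)
            assert d <= cfg.gps_jitter_m + 1e-9

    def test_labels_agree_with_species_map_at_true_coords(self, truth):
        cfg = small_scene_config(seed=2)
        for p in generate_plots(truth, cfg):
            code = truth.species_map.value_at(p.true_x, p.true_y)
            assert int(code) == SPECIES_CODES[p.species]

    def test_train_fraction_reproduces_survey_split(self, truth):
        cfg = small_scene_config(seed=2)
        plots = generate_plots(truth, cfg)
        n_train = sum(p.role == "train" for p in plots)
        assert n_train / len(plots) == pytest.approx(646 / 1142, abs=0.02)

    def test_impossible_quota_raises_with_shortfall(self, truth):
        cfg = small_scene_config(seed=2, presence_plots_per_stratum=5000)
        with pytest.raises(PlotPlacementError, match="5000"):
            generate_plots(truth, cfg)


def test_whole_scene_is_seed_deterministic():
    from shrubmap.synthetic_scene import generate_scene

    cfg = small_scene_config(seed=9)
    a = generate_scene(cfg)
    b = generate_scene(cfg)
    assert a.truth.species_map.data.tobytes() == b.truth.species_map.data.tobytes()
    assert a.cube.tobytes() == b.cube.tobytes()
    assert np.array_equal(a.cloud.z, b.cloud.z)
    assert [(p.x, p.y, p.role) for p in a.plots] == [(p.x, p.y, p.role) for p in b.plots]
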