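"""Self-consistent synthetic urban study area for desk-scale runs.

The generator emulates the acquisition conditions of the mapped city:
~25 returns/m2 LiDAR over a mosaic of grass, deciduous and coniferous
forest, bare ground, roads, buildings and water; a 72-channel reflectance
cube (363-1051 nm, 9.6 nm channels, 1 m pixels) mixed from parametric
leaf-like endmember spectra; and presence/absence field plots in discrete
patches >= 40 m2 separated by >= 10 m with <= 3 m GPS jitter.

Species placement follows the two shrubs' ecology: Himalayan blackberry
favours open and deciduous areas with direct light; English ivy favours
shaded, coniferous sites. Presence pixels also carry a distinctive
understory return-height signature (a dense 1-2.5 m thicket for
blackberry, a ground-hugging mat for ivy) so that the closed-canopy
models, which see no spectral data, have a structural signal to learn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .pointcloud import GROUND, NON_GROUND, PointCloud
from .raster import RasterGrid
from .spectral import BandSet, SpectralLibrary, Spectrum
from .terrain import slope_aspect

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "PlotRecord",
    "Scene",
    "LANDCOVER_CODES",
    "SPECIES_CODES",
    "PERVIOUS_CLASSES",
    "VEGETATED_CLASSES",
    "leaf_spectrum",
    "build_spectral_library",
    "generate_terrain",
    "generate_truth",
    "generate_point_cloud",
    "generate_cube",
    "generate_plots",
    "generate_scene",
]

LANDCOVER_CODES = {
    "grass": 1,
    "deciduous": 2,
    "coniferous": 3,
    "bare": 4,
    "paved": 5,
    "building": 6,
    "water": 7,
}
LANDCOVER_NAMES = {v: k for k, v in LANDCOVER_CODES.items()}
PERVIOUS_CLASSES = (1, 2, 3, 4)
#: classes kept by the detection mask (dirt/paved/building/water are masked)
VEGETATED_CLASSES = (1, 2, 3)

SPECIES_CODES = {"none": 0, "blackberry": 1, "ivy": 2}
SPECIES_NAMES = {v: k for k, v in SPECIES_CODES.items()}


class InvalidConfigError(ValueError):
    pass


class PlotPlacementError(RuntimeError):
    pass


@dataclass
class SceneConfig:
    """Study-condition knobs for the synthetic scene."""

    extent_m: tuple[float, float] = (300.0, 300.0)
    cell_size_m: float = 1.0
    point_density: float = 25.0            # returns per m2
    band_count: int = 72
    band_start_nm: float = 363.0
    band_width_nm: float = 9.6
    species_prevalence: dict = field(
        default_factory=lambda: {"blackberry": 0.18, "ivy": 0.18}
    )
    #: presence plots per species per stratum / absence plots per stratum
    presence_plots_per_stratum: int = 30
    absence_plots_per_stratum: int = 64
    min_plot_separation_m: float = 10.0
    plot_patch_area_m2: float = 40.0
    gps_jitter_m: float = 3.0
    train_fraction: float = 646.0 / 1142.0   # the survey's 646/496 split
    noise_sd_pct: float = 0.6                # cube additive noise
    terrain_relief_m: float = 12.0
    terrain_correlation_m: float = 40.0
    road_spacing_m: float = 140.0
    road_width_m: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        w, hgt = self.extent_m
        if w <= 0 or hgt <= 0:
            raise InvalidConfigError("extent must be positive")
        if self.cell_size_m <= 0:
            raise InvalidConfigError("cell size must be positive")
        for dim in self.extent_m:
            if abs(dim / self.cell_size_m - round(dim / self.cell_size_m)) > 1e-9:
                raise InvalidConfigError("extent must be divisible by cell size")
        for sp, p in self.species_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"prevalence of {sp} outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.extent_m[1] / self.cell_size_m)),
            int(round(self.extent_m[0] / self.cell_size_m)),
        )

    @property
    def bands(self) -> BandSet:
        return BandSet(self.band_count, self.band_start_nm, self.band_width_nm)

    def blank_grid(self) -> RasterGrid:
        return RasterGrid(
            np.zeros(self.shape), (0.0, self.extent_m[1]), self.cell_size_m
        )

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class SceneTruth:
    """Ground truth layers, all on the 1 m grid."""

    dem: RasterGrid
    cover_type: RasterGrid        # LANDCOVER_CODES
    species_map: RasterGrid       # SPECIES_CODES
    canopy_height: RasterGrid     # m (building height on building pixels)
    canopy_cover: RasterGrid      # fraction of returns intercepted aloft
    understory_fraction: RasterGrid
    weibull_scale: RasterGrid
    weibull_shape: RasterGrid


@dataclass
class PlotRecord:
    """One field presence/absence observation."""

    x: float                  # recorded (jittered) coordinates
    y: float
    true_x: float
    true_y: float
    species: str              # blackberry | ivy | none
    presence: bool
    role: str                 # train | validate
    stratum: str              # open | closed


@dataclass
class Scene:
    config: SceneConfig
    truth: SceneTruth
    cloud: PointCloud
    cube: np.ndarray          # (bands, nrow, ncol) reflectance %
    bands: BandSet
    library: SpectralLibrary
    plots: list[PlotRecord]

    @property
    def grid(self) -> RasterGrid:
        return self.truth.dem


# --------------------------------------------------------------------------
# endmember spectra
# --------------------------------------------------------------------------
def leaf_spectrum(
    wavelength_nm: np.ndarray,
    green_peak: float,
    red_well: float,
    nir_plateau: float,
    red_edge_nm: float,
    red_edge_width: float,
) -> np.ndarray:
    """Five-parameter leaf-reflectance template (%).

    A visible region with a green peak near 550 nm over a chlorophyll
    absorption floor, a sigmoidal red edge, and a NIR plateau.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    vis = red_well + (green_peak - red_well) * np.exp(-((wl - 550.0) / 40.0) ** 2)
    s = 1.0 / (1.0 + np.exp(-(wl - red_edge_nm) / red_edge_width))
    return vis * (1.0 - s) + nir_plateau * s


#: per-class template parameters (green peak, red well, NIR, edge nm, edge width)
_LEAF_PARAMS = {
    "blackberry": (14.0, 5.0, 55.0, 705.0, 7.0),
    "ivy": (10.0, 2.5, 26.0, 716.0, 9.0),
    "grass": (17.0, 8.0, 42.0, 702.0, 7.0),
    "lamium": (12.0, 6.0, 45.0, 713.0, 10.0),
    "deciduous": (11.0, 4.2, 46.0, 714.0, 9.0),
    "coniferous": (6.5, 3.2, 28.0, 722.0, 13.0),
}


def _flat_spectrum(wl, level, tilt=0.0):
    return level + tilt * (wl - 700.0) / 350.0


def endmember(name: str, wavelength_nm: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelength_nm, dtype=float)
    if name in _LEAF_PARAMS:
        return leaf_spectrum(wl, *_LEAF_PARAMS[name])
    if name == "bare":
        return _flat_spectrum(wl, 18.0, 10.0)
    if name == "paved":
        return _flat_spectrum(wl, 17.0, 1.0)
    if name == "building":
        return _flat_spectrum(wl, 24.0, 2.0)
    if name == "water":
        return np.clip(_flat_spectrum(wl, 5.0, -4.0), 0.5, None)
    raise KeyError(f"no endmember for class {name!r}")


def build_spectral_library(
    config: SceneConfig,
    n_samples: int = 12,
    species: tuple[str, ...] = ("blackberry", "ivy", "grass", "lamium"),
) -> SpectralLibrary:
    """Field-spectrometer-like library: 1 nm samples with per-sample jitter."""
    rng = config.rng(90)
    wl = np.arange(350.0, 1060.0, 1.0)
    lib = SpectralLibrary()
    for sp in species:
        g, r, n, e, w = _LEAF_PARAMS[sp]
        for i in range(n_samples):
            jitter = rng.normal(0.0, [0.4, 0.15, 1.2, 1.5, 0.3])
            refl = leaf_spectrum(wl, g + jitter[0], r + jitter[1], n + jitter[2],
                                 e + jitter[3], w + jitter[4])
            refl = np.clip(refl + rng.normal(0.0, 0.25, wl.size), 0.0, 100.0)
            lib.add(Spectrum(wl, refl, species=sp, sample_id=f"{sp}_{i:02d}",
                             provenance="field"))
    return lib


# --------------------------------------------------------------------------
# terrain and land cover
# --------------------------------------------------------------------------
def _smooth_field(shape, correlation_cells, rng) -> np.ndarray:
    """Band-limited unit-variance random field (Gaussian-filtered noise)."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=correlation_cells, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_terrain(config: SceneConfig) -> RasterGrid:
    """Smooth random-field DEM; reproducible under the config seed."""
    rng = config.rng(1)
    grid = config.blank_grid()
    corr = config.terrain_correlation_m / config.cell_size_m
    f = _smooth_field(config.shape, corr, rng)
    nrow, ncol = config.shape
    regional = 0.01 * (np.arange(nrow)[:, None] * config.cell_size_m)
    dem = 50.0 + 0.5 * config.terrain_relief_m * f + regional * (
        config.terrain_relief_m > 0
    )
    return grid.like(dem)


def _generate_landcover(config: SceneConfig, rng) -> np.ndarray:
    shape = config.shape
    cell = config.cell_size_m
    u = _smooth_field(shape, 25.0 / cell, rng)
    v = _smooth_field(shape, 18.0 / cell, rng)
    cover = np.full(shape, LANDCOVER_CODES["grass"], dtype=np.int16)
    # quantile thresholds keep the class mix stable across seeds
    q25, q75 = np.quantile(u, [0.27, 0.73])
    cover[u > q75] = LANDCOVER_CODES["deciduous"]
    cover[u < q25] = LANDCOVER_CODES["coniferous"]
    cover[(np.abs(u) < 0.08) & (v > 1.1)] = LANDCOVER_CODES["bare"]
    cover[(v < -1.6)] = LANDCOVER_CODES["water"]

    # straight road corridors (configurable spacing/width) + flanking buildings
    nrow, ncol = shape
    half_w = max(1, int(round(config.road_width_m / (2 * cell))))
    spacing = max(2, int(round(config.road_spacing_m / cell)))
    for c0 in range(spacing // 2, ncol, spacing):
        cover[:, max(0, c0 - half_w):c0 + half_w] = LANDCOVER_CODES["paved"]
    for r0 in range(spacing // 2, nrow, spacing):
        cover[max(0, r0 - half_w):r0 + half_w, :] = LANDCOVER_CODES["paved"]
    n_buildings = max(1, int(nrow * ncol * cell**2 / 9000))
    for _ in range(n_buildings):
        br = int(rng.integers(0, nrow - 12))
        bc = int(rng.integers(0, ncol - 12))
        bh, bw = int(rng.integers(6, 12)), int(rng.integers(6, 12))
        cover[br:br + bh, bc:bc + bw] = LANDCOVER_CODES["building"]
    return cover


def generate_truth(config: SceneConfig) -> SceneTruth:
    """All ground-truth layers (terrain, cover, canopy, species placement)."""
    dem = generate_terrain(config)
    rng = config.rng(2)
    cover = _generate_landcover(config, rng)
    shape = config.shape
    cell = config.cell_size_m

    forest = (cover == LANDCOVER_CODES["deciduous"]) | (
        cover == LANDCOVER_CODES["coniferous"]
    )
    hfield = _smooth_field(shape, 15.0 / cell, rng)
    canopy_height = np.zeros(shape)
    canopy_height[forest] = np.clip(18.0 + 6.0 * hfield[forest], 6.0, 32.0)
    building = cover == LANDCOVER_CODES["building"]
    canopy_height[building] = rng.uniform(5.0, 10.0)

    cfield = _smooth_field(shape, 10.0 / cell, rng)
    canopy_cover = np.zeros(shape)
    canopy_cover[forest] = np.clip(0.8 + 0.15 * cfield[forest], 0.35, 0.97)
    # forest edges thin out to give an open/closed mix inside forest classes
    edge = ndimage.distance_transform_edt(forest) * cell
    canopy_cover[forest] *= np.clip(edge[forest] / 8.0, 0.12, 1.0)
    canopy_cover[building] = 0.95

    wshape = np.zeros(shape)
    wshape[forest] = np.clip(3.0 + 0.5 * _smooth_field(shape, 12.0 / cell, rng)[forest], 1.8, 4.5)

    species = _place_species(config, dem, cover, canopy_cover, rng)
    # established shrub patches need light: the overstory above them stays
    # below full closure, leaving room for a detectable understory stratum
    bb = species == SPECIES_CODES["blackberry"]
    ivy = species == SPECIES_CODES["ivy"]
    canopy_cover[bb] = np.minimum(canopy_cover[bb], 0.55)
    canopy_cover[ivy] = np.minimum(canopy_cover[ivy], 0.65)
    # invaded stands are younger/more open: shorter overstory above patches
    canopy_height[species > 0] = np.minimum(canopy_height[species > 0], 15.0)
    wscale = np.zeros(shape)
    wscale[forest] = 0.7 * canopy_height[forest]

    understory = np.zeros(shape)
    grass = cover == LANDCOVER_CODES["grass"]
    understory[grass] = 0.30
    understory[forest] = 0.15
    understory[species > 0] = 0.55
    understory[species == SPECIES_CODES["ivy"]] = 0.70

    grid = dem
    return SceneTruth(
        dem=dem,
        cover_type=grid.like(cover, nodata=0),
        species_map=grid.like(species, nodata=0),
        canopy_height=grid.like(canopy_height),
        canopy_cover=grid.like(canopy_cover),
        understory_fraction=grid.like(understory),
        weibull_scale=grid.like(wscale),
        weibull_shape=grid.like(wshape),
    )


def _place_species(config, dem, cover, canopy_cover, rng) -> np.ndarray:
    """Logistic-preference placement thresholded per stratum to hit prevalence."""
    shape = config.shape
    cell = config.cell_size_m
    _, northness = slope_aspect(dem)
    north = northness.data
    # species patches are planted clear of the 20% canopy-cover stratum
    # break so each patch belongs unambiguously to one stratum
    stratum_sites = {True: canopy_cover < 0.10, False: canopy_cover > 0.35}
    allowed = np.isin(cover, VEGETATED_CLASSES)
    deciduous = cover == LANDCOVER_CODES["deciduous"]
    coniferous = cover == LANDCOVER_CODES["coniferous"]

    scores = {
        # blackberry: open, deciduous, sunlit (south-facing) sites
        "blackberry": (
            1.2 * (1.0 - canopy_cover) + 2.2 * deciduous - 0.4 * north
            + 1.2 * _smooth_field(shape, 12.0 / cell, rng)
        ),
        # ivy: shaded, coniferous, north-facing sites
        "ivy": (
            1.2 * canopy_cover + 2.2 * coniferous + 0.4 * north
            + 1.2 * _smooth_field(shape, 12.0 / cell, rng)
        ),
    }
    #: share of each species' prevalence allocated to the open stratum
    open_share = {"blackberry": 0.5, "ivy": 0.5}
    # under closed canopy each shrub keeps to its preferred forest type
    # (blackberry: deciduous; ivy: coniferous), the strong-signal regime
    closed_type = {"blackberry": deciduous, "ivy": coniferous}

    species = np.zeros(shape, dtype=np.int16)
    margin = np.full(shape, -np.inf)
    for name, score in scores.items():
        p = config.species_prevalence.get(name, 0.0)
        if p <= 0:
            continue
        target = {True: open_share[name], False: 1 - open_share[name]}
        for is_open, share in target.items():
            stratum = allowed & stratum_sites[is_open]
            if not is_open:
                stratum = stratum & closed_type[name]
            n_stratum = int(stratum.sum())
            if n_stratum == 0:
                continue
            k = int(round(p * share * allowed.sum()))
            k = min(k, n_stratum)
            if k == 0:
                continue
            vals = score[stratum]
            thresh = np.partition(vals, n_stratum - k)[n_stratum - k]
            sel = stratum & (score >= thresh)
            rel = score - thresh
            take = sel & (rel > margin)
            species[take] = SPECIES_CODES[name]
            margin[take] = rel[take]
    return species


# --------------------------------------------------------------------------
# point cloud
# --------------------------------------------------------------------------
def draw_canopy_heights(scale, shape_param, n, rng) -> np.ndarray:
    """Weibull(scale, shape) return heights (used by the cloud generator)."""
    return scale * rng.weibull(shape_param, size=n)


#: per-species understory height samplers (the structural signature)
def _understory_heights(species_code, n, rng):
    if species_code == SPECIES_CODES["blackberry"]:
        h = 0.1 + 1.4 * rng.weibull(3.0, n)
        return np.clip(h, 0.15, 2.4)
    if species_code == SPECIES_CODES["ivy"]:
        return rng.uniform(0.18, 0.55, n)
    return rng.uniform(0.15, 2.4, n)


def generate_point_cloud(truth: SceneTruth, config: SceneConfig) -> PointCloud:
    """Poisson-count returns per pixel: ground, understory, and canopy strata.

    Canopy return heights follow the pixel's Weibull(scale, shape)
    truncated at the canopy height; building pixels return the roof plane;
    understory heights follow the species signature. Ground returns lie on
    the DEM and carry the ground class.
    """
    for name in ("dem", "cover_type", "canopy_height", "canopy_cover",
                 "understory_fraction", "weibull_scale", "weibull_shape"):
        if getattr(truth, name, None) is None:
            raise ValueError(f"missing truth layer {name}")
    rng = config.rng(3)
    grid = truth.dem
    nrow, ncol = grid.shape
    cell = config.cell_size_m
    counts = rng.poisson(config.point_density * cell * cell, nrow * ncol)
    total = int(counts.sum())
    pid = np.repeat(np.arange(nrow * ncol), counts)
    rows, cols = pid // ncol, pid % ncol

    x = grid.origin[0] + (cols + rng.random(total)) * cell
    y = grid.origin[1] - (rows + rng.random(total)) * cell

    cover = truth.cover_type.data.ravel()[pid]
    ch = truth.canopy_height.data.ravel()[pid]
    cc = truth.canopy_cover.data.ravel()[pid]
    uf = truth.understory_fraction.data.ravel()[pid]
    wsc = truth.weibull_scale.data.ravel()[pid]
    wsh = truth.weibull_shape.data.ravel()[pid]
    spc = truth.species_map.data.ravel()[pid]

    u = rng.random(total)
    in_canopy = u < cc
    in_under = (~in_canopy) & (u < cc + uf) & (ch >= 0)

    h = np.zeros(total)
    canopy_veg = in_canopy & (cover != LANDCOVER_CODES["building"]) & (wsc > 0)
    if np.any(canopy_veg):
        draws = draw_canopy_heights(wsc[canopy_veg], np.maximum(wsh[canopy_veg], 0.1),
                                    int(canopy_veg.sum()), rng)
        h[canopy_veg] = np.minimum(draws, ch[canopy_veg])
    roof = in_canopy & (cover == LANDCOVER_CODES["building"])
    h[roof] = ch[roof]
    for code in np.unique(spc[in_under]):
        m = in_under & (spc == code)
        h[m] = _understory_heights(int(code), int(m.sum()), rng)
    # grass understory is a short sward rather than a shrub layer
    grass_under = in_under & (spc == 0) & (cover == LANDCOVER_CODES["grass"])
    h[grass_under] = rng.uniform(0.15, 0.8, int(grass_under.sum()))
    h[in_under] = np.minimum(h[in_under], np.maximum(ch[in_under], 2.5))

    z = truth.dem.sample_bilinear(x, y) + h
    classification = np.where(h > 0, NON_GROUND, GROUND).astype(np.int8)
    return PointCloud(x, y, z, classification)


# --------------------------------------------------------------------------
# reflectance cube
# --------------------------------------------------------------------------
def generate_cube(
    truth: SceneTruth,
    library_or_bands: BandSet | None = None,
    config: SceneConfig | None = None,
    noise_sd_pct: float | None = None,
) -> np.ndarray:
    """Area-weighted endmember mixture cube (reflectance %, clipped to [0, 100]).

    Each pixel mixes its cover class endmember with its species endmember;
    the species fraction is high in the open (the sensor sees the shrub)
    and low under canopy (the sensor sees the overstory). Zero-mean
    Gaussian noise with configurable sd is added per band.
    """
    if config is None:
        raise ValueError("config required")
    bands = config.bands
    noise_sd = config.noise_sd_pct if noise_sd_pct is None else noise_sd_pct
    rng = config.rng(4)
    centers = bands.centers
    ems = {}
    for name, code in LANDCOVER_CODES.items():
        ems[code] = endmember(name, centers)
    sp_em = {
        SPECIES_CODES["blackberry"]: endmember("blackberry", centers),
        SPECIES_CODES["ivy"]: endmember("ivy", centers),
    }
    cover = truth.cover_type.data.astype(int)
    unknown = set(np.unique(cover)) - set(ems)
    if unknown:
        raise KeyError(f"cover classes without endmembers: {sorted(unknown)}")
    nrow, ncol = cover.shape
    base = np.zeros((bands.n_bands, nrow, ncol))
    for code, spec in ems.items():
        m = cover == code
        if m.any():
            base[:, m] = spec[:, None]
    spmap = truth.species_map.data.astype(int)
    cc = truth.canopy_cover.data
    for code, spec in sp_em.items():
        m = spmap == code
        if m.any():
            frac = np.where(cc[m] < 0.2, 0.92, 0.10)
            base[:, m] = frac * spec[:, None] + (1 - frac) * base[:, m]
    if noise_sd > 0:
        base = base + rng.normal(0.0, noise_sd, base.shape)
    return np.clip(base, 0.0, 100.0).astype(np.float32)


# --------------------------------------------------------------------------
# field plots
# --------------------------------------------------------------------------
def _select_separated(candidates_rc, quota, accepted_xy, min_sep, grid, rng):
    """Greedy random selection of pixel centers >= min_sep from all accepted."""
    out = []
    if len(candidates_rc) == 0 and quota > 0:
        return out
    idx = rng.permutation(len(candidates_rc))
    cell = grid.cell_size
    x0, y0 = grid.origin
    sep2 = min_sep * min_sep
    for i in idx:
        if len(out) >= quota:
            break
        r, c = candidates_rc[i]
        x = x0 + (c + 0.5) * cell
        y = y0 - (r + 0.5) * cell
        ok = True
        for (ax, ay) in accepted_xy:
            if (ax - x) ** 2 + (ay - y) ** 2 < sep2:
                ok = False
                break
        if ok:
            accepted_xy.append((x, y))
            out.append((x, y))
    return out


def generate_plots(truth: SceneTruth, config: SceneConfig) -> list[PlotRecord]:
    """Presence plots inside homogeneous patches, absence plots well away.

    Presence plot centers fall in connected same-species patches of at
    least ``plot_patch_area_m2`` (eroded so the jittered point stays in
    the patch); absence centers keep >= 5 m from any species pixel. All
    plots are pairwise separated by ``min_plot_separation_m``. Recorded
    coordinates add a uniform-disc GPS jitter; roles are randomly assigned
    train/validate; the stratum comes from the canopy-cover layer.
    """
    rng = config.rng(5)
    grid = truth.dem
    cell = config.cell_size_m
    spmap = truth.species_map.data.astype(int)
    cc = truth.canopy_cover.data
    # plot sites sit clearly inside one stratum so that the finite-sample
    # LiDAR cover estimate (sd ~ 0.08 at 25 returns) rarely flips them
    # across the 20% canopy-cover break
    stratum_cand = {True: cc < 0.10, False: cc > 0.35}
    any_species = spmap > 0
    # absence sites must stay clear of species pixels even after GPS
    # jitter (<=3 m) plus the 3 m validation disc around the recorded point
    clearance = config.gps_jitter_m + 3.0 + 2.0
    far_from_species = (
        ndimage.distance_transform_edt(~any_species) * cell >= clearance
    )
    pervious = np.isin(truth.cover_type.data, VEGETATED_CLASSES)

    min_pix = int(np.ceil(config.plot_patch_area_m2 / cell**2))
    accepted_xy: list[tuple[float, float]] = []
    plots: list[PlotRecord] = []

    def quota_error(what, got, want):
        raise PlotPlacementError(
            f"could not place {want} {what} plots with "
            f"{config.min_plot_separation_m} m separation; only {got} fitted"
        )

    for name in ("blackberry", "ivy"):
        code = SPECIES_CODES[name]
        mask = spmap == code
        labels, n = ndimage.label(mask)
        if n:
            sizes = np.bincount(labels.ravel())
            big = np.isin(labels, np.flatnonzero(sizes >= min_pix)) & mask
        else:
            big = np.zeros_like(mask)
        # keep plot centers at least one jitter radius inside the patch so
        # the recorded coordinate still samples the species
        margin = max(1, int(math.ceil(config.gps_jitter_m / cell)))
        core = ndimage.binary_erosion(big, iterations=margin) if big.any() else big
        if not core.any():
            core = big
        for is_open, label in ((True, "open"), (False, "closed")):
            cand = np.argwhere(core & stratum_cand[is_open])
            picked = _select_separated(
                cand, config.presence_plots_per_stratum, accepted_xy,
                config.min_plot_separation_m, grid, rng,
            )
            if len(picked) < config.presence_plots_per_stratum:
                quota_error(f"{name} {label} presence", len(picked),
                            config.presence_plots_per_stratum)
            plots.extend(_make_records(picked, name, True, label, config, rng))

    for is_open, label in ((True, "open"), (False, "closed")):
        cand = np.argwhere(pervious & far_from_species & stratum_cand[is_open])
        picked = _select_separated(
            cand, config.absence_plots_per_stratum, accepted_xy,
            config.min_plot_separation_m, grid, rng,
        )
        if len(picked) < config.absence_plots_per_stratum:
            quota_error(f"absence {label}", len(picked),
                        config.absence_plots_per_stratum)
        plots.extend(_make_records(picked, "none", False, label, config, rng))
    return plots


def _make_records(picked, species, presence, stratum, config, rng) -> list[PlotRecord]:
    """Jitter coordinates and assign train/validate roles (stratified split)."""
    n = len(picked)
    n_train = int(round(config.train_fraction * n))
    roles = np.array(["train"] * n_train + ["validate"] * (n - n_train))
    rng.shuffle(roles)
    out = []
    for (x, y), role in zip(picked, roles):
        r = config.gps_jitter_m * math.sqrt(rng.random())
        theta = 2 * math.pi * rng.random()
        jx = np.clip(x + r * math.cos(theta), 1e-6, config.extent_m[0] - 1e-6)
        jy = np.clip(y + r * math.sin(theta), 1e-6, config.extent_m[1] - 1e-6)
        out.append(PlotRecord(float(jx), float(jy), float(x), float(y),
                              species, presence, str(role), stratum))
    return out


def generate_scene(config: SceneConfig | None = None) -> Scene:
    """End-to-end synthetic scene under a single seed."""
    config = config or SceneConfig()
    truth = generate_truth(config)
    cloud = generate_point_cloud(truth, config)
    cube = generate_cube(truth, config=config)
    library = build_spectral_library(config)
    plots = generate_plots(truth, config)
    return Scene(config, truth, cloud, cube, config.bands, library, plots)
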