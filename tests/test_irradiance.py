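import datetime as dt
import math

import numpy as np
import pytest

from shrubmap.irradiance import (
    CanopyProfileGrid,
    svf_from_horizon,
    IrradianceConfig,
    SolarPosition,
    atmospheric_direct,
    beam_transmittance,
    compute_irradiance,
    diffuse_horizontal,
    fit_canopy_profile,
    horizon_and_svf,
    solar_position,
)
from shrubmap.raster import RasterGrid


def almanac_sun(lat, lon, when_utc):
    """Independent ephemeris oracle: Astronomical Almanac low-precision algorithm."""
    n = (
        (when_utc - dt.datetime(2000, 1, 1, 12)).total_seconds() / 86400.0
    )
    L = (280.460 + 0.9856474 * n) % 360.0
    g = math.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = math.radians(L + 1.915 * math.sin(g) + 0.020 * math.sin(2 * g))
    eps = math.radians(23.439 - 0.0000004 * n)
    ra = math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam))
    dec = math.asin(math.sin(eps) * math.sin(lam))
    gmst = (18.697374558 + 24.06570982441908 * n) % 24
    lst = (gmst + lon / 15.0) % 24
    ha = math.radians((lst * 15.0 - math.degrees(ra)) % 360.0)
    latr = math.radians(lat)
    el = math.asin(
        math.sin(latr) * math.sin(dec) + math.cos(latr) * math.cos(dec) * math.cos(ha)
    )
    az = math.atan2(
        -math.sin(ha), math.cos(latr) * math.tan(dec) - math.sin(latr) * math.cos(ha)
    )
    return math.degrees(el), math.degrees(az) % 360.0


class TestSolarPosition:
    @pytest.mark.parametrize("when", [
        dt.datetime(2013, 6, 15, 12), dt.datetime(2013, 3, 15, 9),
        dt.datetime(2013, 10, 15, 16), dt.datetime(2013, 8, 15, 7),
    ])
    def test_matches_independent_ephemeris(self, when):
        lat, lon = 49.19, -122.85
        sun = solar_position(lat, lon, when, utc_offset_hours=-8)
        el, az = almanac_sun(lat, lon, when + dt.timedelta(hours=8))
        assert sun.elevation == pytest.approx(el, abs=0.1)
        assert abs((sun.azimuth - az + 180) % 360 - 180) < 0.15

    def test_midnight_sun_below_horizon_at_49N(self):
        sun = solar_position(49.0, -122.85, dt.datetime(2013, 6, 15, 0), -8)
        assert sun.elevation < 0

    def test_equinox_noon_elevation_is_colatitude(self):
        lat = 49.0
        sun = solar_position(lat, 0.0, dt.datetime(2013, 3, 20, 12), 0.0)
        assert sun.elevation == pytest.approx(90.0 - lat, abs=0.5)

    def test_aware_timestamp_rejected(self):
        with pytest.raises(ValueError):
            solar_position(49.0, 0.0,
                           dt.datetime(2013, 6, 1, tzinfo=dt.timezone.utc))


def _sun(el, az=180.0, doy=166):
    return SolarPosition(el, az, dt.datetime(2013, 6, 15, 12), doy)


class TestAtmosphere:
    def test_sun_below_horizon_gives_zero(self):
        assert atmospheric_direct(_sun(-5.0)) == 0.0

    def test_zero_clearness_gives_zero(self):
        assert atmospheric_direct(_sun(40.0), clearness=0.0) == 0.0

    def test_clearness_is_linear(self):
        b1 = atmospheric_direct(_sun(40.0), clearness=0.25)
        b2 = atmospheric_direct(_sun(40.0), clearness=0.5)
        assert b2 == pytest.approx(2 * b1)

    def test_beam_monotone_decreasing_in_turbidity(self):
        vals = [atmospheric_direct(_sun(35.0), turbidity=t) for t in
                np.linspace(1.0, 8.0, 15)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_nonpositive_turbidity_rejected(self):
        with pytest.raises(ValueError):
            beam_transmittance(40.0, 0.0)

    def test_diffuse_linear_in_svf_through_map(self):
        d1 = diffuse_horizontal(_sun(40.0))
        assert d1 > 0
        assert diffuse_horizontal(_sun(-3.0)) == 0.0


class TestHorizonSvf:
    def test_flat_plane_has_open_sky(self):
        dem = RasterGrid(np.zeros((20, 20)), (0.0, 20.0), 1.0)
        sky = horizon_and_svf(dem, dem, radius=8.0)
        assert np.all(sky.horizon_deg == 0.0)
        assert np.allclose(sky.svf.data, 1.0)

    def test_wall_at_10m_gives_45_degree_sector(self):
        dem = RasterGrid(np.zeros((25, 25)), (0.0, 25.0), 1.0)
        dsm_data = np.zeros((25, 25))
        dsm_data[2, :] = 12.5  # wall 10 m north of the receptor row
        dsm = dem.like(dsm_data)
        sky = horizon_and_svf(dsm, dem, radius=15.0, eye_height=2.5)
        # sector 0 looks due north; wall top is 10 m above the eye at 10 m
        assert sky.horizon_deg[0, 12, 12] == pytest.approx(45.0, abs=0.5)

    def test_uniform_60_degree_horizon_gives_svf_quarter(self):
        horizon = np.full((36, 1, 1), 60.0)
        assert svf_from_horizon(horizon)[0, 0] == pytest.approx(0.25)

    def test_enclosed_pit_approximates_quarter_svf(self):
        n = 31
        dem = RasterGrid(np.zeros((n, n)), (0.0, n), 1.0)
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - n // 2, yy - n // 2)
        dsm = dem.like(np.where(r >= 4, 4.0 * math.tan(math.radians(60.0)), 0.0))
        sky = horizon_and_svf(dsm, dem, radius=10.0, eye_height=0.0)
        c = n // 2
        # ray sampling on the integer grid slightly under-resolves a thin
        # circular rim in a few sectors; the sector formula itself is exact
        assert sky.svf.data[c, c] == pytest.approx(0.25, abs=0.03)


class TestCanopyProfile:
    def test_weibull_parameter_recovery_within_5pct(self):
        rng = np.random.default_rng(3)
        heights = 10.0 * rng.weibull(2.0, 10_000)
        prof = fit_canopy_profile(heights, extinction_height=2.5)
        assert prof.weibull_scale == pytest.approx(10.0, rel=0.05)
        assert prof.weibull_shape == pytest.approx(2.0, rel=0.05)

    def test_all_returns_below_extinction_height(self):
        rng = np.random.default_rng(4)
        heights = rng.uniform(0.2, 2.0, 200)
        prof = fit_canopy_profile(heights, extinction_height=2.5)
        assert prof.extinction_coefficient == 0.0

    def test_too_few_returns_marks_nonvegetated(self):
        prof = fit_canopy_profile(np.array([0.0, 0.0, 5.0]))
        assert not prof.vegetated


def closed_form_daily(cfg, component):
    """Pointwise oracle for a flat, unobstructed, treeless pixel."""
    months = []
    for month in cfg.months:
        hourly = []
        for hour in cfg.hours:
            sun = solar_position(
                cfg.latitude, cfg.longitude,
                dt.datetime(cfg.year, month, cfg.day_of_month, hour),
                cfg.utc_offset_hours)
            if sun.elevation <= 0:
                hourly.append(0.0)
            elif component == "direct":
                hourly.append(
                    atmospheric_direct(sun, cfg.turbidity, cfg.clearness)
                    * math.sin(math.radians(sun.elevation)))
            else:
                hourly.append(diffuse_horizontal(sun, cfg.turbidity, cfg.clearness))
        months.append(np.trapezoid(hourly, dx=3600.0) / 1e6)
    return float(np.mean(months))


class TestIrradianceMaps:
    @pytest.fixture(scope="class")
    def flat_result(self):
        dem = RasterGrid(np.zeros((12, 12)), (0.0, 36.0), 3.0)
        cfg = IrradianceConfig()
        return compute_irradiance(dem, dem, None, cfg), cfg

    def test_flat_scene_direct_equals_closed_form(self, flat_result):
        result, cfg = flat_result
        oracle = closed_form_daily(cfg, "direct")
        assert np.allclose(result.direct_mean_daily.data, oracle, rtol=1e-3)

    def test_flat_scene_diffuse_equals_closed_form(self, flat_result):
        result, cfg = flat_result
        oracle = closed_form_daily(cfg, "diffuse")
        assert np.allclose(result.diffuse_mean_daily.data, oracle, rtol=1e-3)

    def test_seasonal_mean_conserves_monthly_totals(self, flat_result):
        result, _ = flat_result
        assert np.allclose(
            result.direct_mean_daily.data, result.monthly_direct.mean(axis=0))

    def test_building_shadow_reduces_direct(self):
        dem = RasterGrid(np.zeros((12, 12)), (0.0, 36.0), 3.0)
        dsm_data = np.zeros((12, 12))
        dsm_data[8, :] = 30.0  # tall east-west wall; pixels north of it shaded
        result = compute_irradiance(dem, dem.like(dsm_data), None,
                                    IrradianceConfig())
        shaded = result.direct_mean_daily.data[7, 6]   # just north of the wall
        open_px = result.direct_mean_daily.data[1, 6]
        assert shaded < open_px

    def test_opaque_canopy_kills_direct(self):
        dem = RasterGrid(np.zeros((6, 6)), (0.0, 18.0), 3.0)
        shape = dem.shape
        profiles = CanopyProfileGrid(
            scale=np.full(shape, 80.0), shape=np.full(shape, 2.0),
            extinction=np.ones(shape), vegetated=np.ones(shape, bool), grid=dem)
        cfg = IrradianceConfig()
        result = compute_irradiance(dem, dem, profiles, cfg)
        open_total = closed_form_daily(cfg, "direct")
        assert np.all(result.direct_mean_daily.data < 0.01 * open_total)
        assert (result.diffuse_mean_daily.data > 0).all()
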