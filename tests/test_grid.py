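import numpy as np
import pytest
import xarray as xr

from photophen import (PhenologyGrid, PipelineConfig, build_mask, grid_trend,
                       group_igbp, make_grid, pixel_trend, run_grid)
from photophen.synthetic import COMPOSITE_DOYS, SINGLE_SEASON, curve

from _oracles import ols_slope


def _cube_from_pixels(values_by_pixel, lats, lons, year=2001):
    """(n_lat, n_lon) dict/array of 46-vectors → gpp cube."""
    times = (np.datetime64(f"{year}-01-01")
             + np.timedelta64(1, "D") * (COMPOSITE_DOYS - 1))
    gpp = np.empty((46, len(lats), len(lons)))
    for i in range(len(lats)):
        for j in range(len(lons)):
            gpp[:, i, j] = values_by_pixel[i][j]
    return xr.Dataset(
        {"gpp": (("time", "lat", "lon"), gpp, {"units": "g C m-2 day-1"})},
        coords={"time": times, "lat": lats, "lon": lons})


class TestIgbpGrouping:
    def test_broad_class_mapping(self):
        codes = xr.DataArray(np.array([[4, 7], [10, 16]]),
                             coords={"lat": [40.0, 40.05],
                                     "lon": [0.0, 0.05]})
        biome = group_igbp(codes)
        assert biome.values.tolist() == [["forests", "shrublands"],
                                         ["grasslands", "other"]]

    def test_mapping_total_over_all_codes(self):
        for code in range(0, 20):
            da = xr.DataArray(np.array([[code]]),
                              coords={"lat": [40.0], "lon": [0.0]})
            assert group_igbp(da).values[0, 0] in {
                "forests", "shrublands", "savannas", "grasslands",
                "wetlands", "croplands", "other"}


class TestMaskRules:
    def _criterion_cube(self):
        lats = np.array([29.9, 30.1])
        lons = np.array([10.0, 10.05, 10.1])
        base = curve(COMPOSITE_DOYS, SINGLE_SEASON)
        pixels = {}
        for i in range(2):
            pixels[i] = {}
            for j, peak in enumerate((1.9, 2.0, 2.1)):
                pixels[i][j] = base / base.max() * peak
        return _cube_from_pixels(pixels, lats, lons)

    def test_gpp_floor_and_latitude_rules(self):
        cube = self._criterion_cube()
        mask = build_mask(cube, latitude_min=30.0, gpp_floor=2.0)
        keep = mask["keep"].values
        # row at 29.9°N entirely dropped for latitude; at 30.1°N only the
        # record-max-1.9 pixel dropped, for low GPP
        assert keep.tolist() == [[False, False, False], [False, True, True]]
        assert mask["latitude"].values[0].all()
        assert not mask["latitude"].values[1].any()
        assert mask["low_gpp"].values[1].tolist() == [True, False, False]

    def test_all_missing_pixel_dropped(self):
        cube = self._criterion_cube()
        cube["gpp"][:, 1, 2] = np.nan
        mask = build_mask(cube, latitude_min=30.0, gpp_floor=2.0)
        assert not bool(mask["keep"].values[1, 2])

    def test_landcover_rule(self):
        cube = self._criterion_cube()
        igbp = xr.DataArray(np.array([[10, 10, 10], [10, 10, 16]]),
                            coords={"lat": cube["lat"], "lon": cube["lon"]})
        mask = build_mask(cube, igbp=igbp, latitude_min=30.0, gpp_floor=2.0)
        assert not bool(mask["keep"].values[1, 2])
        assert bool(mask["landcover"].values[1, 2])

    def test_missing_units_warns_but_proceeds(self):
        cube = self._criterion_cube()
        del cube["gpp"].attrs["units"]
        with pytest.warns(UserWarning):
            build_mask(cube)


class TestRunGrid:
    def test_uniform_clean_cube_gives_identical_pixels(self):
        cube, _ = make_grid(3, 3, "uniform-single", seed=0, noise_sd=0.0)
        cfg = PipelineConfig(bootstrap_n=0)
        grid, _ = run_grid(cube, cfg)
        ds = grid.datasets[(2001, 1)]
        assert (ds["season_count"].values == 1).all()
        sos = ds["SOS_25"].values
        assert np.isfinite(sos).all()
        assert np.ptp(sos) == pytest.approx(0.0, abs=1e-9)

    def test_double_season_pixel_detected_exactly_where_planted(self):
        cube, truth = make_grid(3, 3, "mixed-single-double", seed=1,
                                noise_sd=0.0)
        grid, _ = run_grid(cube, PipelineConfig(bootstrap_n=0))
        ds = grid.datasets[(2001, 1)]
        np.testing.assert_array_equal(ds["season_count"].values,
                                      truth["season_count"])
        s2 = grid.datasets[(2001, 2)]["SOS_25"].values
        assert (np.isfinite(s2) == (truth["season_count"] == 2)).all()

    def test_masked_pixels_fill_valued_everywhere(self):
        cube, truth = make_grid(4, 4, "masked-patches", seed=2, noise_sd=0.0)
        grid, _ = run_grid(cube, PipelineConfig(bootstrap_n=0))
        ds = grid.datasets[(2001, 1)]
        for name, da in ds.data_vars.items():
            if name in ("season_count", "qa"):
                continue
            assert np.isnan(da.values[truth["masked"]]).all()
        assert (ds["qa"].values[truth["masked"]] == 1).all()

    def test_netcdf_roundtrip(self, tmp_path):
        cube, truth = make_grid(3, 3, "uniform-single", seed=3, noise_sd=0.3)
        cfg = PipelineConfig(bootstrap_n=10, min_bootstrap_successes=5)
        grid, _ = run_grid(cube, cfg, igbp=truth["igbp"], out_dir=tmp_path)
        assert (tmp_path / "2001_SOS.nc").exists()
        back = PhenologyGrid.read(tmp_path, [2001])
        a, b = grid.datasets[(2001, 1)], back.datasets[(2001, 1)]
        for name in a.data_vars:
            np.testing.assert_allclose(a[name].values, b[name].values,
                                       equal_nan=True)
        np.testing.assert_array_equal(a["lat"].values, b["lat"].values)


class TestTrends:
    def test_exact_line_recovered(self):
        years = np.arange(2001, 2021)
        slope, intercept, p = pixel_trend(years, 100 + 0.5 * (years - 2001),
                                          min_years=10)
        assert slope == pytest.approx(0.5, abs=1e-12)
        assert p < 1e-10

    def test_constant_series_has_zero_slope(self):
        years = np.arange(2001, 2021)
        slope, _, _ = pixel_trend(years, np.full(20, 130.0))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_years_is_missing(self):
        years = np.arange(2001, 2006)
        assert np.isnan(pixel_trend(years, years * 0.1)[0])

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_normal_equations_oracle(self, trial):
        rng = np.random.default_rng(trial)
        years = np.arange(2001, 2021)
        vals = rng.normal(120, 10, 20)
        slope, _, _ = pixel_trend(years, vals)
        assert slope == pytest.approx(ols_slope(years, vals), rel=1e-10)

    def test_grid_trend_on_shifting_seasons(self):
        cube, truth = make_grid(2, 2, "trend", seed=5, noise_sd=0.0,
                                years=tuple(range(2001, 2021)),
                                trend_slope=-0.3)
        grid, _ = run_grid(cube, PipelineConfig(bootstrap_n=0))
        slopes = grid_trend(grid, "SOS_25")["slope"].values
        assert np.abs(slopes + 0.3).max() < 0.1
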