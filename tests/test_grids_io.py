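"""netCDF round-trips, depth-orientation normalisation, measures, CSV tables."""

import numpy as np
import pytest
import xarray as xr

from biopump.diagnostics import BCPTimeSeries, compute_csoft
from biopump.grids import Field, GridError, OceanGrid
from biopump.io import (
    LoadError,
    read_cell_measures,
    read_cmip_variable,
    write_cmip_variable,
    write_timeseries_table,
)

from conftest import make_box_grid


def _demo_field(with_time=True):
    rng = np.random.default_rng(0)
    dims = ("time", "lev", "lat", "lon") if with_time else ("lev", "lat", "lon")
    shape = (3, 4, 2, 3) if with_time else (4, 2, 3)
    coords = {
        "lev": ("lev", [50.0, 150.0, 600.0, 1500.0], {"units": "m", "positive": "down"}),
        "lat": ("lat", [-45.0, 45.0]),
        "lon": ("lon", [0.0, 120.0, 240.0]),
    }
    vals = rng.normal(size=shape)
    vals[..., 0, 0] = np.nan  # one masked column
    da = xr.DataArray(vals, dims=dims, coords=coords, name="expc")
    if with_time:
        import cftime

        da = da.assign_coords(
            time=[cftime.datetime(2000, m + 1, 16, calendar="360_day") for m in range(3)]
        )
    return Field("expc", da, "mol m-2 s-1")


class TestVariableRoundTrip:
    def test_values_mask_units_preserved(self, tmp_path):
        f = _demo_field()
        path = tmp_path / "expc.nc"
        write_cmip_variable(f, path)
        back = read_cmip_variable(path, "expc")
        np.testing.assert_array_equal(back.values, f.values)
        assert back.units == f.units
        np.testing.assert_array_equal(back.data["lev"].values, f.data["lev"].values)

    def test_positive_up_depth_normalised(self, tmp_path):
        f = _demo_field(with_time=False)
        flipped = xr.DataArray(
            f.values[::-1],
            dims=("lev", "lat", "lon"),
            coords={
                "lev": ("lev", [-1500.0, -600.0, -150.0, -50.0], {"units": "m", "positive": "up"}),
                "lat": f.data["lat"],
                "lon": f.data["lon"],
            },
            name="expc",
            attrs={"units": "mol m-2 s-1"},
        )
        flipped.to_dataset().to_netcdf(tmp_path / "up.nc", engine="scipy")
        back = read_cmip_variable(tmp_path / "up.nc", "expc")
        assert list(back.data["lev"].values) == [50.0, 150.0, 600.0, 1500.0]
        np.testing.assert_array_equal(back.values, f.values)

    def test_missing_units_is_metadata_error(self, tmp_path):
        da = xr.DataArray(np.ones((2, 2)), dims=("lat", "lon"), name="o2")
        da.to_dataset().to_netcdf(tmp_path / "bad.nc", engine="scipy")
        with pytest.raises(LoadError, match="units"):
            read_cmip_variable(tmp_path / "bad.nc", "o2")

    def test_missing_variable_named_in_error(self, tmp_path):
        da = xr.DataArray(np.ones((2, 2)), dims=("lat", "lon"), name="thetao", attrs={"units": "degC"})
        da.to_dataset().to_netcdf(tmp_path / "t.nc", engine="scipy")
        with pytest.raises(LoadError, match="'o2'"):
            read_cmip_variable(tmp_path / "t.nc", "o2")

    def test_permuted_storage_order_gives_identical_diagnostics(self, tmp_path):
        f = _demo_field(with_time=False)
        grid = make_box_grid()
        write_cmip_variable(f, tmp_path / "a.nc")
        permuted = f.data.transpose("lon", "lev", "lat")
        permuted.attrs["units"] = f.units
        permuted.to_dataset(name="expc").to_netcdf(tmp_path / "b.nc", engine="scipy")
        fa = read_cmip_variable(tmp_path / "a.nc", "expc")
        fb = read_cmip_variable(tmp_path / "b.nc", "expc")
        np.testing.assert_array_equal(fa.values, fb.values)
        aou_a = Field("aou", fa.data, "mol m-3")
        aou_b = Field("aou", fb.data, "mol m-3")
        assert compute_csoft(aou_a, grid) == compute_csoft(aou_b, grid)


class TestCellMeasures:
    def _write_measures(self, tmp_path, grid, with_vol=True):
        area = xr.DataArray(
            grid.cell_area,
            dims=("lat", "lon"),
            coords={"lat": grid.lat, "lon": grid.lon},
            name="areacello",
        )
        write_cmip_variable(Field("areacello", area, "m2"), tmp_path / "area.nc")
        if with_vol:
            vol = xr.DataArray(
                np.where(grid.cell_volume > 0, grid.cell_volume, np.nan),
                dims=("lev", "lat", "lon"),
                coords={
                    "lev": ("lev", grid.depth_centers, {"units": "m", "positive": "down"}),
                    "lat": grid.lat,
                    "lon": grid.lon,
                },
                name="volcello",
            )
            write_cmip_variable(
                Field("volcello", vol, "m3"), tmp_path / "vol.nc", depth_bounds=grid.depth_bounds
            )

    def test_volcello_total_volume_conserved(self, tmp_path):
        grid = make_box_grid()
        self._write_measures(tmp_path, grid)
        back = read_cell_measures(tmp_path / "area.nc", tmp_path / "vol.nc")
        assert back.total_volume == pytest.approx(grid.total_volume, rel=1e-12)

    def test_area_times_thickness_fallback(self, tmp_path):
        grid = make_box_grid()
        self._write_measures(tmp_path, grid, with_vol=False)
        ref = _demo_field(with_time=False)
        back = read_cell_measures(tmp_path / "area.nc", None, reference=ref)
        # hand-derived midpoint bounds for levels 50/150/600/1500 m:
        # interfaces 0, 100, 375, 1050, 1950 -> thicknesses below
        dz = np.array([100.0, 275.0, 675.0, 900.0])
        # the reference field has one masked column; volumes zero there
        expect = grid.cell_area[None] * dz[:, None, None]
        expect[:, 0, 0] = 0.0
        np.testing.assert_allclose(back.cell_volume, expect, rtol=1e-12)

    def test_shape_mismatch_is_grid_error(self, tmp_path):
        grid = make_box_grid()
        self._write_measures(tmp_path, grid)
        bigger = make_box_grid(nlat=3)
        area = xr.DataArray(
            bigger.cell_area,
            dims=("lat", "lon"),
            coords={"lat": bigger.lat, "lon": bigger.lon},
            name="areacello",
        )
        write_cmip_variable(Field("areacello", area, "m2"), tmp_path / "area3.nc")
        with pytest.raises(GridError, match="does not match"):
            read_cell_measures(tmp_path / "area3.nc", tmp_path / "vol.nc")


class TestGridInvariants:
    def test_volume_sums_to_total(self):
        grid = make_box_grid()
        assert np.nansum(grid.cell_volume) == pytest.approx(grid.total_volume, rel=1e-6)

    def test_masked_columns_must_be_empty(self):
        grid = make_box_grid()
        mask = grid.land_mask.copy()
        mask[0, 0] = True
        with pytest.raises(GridError, match="zero volume"):
            OceanGrid(
                cell_area=grid.cell_area,
                depth_centers=grid.depth_centers,
                depth_bounds=grid.depth_bounds,
                cell_volume=grid.cell_volume,
                land_mask=mask,
                lat=grid.lat,
                lon=grid.lon,
            )

    def test_depths_must_increase(self):
        grid = make_box_grid()
        with pytest.raises(GridError, match="increasing"):
            OceanGrid(
                cell_area=grid.cell_area,
                depth_centers=grid.depth_centers[::-1],
                depth_bounds=grid.depth_bounds,
                cell_volume=grid.cell_volume,
                land_mask=grid.land_mask,
                lat=grid.lat,
                lon=grid.lon,
            )


def _series(model="M1", experiment="piControl", years=(2000, 2001, 2002)):
    n = len(years)
    return BCPTimeSeries(
        model_name=model,
        experiment_id=experiment,
        years=np.array(years),
        csoft=np.linspace(100, 101, n),
        ep100=np.full(n, 6.0),
        f1000=np.full(n, 0.8),
        te=np.full(n, 100 * 0.8 / 6.0),
        strat=np.full(n, 1.2),
    )


class TestTimeseriesTable:
    def test_row_count(self, tmp_path):
        path = tmp_path / "t.csv"
        write_timeseries_table([_series("M1"), _series("M2")], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + 6

    def test_empty_collection_header_only(self, tmp_path):
        path = tmp_path / "t.csv"
        write_timeseries_table([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("model,experiment,year,csoft_PgC")

    def test_byte_identical_rewrite(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_timeseries_table([_series()], p1)
        write_timeseries_table([_series()], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_duplicate_rows_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            write_timeseries_table([_series(), _series()], tmp_path / "t.csv")
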