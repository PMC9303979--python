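"""BCP state metrics against hand calculations and scalar-loop oracles."""

import numpy as np
import pytest
import xarray as xr

from biopump.diagnostics import (
    M_C,
    R_C_O,
    UnitError,
    compute_aou,
    compute_csoft,
    integrate_flux,
    interpolate_flux_to_depth,
    seconds_per_year,
    stratification_index,
    transfer_efficiency,
    transfer_efficiency_map,
)
from biopump.grids import Field, GridError, OceanGrid
from biopump.seawater import RHO0, oxygen_saturation

from conftest import make_box_grid


def _field(values, name="x", units="mol m-3", levs=None, grid=None):
    values = np.asarray(values, dtype=float)
    dims = ("lev", "lat", "lon")[3 - values.ndim :]
    coords = {}
    if "lev" in dims:
        coords["lev"] = ("lev", levs if levs is not None else np.arange(values.shape[0]) + 1.0)
    return Field(name, xr.DataArray(values, dims=dims, coords=coords, name=name), units)


class TestAOU:
    def _tsfields(self, T, S):
        return (
            _field(T, "thetao", "degC"),
            _field(S, "so", "0.001"),
        )

    def test_saturated_ocean_has_zero_aou(self):
        T = np.full((2, 2, 2), 10.0)
        S = np.full((2, 2, 2), 35.0)
        sat = oxygen_saturation(T, S) * 1e-6 * RHO0
        thetao, so = self._tsfields(T, S)
        aou = compute_aou(_field(sat, "o2"), thetao, so)
        np.testing.assert_allclose(aou.values, 0.0, atol=1e-15)

    def test_anoxic_limit_equals_saturation(self):
        T = np.full((2, 2, 2), 4.0)
        S = np.full((2, 2, 2), 34.0)
        thetao, so = self._tsfields(T, S)
        aou = compute_aou(_field(np.zeros_like(T), "o2"), thetao, so)
        np.testing.assert_array_equal(
            aou.values, oxygen_saturation(T, S) * 1e-6 * RHO0
        )

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(11)
        T = rng.uniform(0, 25, (3, 2, 2))
        S = rng.uniform(33, 36, (3, 2, 2))
        o2 = rng.uniform(0.1, 0.35, (3, 2, 2))
        thetao, so = self._tsfields(T, S)
        aou = compute_aou(_field(o2, "o2"), thetao, so).values
        for idx in np.ndindex(T.shape):
            expect = oxygen_saturation(float(T[idx]), float(S[idx])) * 1e-6 * RHO0 - o2[idx]
            assert aou[idx] == pytest.approx(expect, rel=1e-14)

    def test_mask_propagates(self):
        T = np.full((2, 2, 2), 10.0)
        T[0, 0, 0] = np.nan
        thetao, so = self._tsfields(T, np.full_like(T, 35.0))
        aou = compute_aou(_field(np.full_like(T, 0.2), "o2"), thetao, so)
        assert np.isnan(aou.values[0, 0, 0])

    def test_unit_mismatch_rejected(self):
        T = np.full((1, 1, 1), 10.0)
        thetao, so = self._tsfields(T, np.full_like(T, 35.0))
        with pytest.raises(UnitError):
            compute_aou(_field(T, "o2", units="umol kg-1"), thetao, so)


class TestCsoft:
    def test_zero_aou_zero_inventory(self):
        grid = make_box_grid()
        aou = _field(np.zeros((4, 2, 3)), "aou", levs=grid.depth_centers)
        assert compute_csoft(aou, grid) == 0.0

    def test_uniform_aou_hand_value(self):
        # 0.1 mol m-3 over 1.3e18 m3: 0.1 * (117/170) * 12.01 * 1.3e18 g
        grid = make_box_grid(area=1.0)
        scale = 1.3e18 / grid.total_volume
        grid = OceanGrid(
            cell_area=grid.cell_area,
            depth_centers=grid.depth_centers,
            depth_bounds=grid.depth_bounds,
            cell_volume=grid.cell_volume * scale,
            land_mask=grid.land_mask,
            lat=grid.lat,
            lon=grid.lon,
        )
        aou = _field(np.full((4, 2, 3), 0.1), "aou", levs=grid.depth_centers)
        assert compute_csoft(aou, grid) == pytest.approx(1074.5, rel=1e-3)

    def test_linearity_in_aou(self):
        grid = make_box_grid()
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 0.3, (4, 2, 3))
        f1 = _field(a, "aou", levs=grid.depth_centers)
        f2 = _field(2 * a, "aou", levs=grid.depth_centers)
        assert compute_csoft(f2, grid) == pytest.approx(2 * compute_csoft(f1, grid), rel=1e-14)

    def test_volume_scaling(self):
        grid = make_box_grid()
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 0.3, (4, 2, 3))
        f = _field(a, "aou", levs=grid.depth_centers)
        scaled = OceanGrid(
            cell_area=grid.cell_area,
            depth_centers=grid.depth_centers,
            depth_bounds=grid.depth_bounds,
            cell_volume=grid.cell_volume * 3.0,
            land_mask=grid.land_mask,
            lat=grid.lat,
            lon=grid.lon,
        )
        assert compute_csoft(f, scaled) == pytest.approx(3 * compute_csoft(f, grid), rel=1e-14)

    def test_mean_concentration_variant(self):
        grid = make_box_grid()
        aou = _field(np.full((4, 2, 3), 0.1), "aou", levs=grid.depth_centers)
        conc = compute_csoft(aou, grid, per_volume=True)
        assert conc == pytest.approx(0.1 * R_C_O * M_C, rel=1e-12)  # g C m-3


class TestDepthInterpolation:
    def test_exact_level_pass_through(self):
        vals = np.arange(4 * 2 * 3, dtype=float).reshape(4, 2, 3)
        f = _field(vals, levs=[50.0, 100.0, 600.0, 1500.0])
        out = interpolate_flux_to_depth(f, 100.0)
        np.testing.assert_array_equal(out.values, vals[1])

    def test_linear_midpoint(self):
        vals = np.stack([np.full((1, 1), 10.0), np.full((1, 1), 6.0)])
        f = _field(vals, levs=[90.0, 110.0])
        assert interpolate_flux_to_depth(f, 100.0).values[0, 0] == pytest.approx(8.0)

    def test_shallow_column_masked(self):
        vals = np.ones((3, 1, 2))
        vals[2, 0, 1] = np.nan  # bottom at 800 m in column 1
        f = _field(vals, levs=[100.0, 800.0, 1200.0])
        out = interpolate_flux_to_depth(f, 1000.0)
        assert np.isfinite(out.values[0, 0])
        assert np.isnan(out.values[0, 1])

    def test_target_below_grid_masked(self):
        f = _field(np.ones((2, 1, 1)), levs=[100.0, 800.0])
        assert np.isnan(interpolate_flux_to_depth(f, 1000.0).values).all()

    def test_nonpositive_target_rejected(self):
        f = _field(np.ones((2, 1, 1)), levs=[100.0, 800.0])
        with pytest.raises(ValueError, match="positive"):
            interpolate_flux_to_depth(f, 0.0)


class TestFluxIntegral:
    def test_uniform_flux_hand_value(self):
        # 1 mol C m-2 y-1 over 3.6e14 m2 -> 12.01 g/mol * 3.6e14 = 4.3236 Pg C/y
        grid = make_box_grid(area=3.6e14 / 6)
        spy = seconds_per_year("360_day")
        f = _field(np.full((2, 3), 1.0 / spy), "expc", units="mol m-2 s-1")
        assert integrate_flux(f, grid, "360_day") == pytest.approx(4.32, rel=1e-2)
        assert integrate_flux(f, grid, "360_day") == pytest.approx(4.3236, rel=1e-12)

    def test_zero_flux(self):
        grid = make_box_grid()
        f = _field(np.zeros((2, 3)), "expc", units="mol m-2 s-1")
        assert integrate_flux(f, grid, "360_day") == 0.0

    def test_two_cell_manual_sum(self):
        grid = make_box_grid(nlat=1, nlon=2, area=2.0e13)
        flux = np.array([[3.0e-9, 7.0e-9]])
        f = _field(flux, "expc", units="mol m-2 s-1")
        spy = seconds_per_year("noleap")
        expect = (3.0e-9 + 7.0e-9) * 2.0e13 * spy * M_C / 1e15
        assert integrate_flux(f, grid, "noleap") == pytest.approx(expect, rel=1e-14)

    def test_wrong_units_rejected(self):
        grid = make_box_grid()
        f = _field(np.zeros((2, 3)), "expc", units="g m-2 d-1")
        with pytest.raises(UnitError):
            integrate_flux(f, grid, "360_day")


class TestTransferEfficiency:
    def test_arithmetic(self):
        assert transfer_efficiency(10.0, 2.0) == pytest.approx(20.0)

    def test_zero_numerator(self):
        assert transfer_efficiency(5.0, 0.0) == 0.0

    def test_identity_flux(self):
        assert transfer_efficiency(5.0, 5.0) == pytest.approx(100.0)

    def test_nonpositive_export_rejected(self):
        with pytest.raises(ValueError, match="export"):
            transfer_efficiency(0.0, 1.0)

    def test_map_constant_ratio(self):
        f1000 = _field(np.full((2, 3), 2.0e-9), "expc", units="mol m-2 s-1")
        f100 = _field(np.full((2, 3), 4.0e-9), "expc", units="mol m-2 s-1")
        m = transfer_efficiency_map(f100, f1000)
        np.testing.assert_allclose(m.values.values, 50.0)

    def test_map_floor_masks(self):
        a = np.full((2, 3), 4.0e-9)
        a[0, 0] = 1.0e-15
        f100 = _field(a, "expc", units="mol m-2 s-1")
        f1000 = _field(np.full((2, 3), 2.0e-9), "expc", units="mol m-2 s-1")
        m = transfer_efficiency_map(f100, f1000, floor=1e-12)
        assert np.isnan(m.values.values[0, 0])
        assert not m.validity_mask[0, 0]

    def test_map_matches_scalar_loop(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 5e-9, (3, 4))
        b = rng.uniform(0, 2e-9, (3, 4))
        floor = 1e-9
        m = transfer_efficiency_map(
            _field(a, "expc", units="mol m-2 s-1"),
            _field(b, "expc", units="mol m-2 s-1"),
            floor=floor,
        )
        for i in range(3):
            for j in range(4):
                if a[i, j] > floor:
                    assert m.values.values[i, j] == pytest.approx(100 * b[i, j] / a[i, j])
                else:
                    assert np.isnan(m.values.values[i, j])

    def test_map_shape_mismatch_rejected(self):
        f100 = _field(np.ones((2, 3)), "expc", units="mol m-2 s-1")
        f1000 = _field(np.ones((2, 4)), "expc", units="mol m-2 s-1")
        with pytest.raises(GridError):
            transfer_efficiency_map(f100, f1000)

    def test_global_te_equals_flux_weighted_map(self):
        """With no floored cells, the global ratio is the f100-weighted map mean."""
        rng = np.random.default_rng(13)
        grid = make_box_grid()
        a = rng.uniform(1e-9, 5e-9, (2, 3))
        b = a * rng.uniform(0.05, 0.3, (2, 3))
        f100 = _field(a, "expc", units="mol m-2 s-1")
        f1000 = _field(b, "expc", units="mol m-2 s-1")
        te_global = transfer_efficiency(
            integrate_flux(f100, grid, "360_day"), integrate_flux(f1000, grid, "360_day")
        )
        m = transfer_efficiency_map(f100, f1000, floor=0.0).values.values
        w = a * grid.ocean_area
        assert te_global == pytest.approx(np.sum(m * w) / np.sum(w), rel=1e-12)


class TestStratification:
    def _sigma(self, profiles, levs):
        return _field(np.asarray(profiles, dtype=float), "sigma0", units="kg m-3", levs=levs)

    def test_vertically_uniform_is_zero(self):
        vals = np.full((3, 2, 2), 27.0)
        grid = make_box_grid(nlat=2, nlon=2, depths=(10.0, 200.0, 500.0))
        out = stratification_index(self._sigma(vals, [10.0, 200.0, 500.0]), grid)
        assert out == pytest.approx(0.0, abs=1e-14)

    def test_equal_area_mean(self):
        grid = make_box_grid(nlat=1, nlon=2, depths=(10.0, 200.0, 500.0))
        vals = np.zeros((3, 1, 2))
        vals[1, 0, 0] = 0.5
        vals[1, 0, 1] = 1.5
        out = stratification_index(self._sigma(vals, [10.0, 200.0, 500.0]), grid)
        assert out == pytest.approx(1.0)

    def test_area_weighted_mean(self):
        grid = make_box_grid(nlat=1, nlon=2, depths=(10.0, 200.0, 500.0))
        grid.cell_area[0, 0] = 1.0e12
        grid.cell_area[0, 1] = 3.0e12
        vals = np.zeros((3, 1, 2))
        vals[1, 0, 0] = 0.4
        vals[1, 0, 1] = 0.8
        out = stratification_index(self._sigma(vals, [10.0, 200.0, 500.0]), grid)
        assert out == pytest.approx(0.7)  # (1*0.4 + 3*0.8)/4

    def test_interpolates_to_200m(self):
        grid = make_box_grid(nlat=1, nlon=1, depths=(10.0, 150.0, 250.0))
        vals = np.array([[[0.0]], [[1.0]], [[3.0]]])
        out = stratification_index(self._sigma(vals, [10.0, 150.0, 250.0]), grid)
        assert out == pytest.approx(2.0)  # linear between 1 at 150 and 3 at 250

    def test_no_deep_level_anywhere_rejected(self):
        grid = make_box_grid(nlat=1, nlon=1, depths=(10.0, 50.0, 150.0))
        vals = np.zeros((3, 1, 1))
        with pytest.raises(ValueError, match="200"):
            stratification_index(self._sigma(vals, [10.0, 50.0, 150.0]), grid)


def test_diagnostics_invariant_under_longitude_rotation():
    """Rolling all fields and the grid in longitude leaves global metrics unchanged."""
    grid = make_box_grid()
    rng = np.random.default_rng(21)
    aou = rng.uniform(0, 0.3, (4, 2, 3))
    flux = rng.uniform(0, 5e-9, (2, 3))
    f_aou = _field(aou, "aou", levs=grid.depth_centers)
    f_flux = _field(flux, "expc", units="mol m-2 s-1")
    rolled_aou = _field(np.roll(aou, 1, axis=-1), "aou", levs=grid.depth_centers)
    rolled_flux = _field(np.roll(flux, 1, axis=-1), "expc", units="mol m-2 s-1")
    assert compute_csoft(f_aou, grid) == pytest.approx(compute_csoft(rolled_aou, grid), rel=1e-14)
    assert integrate_flux(f_flux, grid, "360_day") == pytest.approx(
        integrate_flux(rolled_flux, grid, "360_day"), rel=1e-14
    )
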