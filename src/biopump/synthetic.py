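"""Synthetic CMIP6-like ensemble with known biological-pump ground truth.

The generator writes small CF-netCDF model runs (``o2``, ``expc``,
``thetao``, ``so`` plus ``areacello``/``volcello`` measures) whose
biological-pump diagnostics are known in closed form, so the whole
pipeline can be tested without any archive access.  The construction
mirrors the causal chain of the real system:

* each column carries a Martin power-law POC flux
  ``F(z) = EP_cell (z/100)^(-b_cell)`` with spatially varying export and
  attenuation;
* oxygen is set to saturation (from ``thetao``/``so``) minus a
  respiration-accumulated deficit ``AOU = (170/117) R(z) tau(z)``, where
  ``R = -dF/dz`` and ``tau(z)`` is a fixed interior residence-time
  profile — so the AOU-based carbon storage is exactly the carbon
  implied by the flux field;
* control runs carry only a slow linear drift (a function of parent
  time); scenario runs branch from the control at ``branch_year`` and add
  prescribed trends: export declines, transfer efficiency drifts, the
  upper ocean stratifies (surface-intensified warming), and interior
  residence times lengthen (ventilation slowdown) — the latter is what
  makes sequestered carbon rise while export falls, as in warming
  projections.

Monthly output on a 360-day calendar exercises calendar-aware averaging;
all seasonal cycles have exactly zero annual mean, and noise is injected
per year, so annual ground truths are exact.  Identical parameters and
seed give byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable

import cftime
import numpy as np
import xarray as xr

from .diagnostics import G_PER_PG, M_C, R_C_O, seconds_per_year
from .grids import Field, OceanGrid
from .io import write_cmip_variable
from .seawater import RHO0, oxygen_saturation, potential_density

__all__ = ["GeneratorParams", "GroundTruth", "make_grid", "simulate_run", "ground_truth"]

EXPORT_DEPTH = 100.0  # m
DEEP_FLUX_DEPTH = 1000.0  # m
STRAT_DEPTH = 200.0  # m
BOTTOM_DEPTH = 5000.0  # m
_EARTH_RADIUS = 6.371e6  # m

_EXPERIMENT_INDEX = {"piControl": 0, "historical": 1, "ssp126": 2, "ssp370": 3}


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions of the synthetic ensemble.

    Trends apply to scenario experiments (per century of scenario time);
    drifts are slow functions of parent (control) time present in every
    run, so they cancel under branch-aligned control subtraction.  Noise
    is deliberately weak — it represents the residual internal
    variability of *global annual* metrics, not local variability — so
    the prescribed trends dominate 50-year runs.
    """

    nlat: int = 8
    nlon: int = 16
    nz: int = 20
    years_control: int = 60
    years_scenario: int = 50
    control_start_year: int = 1850
    scenario_start_year: int = 2015
    branch_year: int = 1855
    calendar: str = "360_day"
    # baseline state
    ep0_pg: float = 6.0  # global export production, Pg C y-1
    b_base: float = 0.9  # mean Martin exponent
    b_amplitude: float = 0.2  # spatial amplitude of the exponent
    tau_deep_years: float = 1000.0  # residence time at the bottom
    tau_shape_exponent: float = 1.5  # tau(z) ~ ((z-100)/(bottom-100))^gamma
    # prescribed scenario trends, per century
    ep_trend_pg_per_century: float = -0.5
    te_trend_pct_per_century: float = -1.0
    strat_trend_kgm3_per_century: float = 0.2
    tau_trend_pct_per_century: float = 20.0
    # control drift, per century of parent time
    ep_drift_pg_per_century: float = 0.05
    te_drift_pct_per_century: float = 0.05
    strat_drift_kgm3_per_century: float = 0.01
    tau_drift_pct_per_century: float = 1.0
    # noise
    ep_cell_noise_sd: float = 0.003  # lognormal sigma per cell-year
    theta_noise_sd_degc: float = 0.02  # annual scalar, surface-intensified
    seed: int = 0

    def zero_noise(self) -> "GeneratorParams":
        return replace(self, ep_cell_noise_sd=0.0, theta_noise_sd_degc=0.0)

    def stationary(self) -> "GeneratorParams":
        """Zero trend, zero drift, zero noise: a flat-line control."""
        return replace(
            self.zero_noise(),
            ep_trend_pg_per_century=0.0,
            te_trend_pct_per_century=0.0,
            strat_trend_kgm3_per_century=0.0,
            tau_trend_pct_per_century=0.0,
            ep_drift_pg_per_century=0.0,
            te_drift_pct_per_century=0.0,
            strat_drift_kgm3_per_century=0.0,
            tau_drift_pct_per_century=0.0,
        )


# ---------------------------------------------------------------------------
# grid


def make_grid(nlat: int, nlon: int, nz: int) -> OceanGrid:
    """Regular lat-lon grid with log-spaced levels snapped to 100/200/1000 m.

    Cell areas follow the sphere (proportional to the sine difference of
    the latitude bounds); depth levels are log-spaced from 5 m to 5000 m
    with the nearest levels snapped exactly onto the diagnostic depths so
    that depth interpolation is exact there; a simple two-block continent
    provides a land mask; volumes are area x thickness over ocean.
    """
    if nlat < 2 or nlon < 2:
        raise ValueError("need at least 2x2 horizontal cells")
    lev = np.geomspace(5.0, BOTTOM_DEPTH, nz)
    targets = (EXPORT_DEPTH, STRAT_DEPTH, DEEP_FLUX_DEPTH)
    idx = [int(np.argmin(np.abs(lev - t))) for t in targets]
    if len(set(idx)) != len(idx) or min(idx) == 0 or max(idx) == nz - 1:
        raise ValueError(
            f"nz={nz} too coarse to resolve the 100/200/1000 m diagnostic depths"
        )
    for i, t in zip(idx, targets):
        lev[i] = t
    lev = np.sort(lev)

    mid = 0.5 * (lev[1:] + lev[:-1])
    bounds = np.column_stack(
        [np.concatenate([[0.0], mid]), np.concatenate([mid, [BOTTOM_DEPTH]])]
    )

    dlat = 180.0 / nlat
    dlon = 360.0 / nlon
    lat = -90.0 + dlat * (np.arange(nlat) + 0.5)
    lon = dlon * (np.arange(nlon) + 0.5)
    lat_b = np.radians(np.stack([lat - dlat / 2, lat + dlat / 2]))
    band = _EARTH_RADIUS**2 * np.radians(dlon) * (np.sin(lat_b[1]) - np.sin(lat_b[0]))
    area = np.repeat(band[:, None], nlon, axis=1)

    # two idealised continents
    lon2d = np.broadcast_to(lon[None, :], (nlat, nlon))
    lat2d = np.broadcast_to(lat[:, None], (nlat, nlon))
    land = ((lon2d > 280) & (lon2d < 330) & (np.abs(lat2d) < 70)) | (
        (lon2d > 40) & (lon2d < 80) & (lat2d > 0) & (lat2d < 75)
    )

    dz = bounds[:, 1] - bounds[:, 0]
    volume = np.where(land[None, :, :], 0.0, area[None, :, :] * dz[:, None, None])
    return OceanGrid(
        cell_area=np.where(land, np.nan, area),
        depth_centers=lev,
        depth_bounds=bounds,
        cell_volume=volume,
        land_mask=land,
        lat=lat,
        lon=lon,
    )


# ---------------------------------------------------------------------------
# deterministic construction


def _tau_profile(params: GeneratorParams, z: np.ndarray) -> np.ndarray:
    """Interior residence time, years; zero above the export depth."""
    frac = np.clip((z - EXPORT_DEPTH) / (BOTTOM_DEPTH - EXPORT_DEPTH), 0.0, None)
    return params.tau_deep_years * frac**params.tau_shape_exponent


def _ep_pattern(grid: OceanGrid) -> np.ndarray:
    """Dimensionless export pattern, zero on land, unit area-weighted mean."""
    lat = np.radians(grid.lat)[:, None]
    lon = np.radians(grid.lon)[None, :]
    pat = (0.4 + np.cos(lat) ** 2) * (1.0 + 0.3 * np.sin(2.0 * lon))
    pat = np.where(grid.land_mask, 0.0, pat)
    area = grid.ocean_area
    return pat / np.sum(pat * area) * np.sum(area)


def _b_pattern(params: GeneratorParams, grid: OceanGrid) -> np.ndarray:
    lat = np.radians(grid.lat)[:, None]
    lon = np.radians(grid.lon)[None, :]
    b = params.b_base + params.b_amplitude * np.cos(2 * lat) * np.cos(lon + 1.0)
    return np.where(grid.land_mask, np.nan, b)


def _base_theta(grid: OceanGrid) -> np.ndarray:
    """Climatological potential temperature (nz, nlat), degC."""
    lat = np.radians(grid.lat)
    tsurf = 2.0 + 25.0 * np.cos(lat) ** 2
    z = grid.depth_centers
    return 2.0 + (tsurf[None, :] - 2.0) * np.exp(-z[:, None] / 500.0)


def _base_so(grid: OceanGrid) -> np.ndarray:
    """Climatological practical salinity (nz, nlat)."""
    z = grid.depth_centers
    lat = np.radians(grid.lat)
    return 34.5 + 0.3 * np.exp(-z[:, None] / 300.0) * (1.0 + 0.2 * np.cos(2 * lat))[None, :]


def _seasonal_theta(grid: OceanGrid) -> np.ndarray:
    """Zero-annual-mean seasonal temperature cycle (12, nz, nlat), degC."""
    z = grid.depth_centers
    lat = np.radians(grid.lat)
    months = np.arange(12)
    phase = np.cos(2.0 * np.pi * (months[:, None, None] + 0.5) / 12.0)
    amp = 3.0 * np.cos(lat)[None, None, :] * np.sign(np.sin(lat))[None, None, :]
    depth = np.exp(-z / 50.0)[None, :, None]
    return phase * amp * depth


def _seasonal_export(grid: OceanGrid) -> np.ndarray:
    """Zero-annual-mean multiplicative export seasonality (12, nlat)."""
    lat = np.radians(grid.lat)
    months = np.arange(12)
    phase = np.cos(2.0 * np.pi * (months[:, None] + 0.5) / 12.0)
    return 0.3 * phase * np.sign(np.sin(lat))[None, :] * np.cos(lat)[None, :]


def _dsigma_dt(tref: float = 18.0, sref: float = 35.0) -> float:
    return float(
        (potential_density(tref + 0.5, sref) - potential_density(tref - 0.5, sref))
    )


def _warming_shape(grid: OceanGrid) -> np.ndarray:
    """Vertical shape of scenario warming (surface intensified), (nz,)."""
    return np.exp(-grid.depth_centers / 200.0)


def _time_factors(params: GeneratorParams, experiment_id: str) -> dict[str, np.ndarray]:
    """Per-year deterministic drivers for one experiment.

    Returns calendar years, trend time (centuries since scenario start;
    zero in the control) and parent time (centuries since control start)
    plus the derived global drivers.
    """
    if experiment_id == "piControl":
        n = params.years_control
        years = params.control_start_year + np.arange(n)
        trend_c = np.zeros(n)
        parent_c = (years - params.control_start_year) / 100.0
    else:
        if experiment_id not in _EXPERIMENT_INDEX:
            raise ValueError(f"unknown experiment {experiment_id!r}")
        n = params.years_scenario
        years = params.scenario_start_year + np.arange(n)
        trend_c = np.arange(n) / 100.0
        parent_c = (params.branch_year - params.control_start_year + np.arange(n)) / 100.0
    if np.any(parent_c < 0):
        raise ValueError("branch year precedes the start of the parent control")

    ep_glob = (
        params.ep0_pg
        + params.ep_trend_pg_per_century * trend_c
        + params.ep_drift_pg_per_century * parent_c
    )
    dte = params.te_trend_pct_per_century * trend_c + params.te_drift_pct_per_century * parent_c
    tau_factor = (
        1.0
        + params.tau_trend_pct_per_century / 100.0 * trend_c
        + params.tau_drift_pct_per_century / 100.0 * parent_c
    )
    dstrat = (
        params.strat_trend_kgm3_per_century * trend_c
        + params.strat_drift_kgm3_per_century * parent_c
    )
    return {
        "years": years,
        "trend_c": trend_c,
        "parent_c": parent_c,
        "ep_glob": ep_glob,
        "dte": dte,
        "tau_factor": tau_factor,
        "dstrat": dstrat,
    }


class _State:
    """Deterministic annual construction shared by the writer and the oracle."""

    def __init__(self, params: GeneratorParams, experiment_id: str):
        self.params = params
        self.experiment_id = experiment_id
        self.grid = make_grid(params.nlat, params.nlon, params.nz)
        self.drivers = _time_factors(params, experiment_id)
        g = self.grid
        self.pattern = _ep_pattern(g)
        self.b0 = _b_pattern(params, g)
        self.area = g.ocean_area
        self.ocean = ~g.land_mask
        # baseline flux-weighted transfer efficiency, percent, for the
        # te-trend -> attenuation-shift conversion
        w = self.pattern * self.area
        te_cells = 100.0 * (DEEP_FLUX_DEPTH / EXPORT_DEPTH) ** (
            -np.where(self.ocean, self.b0, 0.0)
        )
        self.te0 = float(np.sum(np.where(self.ocean, w * te_cells, 0.0)) / np.sum(w))
        self.theta0 = _base_theta(g)  # (nz, nlat)
        self.so0 = _base_so(g)
        self.warm_shape = _warming_shape(g)
        self.dsigma = _dsigma_dt()
        # effective strat response of the warming shape: sigma'(T) * (shape(200) - shape(0m level))
        z = g.depth_centers
        s200 = np.interp(STRAT_DEPTH, z, self.warm_shape)
        self.strat_response = self.dsigma * (s200 - self.warm_shape[0])  # per degC of surface warming

    # -- per-year deterministic cell fields ---------------------------------
    def b_cells(self, iy: int) -> np.ndarray:
        # dte is in percentage points; d(TE)/db = -ln(10) TE  (TE in percent)
        db = -self.drivers["dte"][iy] / (np.log(10.0) * self.te0)
        return self.b0 + db

    def ep_cells(self, iy: int) -> np.ndarray:
        """Export at 100 m per cell, mol C m-2 y-1 (noise-free)."""
        total_mol = self.drivers["ep_glob"][iy] * G_PER_PG / M_C
        return total_mol * self.pattern / np.sum(self.pattern * self.area)

    def theta_year(self, iy: int) -> np.ndarray:
        """Annual-mean potential temperature (nz, nlat), degC."""
        dts = self.drivers["dstrat"][iy] / self.strat_response
        return self.theta0 + dts * self.warm_shape[:, None]

    def tau_year(self, iy: int) -> np.ndarray:
        return _tau_profile(self.params, self.grid.depth_centers) * self.drivers[
            "tau_factor"
        ][iy]

    def aou_year(self, iy: int, ep_cells: np.ndarray | None = None) -> np.ndarray:
        """AOU (nz, nlat, nlon), mol O2 m-3, from the respiration closure."""
        g = self.grid
        z = g.depth_centers
        ep = self.ep_cells(iy) if ep_cells is None else ep_cells
        b = self.b_cells(iy)
        with np.errstate(invalid="ignore"):
            resp = (
                ep[None, :, :]
                * b[None, :, :]
                * EXPORT_DEPTH ** b[None, :, :]
                * z[:, None, None] ** (-b[None, :, :] - 1.0)
            )  # mol C m-3 y-1
        aou_c = resp * self.tau_year(iy)[:, None, None]  # mol C m-3
        aou_c = np.where(z[:, None, None] < EXPORT_DEPTH, 0.0, aou_c)
        aou = aou_c / R_C_O  # mol O2 m-3
        return np.where(self.ocean[None, :, :], aou, np.nan)

    def expc_profile(self, iy: int, ep_cells: np.ndarray | None = None) -> np.ndarray:
        """Annual-mean POC flux (nz, nlat, nlon), mol C m-2 y-1."""
        g = self.grid
        z = g.depth_centers
        ep = self.ep_cells(iy) if ep_cells is None else ep_cells
        b = self.b_cells(iy)
        with np.errstate(invalid="ignore"):
            shape = np.where(
                z[:, None, None] < EXPORT_DEPTH,
                1.0,
                (z[:, None, None] / EXPORT_DEPTH) ** (-b[None, :, :]),
            )
        out = ep[None, :, :] * shape
        return np.where(self.ocean[None, :, :], out, np.nan)


# ---------------------------------------------------------------------------
# file writer


def _time_axis(params: GeneratorParams, years: np.ndarray):
    """Mid-month cftime coordinates for the run."""
    start = int(years[0])
    dates = []
    for y in years:
        for m in range(12):
            dates.append(
                cftime.datetime(int(y), m + 1, 16, calendar=params.calendar)
            )
    units = f"days since {start}-01-01"
    return xr.DataArray(
        np.array(dates, dtype=object), dims="time", name="time"
    ), units


def _rng(params: GeneratorParams, experiment_id: str, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=params.seed, spawn_key=(_EXPERIMENT_INDEX[experiment_id], stream)
    )
    return np.random.default_rng(ss)


def _noise(params: GeneratorParams, experiment_id: str, n_years: int, grid: OceanGrid):
    """Annual noise draws: per-cell lognormal export multipliers, theta scalar."""
    rng_ep = _rng(params, experiment_id, 0)
    rng_th = _rng(params, experiment_id, 1)
    sd = params.ep_cell_noise_sd
    shape = (n_years,) + grid.cell_area.shape
    if sd > 0:
        mult = np.exp(rng_ep.standard_normal(shape) * sd - 0.5 * sd * sd)
    else:
        mult = np.ones(shape)
    tsd = params.theta_noise_sd_degc
    eta = rng_th.standard_normal(n_years) * tsd if tsd > 0 else np.zeros(n_years)
    return mult, eta


def simulate_run(
    params: GeneratorParams,
    experiment_id: str,
    outdir: str | os.PathLike,
    model_name: str = "SYNTH",
) -> dict[str, str]:
    """Write one experiment's netCDF files; returns variable -> path.

    Files: ``{var}_{model}_{experiment}.nc`` for o2/expc/thetao/so plus
    ``areacello_{model}.nc`` and ``volcello_{model}.nc``.  Scenario files
    carry ``branch_time_in_parent`` / ``parent_time_units`` global
    attributes.  Identical params and seed give byte-identical files.
    """
    state = _State(params, experiment_id)
    g = state.grid
    years = state.drivers["years"]
    ny = years.size
    nz, nlat, nlon = g.nz, g.lat.size, g.lon.size
    mult, eta = _noise(params, experiment_id, ny, g)

    time, time_units = _time_axis(params, years)
    coords = {
        "time": time,
        "lev": ("lev", g.depth_centers, {"units": "m", "positive": "down"}),
        "lat": ("lat", g.lat, {"units": "degrees_north"}),
        "lon": ("lon", g.lon, {"units": "degrees_east"}),
    }

    season_t = _seasonal_theta(g)  # (12, nz, nlat)
    season_e = _seasonal_export(g)  # (12, nlat)
    spy = seconds_per_year(params.calendar)

    theta = np.empty((ny * 12, nz, nlat, nlon))
    so = np.empty_like(theta)
    expc = np.empty_like(theta)
    o2 = np.empty_like(theta)
    so_clim = np.broadcast_to(state.so0[:, :, None], (nz, nlat, nlon))

    for iy in range(ny):
        th_y = state.theta_year(iy)[:, :, None] + eta[iy] * state.warm_shape[:, None, None]
        ep_y = state.ep_cells(iy) * mult[iy]
        aou_y = state.aou_year(iy, ep_cells=ep_y)
        flux_y = state.expc_profile(iy, ep_cells=ep_y) / spy  # mol m-2 s-1
        sl = slice(iy * 12, (iy + 1) * 12)
        theta[sl] = th_y[None] + season_t[:, :, :, None]
        so[sl] = so_clim[None]
        expc[sl] = flux_y[None] * (1.0 + season_e[:, None, :, None])
        sat = oxygen_saturation(theta[sl], so[sl]) * 1.0e-6 * RHO0  # mol m-3
        o2[sl] = sat - aou_y[None]

    land3 = g.land_mask[None, None, :, :]
    for arr in (theta, so, expc, o2):
        np.copyto(arr, np.nan, where=np.broadcast_to(land3, arr.shape))

    attrs = {
        "source_id": model_name,
        "experiment_id": experiment_id,
        "calendar": params.calendar,
    }
    if experiment_id != "piControl":
        days = (params.branch_year - params.control_start_year) * 360.0
        attrs.update(
            branch_time_in_parent=days,
            parent_time_units=f"days since {params.control_start_year}-01-01",
            parent_experiment_id="piControl",
        )

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    var_units = {
        "thetao": ("degC", theta),
        "so": ("0.001", so),
        "expc": ("mol m-2 s-1", expc),
        "o2": ("mol m-3", o2),
    }
    for var, (units, arr) in var_units.items():
        da = xr.DataArray(arr, dims=("time", "lev", "lat", "lon"), coords=coords, name=var)
        path = os.path.join(outdir, f"{var}_{model_name}_{experiment_id}.nc")
        write_cmip_variable(
            Field(var, da, units),
            path,
            attrs=attrs,
            depth_bounds=g.depth_bounds,
            time_units=time_units,
            calendar=params.calendar,
        )
        paths[var] = path

    area_path = os.path.join(outdir, f"areacello_{model_name}.nc")
    vol_path = os.path.join(outdir, f"volcello_{model_name}.nc")
    if not os.path.exists(area_path):
        area_da = xr.DataArray(
            g.cell_area,
            dims=("lat", "lon"),
            coords={k: coords[k] for k in ("lat", "lon")},
            name="areacello",
        )
        write_cmip_variable(Field("areacello", area_da, "m2"), area_path, attrs={"source_id": model_name})
        vol = np.where(g.cell_volume > 0, g.cell_volume, np.nan)
        vol_da = xr.DataArray(
            vol,
            dims=("lev", "lat", "lon"),
            coords={k: coords[k] for k in ("lev", "lat", "lon")},
            name="volcello",
        )
        write_cmip_variable(
            Field("volcello", vol_da, "m3"),
            vol_path,
            attrs={"source_id": model_name},
            depth_bounds=g.depth_bounds,
        )
    paths["areacello"] = area_path
    paths["volcello"] = vol_path
    return paths


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Noise-free annual metric trajectories implied by the construction."""

    experiment_id: str
    years: np.ndarray
    csoft: np.ndarray  # Pg C
    ep100: np.ndarray  # Pg C y-1
    f1000: np.ndarray  # Pg C y-1
    te: np.ndarray  # percent
    strat: np.ndarray  # kg m-3
    noise_sd: dict[str, float]  # 1-sigma of injected noise per metric


def ground_truth(params: GeneratorParams, experiment_id: str = "piControl") -> GroundTruth:
    """Expected annual diagnostics of a generated run, without noise.

    Uses the same discrete bookkeeping as the construction (grid levels,
    monthly seasonal cycle, linear depth interpolation), so a pipeline run
    on the generated files differs from these trajectories only through
    the injected noise.  ``noise_sd`` gives the 1-sigma effect of that
    noise on each global metric (linear propagation of the per-cell
    lognormal export multipliers; numerical derivative for the
    temperature scalar), for tolerance checks.
    """
    state = _State(params, experiment_id)
    g = state.grid
    years = state.drivers["years"]
    ny = years.size
    area = g.ocean_area
    vol = g.cell_volume

    csoft = np.empty(ny)
    ep100 = np.empty(ny)
    f1000 = np.empty(ny)
    strat = np.empty(ny)
    season_t = _seasonal_theta(g)
    z = g.depth_centers
    k1000 = int(np.argmin(np.abs(z - DEEP_FLUX_DEPTH)))
    k200 = int(np.argmin(np.abs(z - STRAT_DEPTH)))

    for iy in range(ny):
        aou = state.aou_year(iy)
        csoft[iy] = np.nansum(np.nan_to_num(aou) * vol) * R_C_O * M_C / G_PER_PG
        flux = state.expc_profile(iy)  # mol m-2 y-1
        ep100[iy] = np.nansum(np.nan_to_num(flux[_level(z, EXPORT_DEPTH)]) * area) * M_C / G_PER_PG
        f1000[iy] = np.nansum(np.nan_to_num(flux[k1000]) * area) * M_C / G_PER_PG
        # stratification via the same monthly sigma bookkeeping as the pipeline
        th = state.theta_year(iy)[None, :, :] + season_t  # (12, nz, nlat)
        sig = potential_density(th, state.so0[None, :, :]).mean(axis=0)  # annual mean
        diff = sig[k200] - sig[0]  # (nlat,)
        w = area.sum(axis=1)
        strat[iy] = float(np.sum(diff * w) / np.sum(w))
    te = 100.0 * f1000 / ep100

    noise_sd = _noise_propagation(state)
    return GroundTruth(
        experiment_id=experiment_id,
        years=years,
        csoft=csoft,
        ep100=ep100,
        f1000=f1000,
        te=te,
        strat=strat,
        noise_sd=noise_sd,
    )


def _level(z: np.ndarray, target: float) -> int:
    k = int(np.argmin(np.abs(z - target)))
    if not np.isclose(z[k], target):
        raise ValueError(f"grid has no exact level at {target} m")
    return k


def _noise_propagation(state: _State) -> dict[str, float]:
    """1-sigma effect of the injected noise on each global annual metric."""
    p = state.params
    g = state.grid
    area = g.ocean_area
    sd = p.ep_cell_noise_sd
    ep = state.ep_cells(0)  # mol m-2 y-1
    b = np.where(state.ocean, state.b_cells(0), 0.0)
    a_i = np.where(state.ocean, ep * area, 0.0) * M_C / G_PER_PG  # Pg per cell
    ratio = (DEEP_FLUX_DEPTH / EXPORT_DEPTH) ** (-b)
    EP = float(a_i.sum())
    F = float((a_i * ratio).sum())
    te = 100.0 * F / EP
    sd_ep = sd * float(np.sqrt((a_i**2).sum()))
    sd_f = sd * float(np.sqrt(((a_i * ratio) ** 2).sum()))
    # delta method for the ratio TE = 100 F / EP
    dte_i = 100.0 / EP * a_i * (ratio - F / EP)
    sd_te = sd * float(np.sqrt((dte_i**2).sum()))
    # csoft: per-cell column conversion factor (Pg C per unit multiplier)
    aou = np.nan_to_num(state.aou_year(0))
    col = (aou * g.cell_volume).sum(axis=0) * R_C_O * M_C / G_PER_PG
    sd_cs = sd * float(np.sqrt((col**2).sum()))
    # strat: numerical derivative wrt the annual theta scalar
    tsd = p.theta_noise_sd_degc
    if tsd > 0:
        season_t = _seasonal_theta(g)
        z = g.depth_centers
        k200 = _level(z, STRAT_DEPTH)
        w = area.sum(axis=1)

        def _strat(eps: float) -> float:
            th = state.theta_year(0)[None] + season_t + eps * state.warm_shape[None, :, None]
            sig = potential_density(th, state.so0[None, :, :]).mean(axis=0)
            d = sig[k200] - sig[0]
            return float(np.sum(d * w) / np.sum(w))

        h = 0.01
        sd_strat = tsd * abs(_strat(h) - _strat(-h)) / (2 * h)
    else:
        sd_strat = 0.0
    return {"ep100": sd_ep, "f1000": sd_f, "te": sd_te, "csoft": sd_cs, "strat": sd_strat}


# ---------------------------------------------------------------------------
# ensemble convenience


def generate_ensemble(
    params: GeneratorParams,
    outdir: str | os.PathLike,
    n_models: int = 2,
    experiments: Iterable[str] = ("piControl", "ssp370"),
) -> dict:
    """Write a small multi-model ensemble and return a pipeline config dict.

    Model variants differ in baseline export, attenuation pattern and
    seed, emulating the structural spread of a real ensemble.  The
    returned mapping is the ``models:`` section understood by
    :class:`biopump.pipeline.PipelineConfig` (dump it to YAML for the
    command-line interface).
    """
    models = {}
    for i in range(n_models):
        name = f"SYNTH-{chr(65 + i)}"
        p = replace(
            params,
            seed=params.seed + i,
            ep0_pg=params.ep0_pg * (1.0 + 0.15 * i),
            b_base=params.b_base + 0.12 * ((i % 3) - 1),
        )
        mdir = os.path.join(os.fspath(outdir), name)
        exp_spec: dict[str, dict[str, str]] = {}
        area = vol = None
        for exp in experiments:
            paths = simulate_run(p, exp, mdir, model_name=name)
            area, vol = paths["areacello"], paths["volcello"]
            exp_spec[exp] = {v: paths[v] for v in ("o2", "expc", "thetao", "so")}
        models[name] = {
            "areacello": area,
            "volcello": vol,
            "experiments": exp_spec,
        }
    return {"models": models}
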