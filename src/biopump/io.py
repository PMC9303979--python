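"""CF-netCDF input/output for CMIP6-style variables and cell measures.

Files are read and written through xarray.  Depth is normalised at this
boundary to the interior convention (metres, positive down, increasing);
coordinate order is normalised to (time, lev, lat, lon); the file's fill
value becomes NaN.  Writing uses the scipy netCDF backend (NETCDF3
classic), which every CF-aware tool reads.
"""

from __future__ import annotations

import io as _io
import os
from collections.abc import Iterable

import cftime
import numpy as np
import pandas as pd
import xarray as xr

from .grids import CANONICAL_DIMS, Field, GridError, OceanGrid

__all__ = [
    "LoadError",
    "read_cmip_variable",
    "read_cell_measures",
    "read_branch_year",
    "write_cmip_variable",
    "write_timeseries_table",
    "TABLE_COLUMNS",
]

#: Column layout of the metric tables written by the pipeline.
TABLE_COLUMNS = [
    "model",
    "experiment",
    "year",
    "csoft_PgC",
    "ep100_PgCyr",
    "f1000_PgCyr",
    "te_percent",
    "strat_kgm3",
]

_DIM_ALIASES = {
    "time": "time",
    "lev": "lev",
    "olevel": "lev",
    "depth": "lev",
    "deptht": "lev",
    "lat": "lat",
    "latitude": "lat",
    "nav_lat": "lat",
    "lon": "lon",
    "longitude": "lon",
    "nav_lon": "lon",
}


class LoadError(IOError):
    """A required variable or attribute is missing from an input file."""


def _open(path: str | os.PathLike) -> xr.Dataset:
    if not os.path.exists(path):
        raise LoadError(f"input file not found: {path}")
    coder = xr.coders.CFDatetimeCoder(use_cftime=True)
    return xr.open_dataset(path, engine="scipy", decode_times=coder)


def _normalize(da: xr.DataArray) -> xr.DataArray:
    """Rename dims to canonical names, order (time, lev, lat, lon), depth down."""
    ren = {d: _DIM_ALIASES[d] for d in da.dims if d in _DIM_ALIASES and d != _DIM_ALIASES[d]}
    if ren:
        da = da.rename(ren)
    unknown = [d for d in da.dims if d not in CANONICAL_DIMS]
    if unknown:
        raise LoadError(f"unrecognised dimensions {unknown} on {da.name!r}")
    if "lev" in da.dims:
        lev = da["lev"]
        positive = str(lev.attrs.get("positive", "")).lower()
        vals = np.asarray(lev.values, dtype=float)
        if positive == "up" or (positive == "" and np.nanmean(vals) < 0):
            da = da.assign_coords(lev=-vals)
        if da["lev"].values[0] > da["lev"].values[-1]:
            da = da.isel(lev=slice(None, None, -1))
        da["lev"].attrs["positive"] = "down"
        da["lev"].attrs.setdefault("units", "m")
    order = [d for d in CANONICAL_DIMS if d in da.dims]
    return da.transpose(*order)


def read_cmip_variable(path: str | os.PathLike, var_name: str) -> Field:
    """Read one CMIP6 variable from a CF netCDF file as a :class:`Field`.

    The returned field has canonical dimension order, depth in metres
    positive down regardless of the stored orientation, and NaN for
    missing cells.  Raises :class:`LoadError` if the variable or its
    ``units`` attribute is absent.
    """
    ds = _open(path)
    if var_name not in ds:
        raise LoadError(f"variable {var_name!r} not found in {path}")
    da = ds[var_name]
    units = da.attrs.get("units")
    if not units:
        raise LoadError(f"variable {var_name!r} in {path} lacks a units attribute")
    da = _normalize(da.astype(float)).load()
    ds.close()
    return Field(var_name, da, units)


def read_branch_year(path: str | os.PathLike) -> int | None:
    """Branch year in the parent (control) run, from global attributes.

    Uses ``branch_time_in_parent`` with ``parent_time_units`` (and the
    parent calendar if recorded); sub-annual branch times are rounded to
    the nearest calendar year.  Returns None when no branch metadata is
    present (e.g. a control run).
    """
    ds = _open(path)
    try:
        bt = ds.attrs.get("branch_time_in_parent")
        tu = ds.attrs.get("parent_time_units")
        if bt is None or tu is None:
            return None
        cal = ds.attrs.get("parent_activity_calendar") or ds.attrs.get("calendar", "360_day")
        date = cftime.num2date(float(bt), tu, calendar=cal)
        # round to nearest year boundary
        return int(date.year + (1 if date.month > 6 else 0))
    finally:
        ds.close()


def read_cell_measures(
    area_path: str | os.PathLike,
    volume_path: str | os.PathLike | None = None,
    reference: Field | None = None,
) -> OceanGrid:
    """Build an :class:`OceanGrid` from ``areacello`` (and ``volcello``).

    When ``volume_path`` is None, cell volumes are reconstructed as
    area x layer thickness using the depth bounds of ``reference`` (a 3-D
    field whose ``lev`` coordinate carries bounds) — columns are then
    full-depth wherever the reference field has data.  The land mask is
    taken from missing/zero cells of the measures.
    """
    ds = _open(area_path)
    if "areacello" not in ds:
        raise LoadError(f"areacello not found in {area_path}")
    area = _normalize(ds["areacello"].astype(float)).load()
    lat = np.asarray(area["lat"].values, dtype=float)
    lon = np.asarray(area["lon"].values, dtype=float)
    ds.close()

    if volume_path is not None:
        dsv = _open(volume_path)
        if "volcello" not in dsv:
            raise LoadError(f"volcello not found in {volume_path}")
        volda = _normalize(dsv["volcello"].astype(float)).load()
        if volda.shape[-2:] != area.shape:
            dsv.close()
            raise GridError(
                f"volcello horizontal shape {volda.shape[-2:]} does not match "
                f"areacello {area.shape}"
            )
        lev = np.asarray(volda["lev"].values, dtype=float)
        bounds = _bounds_from(dsv, volda)
        dsv.close()
        volume = np.nan_to_num(volda.values)
    else:
        if reference is None or "lev" not in reference.data.dims:
            raise GridError("volcello absent: need a 3-D reference field with depth bounds")
        if reference.data.shape[-2:] != area.shape:
            raise GridError("reference field horizontal shape does not match areacello")
        lev = np.asarray(reference.data["lev"].values, dtype=float)
        bounds = _default_bounds(lev)
        dz = bounds[:, 1] - bounds[:, 0]
        ref3d = reference.data.isel(time=0) if "time" in reference.data.dims else reference.data
        wet = np.isfinite(ref3d.values)
        volume = np.where(wet, np.nan_to_num(area.values)[None, :, :] * dz[:, None, None], 0.0)

    mask = ~np.isfinite(area.values) | (np.nan_to_num(area.values) <= 0)
    volume = np.where(mask[None, :, :], 0.0, np.nan_to_num(volume))
    return OceanGrid(
        cell_area=area.values,
        depth_centers=lev,
        depth_bounds=bounds,
        cell_volume=volume,
        land_mask=mask,
        lat=lat,
        lon=lon,
    )


def _bounds_from(ds: xr.Dataset, da: xr.DataArray) -> np.ndarray:
    name = da["lev"].attrs.get("bounds", "lev_bnds")
    if name in ds:
        b = np.sort(np.abs(np.asarray(ds[name].values, dtype=float)), axis=1)
        if b.shape[0] != da["lev"].size:  # stored for the pre-flip orientation
            b = b[::-1]
        order = np.argsort(b[:, 0])
        return b[order]
    return _default_bounds(np.asarray(da["lev"].values, dtype=float))


def _default_bounds(lev: np.ndarray) -> np.ndarray:
    mid = 0.5 * (lev[1:] + lev[:-1])
    upper = np.concatenate([[0.0], mid])
    lower = np.concatenate([mid, [lev[-1] + (lev[-1] - mid[-1])]])
    return np.column_stack([upper, lower])


def write_cmip_variable(
    field: Field,
    path: str | os.PathLike,
    attrs: dict | None = None,
    depth_bounds: np.ndarray | None = None,
    time_units: str = "days since 1850-01-01",
    calendar: str = "360_day",
) -> None:
    """Write a :class:`Field` as a CF netCDF (NETCDF3) file.

    Depth is stored positive down with a ``lev_bnds`` variable when bounds
    are given.  Output is deterministic: no timestamps or history attributes
    are written, so identical inputs give byte-identical files.
    """
    da = field.data.copy()
    da.attrs["units"] = field.units
    ds = da.to_dataset(name=field.name)
    if depth_bounds is not None and "lev" in da.dims:
        ds["lev_bnds"] = (("lev", "bnds"), np.asarray(depth_bounds, dtype=float))
        ds["lev"].attrs["bounds"] = "lev_bnds"
    enc = {}
    if "time" in da.dims:
        enc["time"] = {"units": time_units, "calendar": calendar}
    ds.attrs.update(attrs or {})
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def write_timeseries_table(series: Iterable, path: str | os.PathLike) -> None:
    """Write a collection of annual metric series as one CSV table.

    ``series`` is an iterable of objects exposing ``to_frame()`` (see
    :class:`biopump.diagnostics.BCPTimeSeries`).  One row per
    (model, experiment, year); duplicate keys raise ``ValueError``.
    Rewriting identical inputs yields byte-identical files.
    """
    frames = [s.to_frame() for s in series]
    if frames:
        df = pd.concat(frames, ignore_index=True)
        df = df[TABLE_COLUMNS]
        dup = df.duplicated(subset=["model", "experiment", "year"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["model", "experiment", "year"]].tolist()
            raise ValueError(f"duplicate (model, experiment, year) row: {key}")
        df = df.sort_values(["model", "experiment", "year"], kind="mergesort")
    else:
        df = pd.DataFrame(columns=TABLE_COLUMNS)
    buf = _io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n", float_format="%.10g")
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())
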