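"""Shared data model: ocean grid, physical fields, experiment runs.

All diagnostics in this package integrate over a fixed ocean grid.  The
grid carries the integration measure — horizontal cell areas (``areacello``),
cell volumes (``volcello`` or area x layer thickness) — together with the
depth axis and the land mask.  The interior convention is depth in metres,
positive down, increasing with index; array order (time, lev, lat, lon).
Masked (land / below-bathymetry) cells are NaN in fields and zero-volume in
the grid, so they contribute nothing to integrals.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np
import xarray as xr

__all__ = ["OceanGrid", "Field", "ExperimentRun", "GridError", "CANONICAL_DIMS"]

CANONICAL_DIMS = ("time", "lev", "lat", "lon")


class GridError(ValueError):
    """Inconsistent grid definition or grid/field shape mismatch."""


@dataclass
class OceanGrid:
    """Grid-cell measures and mask for global integrals.

    Attributes
    ----------
    cell_area : (nlat, nlon) ndarray
        Horizontal cell area, m^2.  NaN or 0 over land.
    depth_centers : (nz,) ndarray
        Layer mid-depths, m, positive down, strictly increasing.
    depth_bounds : (nz, 2) ndarray
        Upper/lower layer interfaces, m.
    cell_volume : (nz, nlat, nlon) ndarray
        Ocean volume per cell, m^3; zero for masked cells.
    land_mask : (nlat, nlon) bool ndarray
        True where the column is land (excluded from area weights).
    lat, lon : (nlat,), (nlon,) ndarray
        Coordinate values (degrees), used for CF round-trips.
    """

    cell_area: np.ndarray
    depth_centers: np.ndarray
    depth_bounds: np.ndarray
    cell_volume: np.ndarray
    land_mask: np.ndarray
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.cell_area = np.asarray(self.cell_area, dtype=float)
        self.depth_centers = np.asarray(self.depth_centers, dtype=float)
        self.depth_bounds = np.asarray(self.depth_bounds, dtype=float)
        self.cell_volume = np.asarray(self.cell_volume, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        nz = self.depth_centers.size
        if self.cell_volume.shape != (nz,) + self.cell_area.shape:
            raise GridError(
                f"cell_volume shape {self.cell_volume.shape} inconsistent with "
                f"{nz} levels and area shape {self.cell_area.shape}"
            )
        if self.land_mask.shape != self.cell_area.shape:
            raise GridError("land_mask / cell_area shape mismatch")
        if nz > 1 and not np.all(np.diff(self.depth_centers) > 0):
            raise GridError("depth_centers must be strictly increasing (positive down)")
        if not np.all(
            (self.depth_bounds[:, 0] <= self.depth_centers)
            & (self.depth_centers <= self.depth_bounds[:, 1])
        ):
            raise GridError("depth_centers must lie within depth_bounds")
        vol = self.cell_volume
        if np.any(vol[np.isfinite(vol)] < 0):
            raise GridError("negative cell volumes")
        # land columns must carry zero volume
        if np.any(np.nan_to_num(vol[:, self.land_mask]) != 0.0):
            raise GridError("masked columns must have zero volume")

    @property
    def nz(self) -> int:
        return self.depth_centers.size

    @property
    def layer_thickness(self) -> np.ndarray:
        """Layer thickness dz per level, m."""
        return self.depth_bounds[:, 1] - self.depth_bounds[:, 0]

    @property
    def total_volume(self) -> float:
        """Total ocean volume V_tot, m^3 (masked cells excluded)."""
        return float(np.nansum(self.cell_volume))

    @property
    def ocean_area(self) -> np.ndarray:
        """Cell area with land zeroed, m^2."""
        area = np.where(self.land_mask, 0.0, np.nan_to_num(self.cell_area))
        return area


@dataclass
class Field:
    """A physical variable on the common grid with explicit units.

    ``data`` is an :class:`xarray.DataArray` whose dims are an ordered
    subset of ``(time, lev, lat, lon)`` with ``lev`` in metres positive
    down.  Missing cells are NaN.
    """

    name: str
    data: xr.DataArray
    units: str

    def __post_init__(self) -> None:
        extra = [d for d in self.data.dims if d not in CANONICAL_DIMS]
        if extra:
            raise ValueError(f"non-canonical dims {extra} on field {self.name!r}")
        order = [d for d in CANONICAL_DIMS if d in self.data.dims]
        if tuple(self.data.dims) != tuple(order):
            self.data = self.data.transpose(*order)
        if not self.units:
            raise ValueError(f"field {self.name!r} has empty units")

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    @property
    def dims(self) -> tuple:
        return self.data.dims

    def sel_time(self, index: int) -> "Field":
        """Field at one time index (time dimension dropped)."""
        return Field(self.name, self.data.isel(time=index), self.units)

    def check_grid(self, grid: OceanGrid) -> None:
        """Raise :class:`GridError` if the field does not fit ``grid``."""
        sizes = self.data.sizes
        if sizes.get("lat", grid.cell_area.shape[0]) != grid.cell_area.shape[0] or (
            sizes.get("lon", grid.cell_area.shape[1]) != grid.cell_area.shape[1]
        ):
            raise GridError(
                f"field {self.name!r} horizontal shape does not match grid"
            )
        if "lev" in sizes and sizes["lev"] != grid.nz:
            raise GridError(f"field {self.name!r} has {sizes['lev']} levels, grid {grid.nz}")


@dataclass
class ExperimentRun:
    """A (model, experiment) bundle of fields sharing one grid and time axis."""

    model_name: str
    experiment_id: str
    calendar: str
    fields: dict[str, Field]
    branch_year: int | None = None
    attrs: dict[str, Any] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment_id != "piControl" and self.branch_year is None:
            raise ValueError(
                f"non-control experiment {self.experiment_id!r} requires a branch_year"
            )
        times = {
            f.data.sizes["time"] for f in self.fields.values() if "time" in f.data.dims
        }
        if len(times) > 1:
            raise ValueError(f"fields of {self.experiment_id!r} disagree on time length")

    def __getitem__(self, name: str) -> Field:
        return self.fields[name]

    def __contains__(self, name: str) -> bool:
        return name in self.fields
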