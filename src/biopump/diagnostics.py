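"""Biological-carbon-pump state metrics from gridded ocean fields.

The metrics quantify the three legs of the soft-tissue pump:

* **AOU** — apparent oxygen utilization, ``O2_sat(T, S) - O2``, the
  cumulative respiration signal of a water parcel (mol m-3);
* **C_soft** — carbon sequestered by the pump, the volume integral of AOU
  converted to carbon with the stoichiometric ratio R_C:O = 117:170 and the
  molar mass of carbon, reported in Pg C;
* **EP100 / F1000** — globally integrated downward POC flux at 100 m
  (export production) and 1000 m (Pg C y-1), extracted from the 3-D
  ``expc`` field by linear interpolation in depth;
* **TE** — transfer efficiency, the percentage of the 100 m export that
  reaches 1000 m, globally or per column;
* **stratification index** — area-weighted global mean of
  sigma0(200 m) - sigma0(surface), kg m-3.

Sign convention: AOU is positive where oxygen is depleted (saturation
minus observed), so C_soft is positive for a respiring interior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grids import Field, GridError, OceanGrid
from .io import TABLE_COLUMNS
from .seawater import RHO0, oxygen_saturation

__all__ = [
    "R_C_O",
    "M_C",
    "G_PER_PG",
    "seconds_per_year",
    "compute_aou",
    "compute_csoft",
    "interpolate_flux_to_depth",
    "integrate_flux",
    "transfer_efficiency",
    "transfer_efficiency_map",
    "stratification_index",
    "TransferEfficiencyMap",
    "BCPTimeSeries",
    "UnitError",
]

#: Stoichiometric mol C produced per mol O2 consumed during remineralization.
R_C_O = 117.0 / 170.0
#: Molar mass of carbon, g mol-1.
M_C = 12.01
#: Grams per petagram.
G_PER_PG = 1.0e15

_CAL_DAYS = {
    "360_day": 360.0,
    "noleap": 365.0,
    "365_day": 365.0,
    "all_leap": 366.0,
    "366_day": 366.0,
    "standard": 365.25,
    "gregorian": 365.25,
    "proleptic_gregorian": 365.25,
    "julian": 365.25,
}


class UnitError(ValueError):
    """A field's units are not the ones the diagnostic requires."""


def seconds_per_year(calendar: str) -> float:
    """Length of the model year in seconds for a CF calendar."""
    try:
        return _CAL_DAYS[calendar] * 86400.0
    except KeyError:
        raise ValueError(f"unknown calendar {calendar!r}") from None


def _canon_unit(u: str) -> str:
    return (
        u.replace("**", "")
        .replace("^", "")
        .replace(" ", "")
        .replace("-", "")
        .replace("/", "")
        .lower()
    )


def _require_units(field: Field, accepted: tuple[str, ...], what: str) -> None:
    if _canon_unit(field.units) not in {_canon_unit(a) for a in accepted}:
        raise UnitError(
            f"{what}: field {field.name!r} has units {field.units!r}, "
            f"expected one of {accepted}"
        )


def compute_aou(
    o2: Field,
    thetao: Field,
    so: Field,
    rho0: float = RHO0,
    fit: str = "benson_krause",
) -> Field:
    """Apparent oxygen utilization, mol m-3.

    ``AOU = O2_sat(thetao, so) - o2`` elementwise; positive where oxygen
    has been consumed.  The gravimetric solubility (umol kg-1) is converted
    to mol m-3 with the fixed reference density ``rho0``.  Masked cells in
    any input propagate.
    """
    _require_units(o2, ("mol m-3", "mol/m3"), "compute_aou")
    _require_units(thetao, ("degC", "deg_C", "celsius"), "compute_aou")
    _require_units(so, ("0.001", "psu", "1e-3", "g/kg", "g kg-1"), "compute_aou")
    sat_umol_kg = oxygen_saturation(thetao.values, so.values, fit=fit)
    sat = sat_umol_kg * 1.0e-6 * rho0  # -> mol m-3
    data = xr.DataArray(
        sat - o2.values, coords=o2.data.coords, dims=o2.data.dims, name="aou"
    )
    return Field("aou", data, "mol m-3")


def compute_csoft(aou: Field, grid: OceanGrid, per_volume: bool = False):
    """Carbon sequestered by the soft-tissue pump.

    ``C_soft = sum_cells AOU * R_C:O * m_C * dV`` in Pg C (the total
    inventory).  With ``per_volume=True`` the integral is divided by the
    total ocean volume, giving the mean concentration in g C m-3 instead.
    Returns a scalar, or a 1-D array over time if ``aou`` has a time axis.
    """
    _require_units(aou, ("mol m-3", "mol/m3"), "compute_csoft")
    aou.check_grid(grid)
    vol = grid.cell_volume
    if vol.size == 0:
        raise GridError("grid has no cell volumes")
    vals = np.nan_to_num(aou.values)  # masked cells contribute zero
    grams = np.tensordot(vals, vol, axes=([-3, -2, -1], [0, 1, 2])) * R_C_O * M_C
    if per_volume:
        vtot = grid.total_volume
        if vtot <= 0:
            raise GridError("total ocean volume is zero")
        out = grams / vtot
    else:
        out = grams / G_PER_PG
    return float(out) if np.ndim(out) == 0 else out


def interpolate_flux_to_depth(field: Field, z_target: float) -> Field:
    """Extract a 3-D field at one depth, linearly interpolating if needed.

    If a model level coincides with ``z_target`` its values are returned
    exactly; otherwise values are linearly interpolated in depth between
    the bracketing levels.  Columns whose deepest valid level is shallower
    than ``z_target`` (including below-bathymetry NaNs at the bracketing
    level) come back masked.
    """
    if z_target <= 0:
        raise ValueError(f"z_target must be positive, got {z_target}")
    if "lev" not in field.data.dims:
        raise ValueError(f"field {field.name!r} has no depth axis")
    lev = np.asarray(field.data["lev"].values, dtype=float)
    vals = field.data.transpose(..., "lev", "lat", "lon").values
    ax = vals.ndim - 3  # lev axis
    exact = np.isclose(lev, z_target, rtol=1e-12, atol=1e-9)
    if exact.any():
        out = np.take(vals, int(np.argmax(exact)), axis=ax)
    else:
        k = int(np.searchsorted(lev, z_target))
        if k == 0 or k == lev.size:
            shape = vals.shape[:ax] + vals.shape[ax + 1 :]
            out = np.full(shape, np.nan)
        else:
            lo = np.take(vals, k - 1, axis=ax)
            hi = np.take(vals, k, axis=ax)
            w = (z_target - lev[k - 1]) / (lev[k] - lev[k - 1])
            out = (1.0 - w) * lo + w * hi  # NaN if either bracket is NaN
    dims = tuple(d for d in field.data.dims if d != "lev")
    coords = {d: field.data.coords[d] for d in dims if d in field.data.coords}
    da = xr.DataArray(out, dims=dims, coords=coords, name=field.name)
    return Field(field.name, da, field.units)


def integrate_flux(flux2d: Field, grid: OceanGrid, calendar: str):
    """Globally integrated POC flux, Pg C y-1.

    ``sum_cells flux * area * seconds_per_year(calendar) * m_C / 1e15``;
    masked cells contribute zero.  ``flux2d`` must be in mol m-2 s-1 (the
    CMIP6 ``expc`` unit).  Returns a scalar, or an array over time.
    """
    _require_units(flux2d, ("mol m-2 s-1", "mol/m2/s"), "integrate_flux")
    flux2d.check_grid(grid)
    area = grid.ocean_area
    vals = np.nan_to_num(flux2d.values)
    mol_per_s = np.tensordot(vals, area, axes=([-2, -1], [0, 1]))
    out = mol_per_s * seconds_per_year(calendar) * M_C / G_PER_PG
    return float(out) if np.ndim(out) == 0 else out


def transfer_efficiency(ep100, f1000):
    """Global transfer efficiency, percent: 100 * F(1000 m) / EP(100 m)."""
    ep = np.asarray(ep100, dtype=float)
    if np.any(ep <= 0):
        raise ValueError("transfer efficiency undefined for export production <= 0")
    out = 100.0 * np.asarray(f1000, dtype=float) / ep
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class TransferEfficiencyMap:
    """Per-column transfer efficiency (%), masked where export is negligible."""

    values: xr.DataArray  # (lat, lon), percent, NaN where invalid
    validity_mask: np.ndarray  # bool (lat, lon)
    floor: float


def transfer_efficiency_map(
    f100: Field, f1000: Field, floor: float = 1.0e-12
) -> TransferEfficiencyMap:
    """Map of 100 * f1000 / f100 where ``f100 > floor``; elsewhere masked.

    The floor (mol m-2 s-1) avoids ratio blow-ups where export is
    effectively zero.
    """
    if f100.data.shape != f1000.data.shape:
        raise GridError(
            f"transfer_efficiency_map: shapes differ {f100.data.shape} vs {f1000.data.shape}"
        )
    a = f100.values
    b = f1000.values
    with np.errstate(invalid="ignore"):
        valid = np.isfinite(a) & np.isfinite(b) & (a > floor)
        vals = np.where(valid, 100.0 * b / np.where(valid, a, 1.0), np.nan)
    da = xr.DataArray(vals, dims=f100.data.dims, coords=f100.data.coords, name="te")
    return TransferEfficiencyMap(values=da, validity_mask=valid, floor=floor)


def stratification_index(sigma0: Field, grid: OceanGrid, z_ref: float = 200.0):
    """Area-weighted global mean of sigma0(z_ref) - sigma0(surface), kg m-3.

    The surface value is the top model level; the value at ``z_ref``
    (default 200 m) uses the same linear depth interpolation as the flux
    extraction.  Columns shallower than ``z_ref`` are excluded from the
    area weights.  Returns a scalar, or an array over time.
    """
    lev = np.asarray(sigma0.data["lev"].values, dtype=float)
    if lev[-1] < z_ref and not np.isclose(lev[-1], z_ref):
        raise ValueError(f"no level at or below {z_ref} m anywhere in the field")
    sigma0.check_grid(grid)
    surf = sigma0.data.isel(lev=0).values
    deep = interpolate_flux_to_depth(sigma0, z_ref).values
    diff = deep - surf
    area = grid.ocean_area
    w = np.where(np.isfinite(diff), area, 0.0)
    wsum = w.sum(axis=(-2, -1))
    out = np.where(
        wsum > 0, np.nansum(np.nan_to_num(diff) * w, axis=(-2, -1)) / np.where(wsum > 0, wsum, 1.0), np.nan
    )
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class BCPTimeSeries:
    """Annual global BCP metrics for one (model, experiment)."""

    model_name: str
    experiment_id: str
    years: np.ndarray  # calendar years, strictly increasing
    csoft: np.ndarray  # Pg C
    ep100: np.ndarray  # Pg C y-1
    f1000: np.ndarray  # Pg C y-1
    te: np.ndarray  # percent
    strat: np.ndarray  # kg m-3

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        for attr in ("csoft", "ep100", "f1000", "te", "strat"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
            if getattr(self, attr).shape != self.years.shape:
                raise ValueError(f"{attr} length does not match years")
        if self.years.size > 1 and not np.all(np.diff(self.years) > 0):
            raise ValueError("years must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_name,
                "experiment": self.experiment_id,
                "year": self.years,
                "csoft_PgC": self.csoft,
                "ep100_PgCyr": self.ep100,
                "f1000_PgCyr": self.f1000,
                "te_percent": self.te,
                "strat_kgm3": self.strat,
            },
            columns=TABLE_COLUMNS,
        )
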