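"""Temporal processing of model output and derived metrics.

Covers the bookkeeping between raw monthly model output and the anomaly
series that carry the climate signal: calendar-aware annual averaging,
alignment of a scenario run with its parent control at the branch point,
subtraction of the control ("drift removal"), and moving-average
smoothing.  Drift removal subtracts the control's actual values over the
equivalent segment, not a fitted trend, so any drift shape shared by the
two runs cancels exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import xarray as xr

from .grids import Field

__all__ = ["AnnualSeries", "AlignmentError", "annual_mean", "remove_drift", "moving_average"]


class AlignmentError(ValueError):
    """Scenario and control share no overlap from the branch point."""


@dataclass
class AnnualSeries:
    """One annual metric trajectory with provenance."""

    years: np.ndarray
    values: np.ndarray
    units: str
    experiment_id: str = ""
    model_name: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must have the same length")
        if self.years.size > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be contiguous and increasing")


def annual_mean(field: Field, calendar: str | None = None) -> Field:
    """Time-weighted annual mean of a field with a sub-annual time axis.

    Months are weighted by their length in the run's calendar (equal for a
    360-day calendar, 28..31 d for realistic ones), so the mean is the true
    time average.  Years without full month coverage at the start or end
    are dropped with a warning.  The annual time coordinate becomes the
    integer calendar year.
    """
    da = field.data
    if "time" not in da.dims:
        raise ValueError(f"field {field.name!r} has no time axis")
    years = da["time"].dt.year
    weights = da["time"].dt.days_in_month.astype(float)
    cal = calendar or da["time"].dt.calendar
    expected = {
        "360_day": 360.0,
        "noleap": 365.0,
        "365_day": 365.0,
        "all_leap": 366.0,
        "366_day": 366.0,
    }.get(cal)

    wsum = weights.groupby(years.rename("year")).sum()
    if expected is not None:
        full = wsum >= expected - 0.5
    else:  # gregorian-family: require 12 months
        counts = xr.ones_like(weights).groupby(years.rename("year")).sum()
        full = counts >= 12
    if not bool(full.all()):
        dropped = wsum["year"].values[~full.values]
        warnings.warn(
            f"dropping partially covered year(s) {list(dropped)}",
            RuntimeWarning,
            stacklevel=2,
        )

    # skipna=False keeps land/masked cells NaN instead of silently zeroing them
    num = (da * weights).groupby(years.rename("year")).sum(dim="time", skipna=False)
    mean = (num / wsum).where(full, drop=False).sel(year=wsum["year"][full.values])
    mean = mean.rename(year="time")
    out = mean.assign_coords(time=mean["time"].astype(int))
    order = [d for d in ("time", "lev", "lat", "lon") if d in out.dims]
    return Field(field.name, out.transpose(*order), field.units)


def remove_drift(
    scenario: AnnualSeries, control: AnnualSeries, branch_year: int
) -> AnnualSeries:
    """Anomaly of a scenario relative to the equivalent control segment.

    Year ``i`` of the scenario is paired with control year
    ``branch_year + i``; the anomaly is the plain difference, so a drift
    present in both runs cancels exactly.  If the control ends before the
    scenario does, the output is truncated to the overlap with a warning.
    """
    if scenario.units != control.units:
        raise ValueError(
            f"unit mismatch: scenario {scenario.units!r} vs control {control.units!r}"
        )
    offset = branch_year - int(control.years[0])
    if offset < 0 or offset >= control.years.size:
        raise AlignmentError(
            f"branch year {branch_year} outside control span "
            f"{control.years[0]}..{control.years[-1]}"
        )
    n = min(scenario.years.size, control.years.size - offset)
    if n <= 0:
        raise AlignmentError("no overlap between scenario and aligned control")
    if n < scenario.years.size:
        warnings.warn(
            f"control ends {scenario.years.size - n} y before the scenario; "
            "anomaly truncated to the overlap",
            RuntimeWarning,
            stacklevel=2,
        )
    values = scenario.values[:n] - control.values[offset : offset + n]
    return replace(scenario, years=scenario.years[:n].copy(), values=values)


def moving_average(series: AnnualSeries, window: int = 10) -> AnnualSeries:
    """Centered moving average; edges use the available shorter window.

    ``min_periods = ceil(window / 2)`` keeps the series length unchanged
    while avoiding means over nearly empty windows.  ``window=1`` is the
    identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > series.years.size:
        raise ValueError(
            f"window {window} longer than series ({series.years.size} y)"
        )
    smoothed = (
        pd.Series(series.values)
        .rolling(window=window, center=True, min_periods=(window + 1) // 2)
        .mean()
        .to_numpy()
    )
    return replace(series, values=smoothed)
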