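"""End-to-end orchestration: files -> annual metrics -> anomalies -> tables.

The pipeline mirrors the processing chain applied to each ensemble
member: read the CMIP6-named variables and cell measures, form
calendar-weighted annual means, compute the pump metrics (C_soft, EP100,
F1000, TE, stratification index), subtract the branch-aligned control
segment from every scenario metric, smooth with a moving average, and
write CSV tables (plus optional transfer-efficiency maps as netCDF).
Models that fail a stage are excluded with a logged reason; the others
continue.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import xarray as xr
import yaml

from . import diagnostics as dg
from .grids import Field, OceanGrid
from .io import (
    read_branch_year,
    read_cell_measures,
    read_cmip_variable,
    write_timeseries_table,
)
from .seawater import RHO0, potential_density
from .timeseries import AnnualSeries, annual_mean, moving_average, remove_drift

logger = logging.getLogger("biopump")

__all__ = [
    "PipelineConfig",
    "ModelSpec",
    "ValidationReport",
    "validate_inputs",
    "run_pipeline",
    "PipelineResult",
    "ConfigError",
]

REQUIRED_VARS = ("o2", "expc", "thetao", "so")
METRICS = ("csoft", "ep100", "f1000", "te", "strat")
METRIC_UNITS = {
    "csoft": "Pg C",
    "ep100": "Pg C yr-1",
    "f1000": "Pg C yr-1",
    "te": "percent",
    "strat": "kg m-3",
}


class ConfigError(ValueError):
    """The pipeline configuration is unusable."""


@dataclass
class ModelSpec:
    """File layout for one model: measures plus per-experiment variables."""

    name: str
    areacello: str
    volcello: str | None
    experiments: dict[str, dict[str, str]]  # experiment -> var -> path
    branch_year: int | None = None  # override; else read from file metadata


@dataclass
class PipelineConfig:
    models: list[ModelSpec]
    outdir: str = "bcp_out"
    export_depth: float = 100.0
    deep_depth: float = 1000.0
    strat_depth: float = 200.0
    smoothing_window: int = 10
    te_floor: float = 1.0e-12
    rho0: float = RHO0
    o2_fit: str = "benson_krause"
    write_te_maps: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        depths = (self.export_depth, self.strat_depth, self.deep_depth)
        if any(d <= 0 for d in depths) or not (
            self.export_depth < self.strat_depth < self.deep_depth
        ):
            raise ConfigError(f"diagnostic depths must be positive and increasing: {depths}")
        if self.smoothing_window < 1:
            raise ConfigError("smoothing window must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "models" not in raw:
            raise ConfigError(f"config {path} must be a mapping with a 'models' section")
        models = []
        for name, spec in raw["models"].items():
            models.append(
                ModelSpec(
                    name=name,
                    areacello=spec["areacello"],
                    volcello=spec.get("volcello"),
                    experiments=spec["experiments"],
                    branch_year=spec.get("branch_year"),
                )
            )
        depths = raw.get("depths", {})
        return cls(
            models=models,
            outdir=raw.get("outdir", "bcp_out"),
            export_depth=float(depths.get("export", 100.0)),
            deep_depth=float(depths.get("deep", 1000.0)),
            strat_depth=float(depths.get("strat", 200.0)),
            smoothing_window=int(raw.get("smoothing_window", 10)),
            te_floor=float(raw.get("te_floor", 1.0e-12)),
            rho0=float(raw.get("rho0", RHO0)),
            o2_fit=raw.get("o2_fit", "benson_krause"),
            write_te_maps=bool(raw.get("write_te_maps", False)),
            log_level=raw.get("log_level", "INFO"),
        )


@dataclass
class ValidationReport:
    usable: list[str]
    excluded: dict[str, str]  # model -> reason
    checks: dict[str, dict[str, bool]]  # model -> check -> passed

    @property
    def ok(self) -> bool:
        return bool(self.usable)


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Check variable availability per model; exclude unusable models.

    A model needs both dissolved oxygen and the 3-D POC flux in every
    experiment (the ensemble-selection rule), a control experiment, at
    least one non-control experiment, and existing files.  Raises
    :class:`ConfigError` if no model survives.
    """
    usable, excluded, checks = [], {}, {}
    for m in config.models:
        c: dict[str, bool] = {}
        reason = None
        missing_paths = [p for p in _all_paths(m) if not os.path.exists(p)]
        c["paths_exist"] = not missing_paths
        if missing_paths:
            reason = f"missing file(s): {missing_paths[0]}"
        c["has_control"] = "piControl" in m.experiments
        if reason is None and not c["has_control"]:
            reason = "no piControl experiment"
        scen = [e for e in m.experiments if e != "piControl"]
        c["has_scenario"] = bool(scen)
        if reason is None and not scen:
            reason = "no scenario experiment"
        for var in REQUIRED_VARS:
            ok = all(var in spec for spec in m.experiments.values())
            c[f"has_{var}"] = ok
            if reason is None and not ok:
                reason = {
                    "o2": "no dissolved oxygen",
                    "expc": "no 3-D POC flux",
                }.get(var, f"missing variable {var}")
        if reason is None:
            usable.append(m.name)
        else:
            excluded[m.name] = reason
            logger.warning("model %s excluded: %s", m.name, reason)
        checks[m.name] = c
    if not usable:
        raise ConfigError(f"no usable models: {excluded}")
    return ValidationReport(usable=usable, excluded=excluded, checks=checks)


def _all_paths(m: ModelSpec):
    yield m.areacello
    if m.volcello:
        yield m.volcello
    for spec in m.experiments.values():
        yield from spec.values()


# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    series: dict[tuple[str, str], dg.BCPTimeSeries]  # (model, experiment) -> raw
    anomalies: dict[tuple[str, str], dg.BCPTimeSeries]
    smoothed: dict[tuple[str, str], dg.BCPTimeSeries]
    summary: "object"  # pandas DataFrame: control-mean metrics per model
    report: ValidationReport
    outputs: dict[str, str] = dc_field(default_factory=dict)


def _experiment_series(
    config: PipelineConfig, model: ModelSpec, experiment: str, grid: OceanGrid
) -> dg.BCPTimeSeries:
    """Annual BCP metrics for one (model, experiment) from its files."""
    spec = model.experiments[experiment]
    o2 = read_cmip_variable(spec["o2"], "o2")
    thetao = read_cmip_variable(spec["thetao"], "thetao")
    so = read_cmip_variable(spec["so"], "so")
    expc = read_cmip_variable(spec["expc"], "expc")
    calendar = o2.data["time"].dt.calendar

    # AOU and sigma0 at native (monthly) resolution, then annual means:
    # both are nonlinear in T and S, so averaging first would bias them.
    aou = dg.compute_aou(o2, thetao, so, rho0=config.rho0, fit=config.o2_fit)
    aou_annual = annual_mean(aou)
    csoft = dg.compute_csoft(aou_annual, grid)

    sigma = Field(
        "sigma0",
        xr.DataArray(
            potential_density(thetao.values, so.values),
            coords=thetao.data.coords,
            dims=thetao.data.dims,
        ),
        "kg m-3",
    )
    strat = dg.stratification_index(annual_mean(sigma), grid, z_ref=config.strat_depth)

    expc_annual = annual_mean(expc)
    f100 = dg.interpolate_flux_to_depth(expc_annual, config.export_depth)
    f1000 = dg.interpolate_flux_to_depth(expc_annual, config.deep_depth)
    ep100 = dg.integrate_flux(f100, grid, calendar)
    f1000_int = dg.integrate_flux(f1000, grid, calendar)
    te = dg.transfer_efficiency(ep100, f1000_int)

    years = np.asarray(expc_annual.data["time"].values, dtype=int)
    return dg.BCPTimeSeries(
        model_name=model.name,
        experiment_id=experiment,
        years=years,
        csoft=np.atleast_1d(csoft),
        ep100=np.atleast_1d(ep100),
        f1000=np.atleast_1d(f1000_int),
        te=np.atleast_1d(te),
        strat=np.atleast_1d(strat),
    )


def _te_map_dataset(
    config: PipelineConfig, model: ModelSpec, grid: OceanGrid
) -> xr.Dataset:
    """Control-mean TE map plus scenario-minus-control change maps."""
    out = {}
    ctrl = _mean_te_map(config, model, "piControl", grid)
    out["te_piControl"] = (("lat", "lon"), ctrl.values)
    for exp in model.experiments:
        if exp == "piControl":
            continue
        scen = _mean_te_map(config, model, exp, grid)
        out[f"te_change_{exp}"] = (("lat", "lon"), scen.values - ctrl.values)
    ds = xr.Dataset(out, coords={"lat": grid.lat, "lon": grid.lon})
    for name in ds.data_vars:
        ds[name].attrs["units"] = "percent"
    return ds


def _mean_te_map(config, model, experiment, grid):
    spec = model.experiments[experiment]
    expc = read_cmip_variable(spec["expc"], "expc")
    expc_mean = Field("expc", annual_mean(expc).data.mean("time"), expc.units)
    f100 = dg.interpolate_flux_to_depth(expc_mean, config.export_depth)
    f1000 = dg.interpolate_flux_to_depth(expc_mean, config.deep_depth)
    return dg.transfer_efficiency_map(f100, f1000, floor=config.te_floor).values


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage for every usable model and write the output tables.

    Outputs in ``config.outdir``: ``timeseries.csv`` (raw annual metrics),
    ``anomalies.csv`` (control-subtracted), ``anomalies_smoothed.csv``
    (moving-average of the anomalies), ``control_summary.csv``
    (control-run mean state per model) and, optionally,
    ``te_maps_<model>.nc``.  Deterministic for fixed config and files.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report = validate_inputs(config)
    os.makedirs(config.outdir, exist_ok=True)

    series: dict[tuple[str, str], dg.BCPTimeSeries] = {}
    anomalies: dict[tuple[str, str], dg.BCPTimeSeries] = {}
    smoothed: dict[tuple[str, str], dg.BCPTimeSeries] = {}
    summary_rows = []

    for model in config.models:
        if model.name not in report.usable:
            continue
        try:
            ref = read_cmip_variable(model.experiments["piControl"]["o2"], "o2")
            grid = read_cell_measures(model.areacello, model.volcello, reference=ref)
            for exp in sorted(model.experiments):
                series[(model.name, exp)] = _experiment_series(config, model, exp, grid)
                logger.info("model %s: %s diagnostics done", model.name, exp)

            ctrl = series[(model.name, "piControl")]
            summary_rows.append(_summarise_control(model.name, ctrl))

            for exp in sorted(model.experiments):
                if exp == "piControl":
                    continue
                branch = model.branch_year
                if branch is None:
                    branch = read_branch_year(model.experiments[exp]["o2"])
                if branch is None:
                    raise ConfigError(
                        f"{model.name}/{exp}: no branch year in config or file metadata"
                    )
                anomalies[(model.name, exp)] = _anomaly(series[(model.name, exp)], ctrl, branch)
                smoothed[(model.name, exp)] = _smooth(
                    anomalies[(model.name, exp)], config.smoothing_window
                )
                logger.info(
                    "model %s: %s drift-removed at branch year %d", model.name, exp, branch
                )
            if config.write_te_maps:
                ds = _te_map_dataset(config, model, grid)
                path = os.path.join(config.outdir, f"te_maps_{model.name}.nc")
                ds.to_netcdf(path, engine="scipy")
        except Exception:
            logger.exception("model %s failed; continuing with the others", model.name)
            for key in [k for k in series if k[0] == model.name]:
                series.pop(key)
                anomalies.pop(key, None)
                smoothed.pop(key, None)
            summary_rows = [r for r in summary_rows if r["model"] != model.name]

    import pandas as pd

    summary = pd.DataFrame(
        summary_rows,
        columns=["model", "csoft_PgC", "ep100_PgCyr", "f1000_PgCyr", "te_percent", "strat_kgm3"],
    )

    outputs = {}
    for name, collection in (
        ("timeseries.csv", series),
        ("anomalies.csv", anomalies),
        ("anomalies_smoothed.csv", smoothed),
    ):
        path = os.path.join(config.outdir, name)
        write_timeseries_table(list(collection.values()), path)
        outputs[name] = path
    path = os.path.join(config.outdir, "control_summary.csv")
    summary.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")
    outputs["control_summary.csv"] = path
    return PipelineResult(
        series=series,
        anomalies=anomalies,
        smoothed=smoothed,
        summary=summary,
        report=report,
        outputs=outputs,
    )


def _summarise_control(name: str, ctrl: dg.BCPTimeSeries) -> dict:
    ep = float(ctrl.ep100.mean())
    f = float(ctrl.f1000.mean())
    return {
        "model": name,
        "csoft_PgC": float(ctrl.csoft.mean()),
        "ep100_PgCyr": ep,
        "f1000_PgCyr": f,
        # ratio of control means, so TE = 100 F1000/EP100 holds row-wise
        "te_percent": 100.0 * f / ep,
        "strat_kgm3": float(ctrl.strat.mean()),
    }


def _metric_series(ts: dg.BCPTimeSeries, metric: str) -> AnnualSeries:
    return AnnualSeries(
        years=ts.years,
        values=getattr(ts, metric),
        units=METRIC_UNITS[metric],
        experiment_id=ts.experiment_id,
        model_name=ts.model_name,
    )


def _anomaly(scen: dg.BCPTimeSeries, ctrl: dg.BCPTimeSeries, branch: int) -> dg.BCPTimeSeries:
    out = {}
    n = None
    for metric in METRICS:
        an = remove_drift(_metric_series(scen, metric), _metric_series(ctrl, metric), branch)
        out[metric] = an.values
        n = an.years.size
    return dg.BCPTimeSeries(
        model_name=scen.model_name,
        experiment_id=scen.experiment_id,
        years=scen.years[:n],
        **out,
    )


def _smooth(ts: dg.BCPTimeSeries, window: int) -> dg.BCPTimeSeries:
    # short series (e.g. truncated overlaps) get the widest window that fits
    w = min(window, ts.years.size)
    out = {
        m: moving_average(_metric_series(ts, m), window=w).values for m in METRICS
    }
    return dg.BCPTimeSeries(
        model_name=ts.model_name,
        experiment_id=ts.experiment_id,
        years=ts.years,
        **out,
    )
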