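"""Shared fixtures: tiny analytic grids and a session-scoped synthetic ensemble."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from biopump.grids import OceanGrid
from biopump.pipeline import ModelSpec, PipelineConfig, run_pipeline
from biopump.synthetic import GeneratorParams, ground_truth, simulate_run

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def make_box_grid(
    nz: int = 4,
    nlat: int = 2,
    nlon: int = 3,
    depths=(50.0, 150.0, 600.0, 1500.0),
    area: float = 1.0e12,
) -> OceanGrid:
    """A tiny all-ocean box grid with uniform cell areas for hand checks."""
    depths = np.asarray(depths, dtype=float)
    mid = 0.5 * (depths[1:] + depths[:-1])
    bounds = np.column_stack(
        [np.concatenate([[0.0], mid]), np.concatenate([mid, [depths[-1] * 1.2]])]
    )
    areas = np.full((nlat, nlon), area)
    dz = bounds[:, 1] - bounds[:, 0]
    vol = areas[None] * dz[:, None, None]
    return OceanGrid(
        cell_area=areas,
        depth_centers=depths,
        depth_bounds=bounds,
        cell_volume=vol,
        land_mask=np.zeros((nlat, nlon), dtype=bool),
        lat=np.linspace(-45, 45, nlat),
        lon=np.linspace(0, 240, nlon),
    )


@pytest.fixture(scope="session")
def study_params() -> GeneratorParams:
    """The default study conditions: 8x16x20 grid, 50-y scenario."""
    return GeneratorParams(seed=7)


@pytest.fixture(scope="session")
def study_runs(study_params, tmp_path_factory):
    """Generated control + scenario files for the default conditions."""
    outdir = tmp_path_factory.mktemp("ensemble")
    paths = {
        exp: simulate_run(study_params, exp, outdir, model_name="SYNTH-A")
        for exp in ("piControl", "ssp370")
    }
    return outdir, paths


@pytest.fixture(scope="session")
def study_pipeline(study_runs, tmp_path_factory):
    """Full pipeline result on the generated ensemble."""
    outdir, paths = study_runs
    cfg = PipelineConfig(
        models=[
            ModelSpec(
                name="SYNTH-A",
                areacello=paths["piControl"]["areacello"],
                volcello=paths["piControl"]["volcello"],
                experiments={
                    exp: {v: paths[exp][v] for v in ("o2", "expc", "thetao", "so")}
                    for exp in paths
                },
            )
        ],
        outdir=str(tmp_path_factory.mktemp("results")),
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def study_truth(study_params):
    return {exp: ground_truth(study_params, exp) for exp in ("piControl", "ssp370")}
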