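"""Shared plumbing for the numbered analysis drivers."""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np

from drygpp import aridity, io, synthetic_data
from drygpp.synthetic_data import ScenarioConfig

SCENARIOS = ("rcp45", "rcp85")


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    return ap.parse_args()


def scenario_config(seed: int, scenario: str) -> ScenarioConfig:
    return ScenarioConfig(seed=seed, scenario=scenario)


def scenario_path(outdir: Path, scenario: str) -> Path:
    return outdir / "data" / f"scenario_{scenario}.nc"


def load_scenario(outdir: Path, scenario: str):
    """Config + climate grids + AI + baseline GPP written by 01_simulate."""
    truth = io.read_json(outdir / "data" / f"truth_{scenario}.json")
    cfg = ScenarioConfig.from_dict(truth["scenario_config"])
    ds = io.read_grid(scenario_path(outdir, scenario))
    ai = aridity.aridity_index(ds["precip"], ds["pet"])
    base_years = np.arange(cfg.baseline_years[0], cfg.baseline_years[1] + 1)
    gpp_obs = ds["gpp"].sel(time=base_years)
    return cfg, ds, ai, gpp_obs


def areas_for(cfg: ScenarioConfig):
    lats, _ = cfg.grid_coords()
    return aridity.cell_areas(lats, cfg.resolution)
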