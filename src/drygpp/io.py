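"""Run configuration, provenance, and file I/O (NetCDF / CSV / JSON / YAML).

Gridded fields travel as CF-style NetCDF (classic format via xarray's scipy
backend): dims (time, lat, lon), units attributes, integer class/region
variables with flag_values/flag_meanings.  Tabular outputs are CSV with a
single ``#``-prefixed provenance comment line (config hash + seed), so
re-running with the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .gpp_ai_model import PolyFit
from .synthetic_data import ScenarioConfig

__all__ = [
    "RunConfig",
    "load_run_config",
    "config_hash",
    "write_grid",
    "read_grid",
    "write_table",
    "read_table",
    "write_fits",
    "read_fits",
    "write_json",
    "read_json",
]


class RunConfig(BaseModel):
    """Validated run options for the command-line pipeline."""

    outdir: str = "runs/default"
    seed: int = 0
    scenario: str = "rcp45"
    scenario_overrides: dict = Field(default_factory=dict)
    sample_mode: str = "cell_mean"
    degree_policy: int | str = "aicc"
    anomaly_mode: str = "trend_removed"
    driver_order: list[str] = Field(default_factory=lambda: ["precip", "tair"])
    projection_windows: Optional[dict[str, tuple[int, int]]] = None
    log_level: str = "INFO"

    @field_validator("scenario")
    @classmethod
    def _scenario(cls, v: str) -> str:
        if v not in ("rcp45", "rcp85"):
            raise ValueError("scenario must be 'rcp45' or 'rcp85'")
        return v

    @field_validator("sample_mode")
    @classmethod
    def _sample_mode(cls, v: str) -> str:
        if v not in ("cell_mean", "cell_year"):
            raise ValueError("sample_mode must be 'cell_mean' or 'cell_year'")
        return v

    @field_validator("anomaly_mode")
    @classmethod
    def _anomaly_mode(cls, v: str) -> str:
        if v not in ("mean_removed", "trend_removed"):
            raise ValueError("anomaly_mode must be 'mean_removed' or 'trend_removed'")
        return v

    @field_validator("degree_policy")
    @classmethod
    def _degree_policy(cls, v):
        if isinstance(v, int):
            if v < 1:
                raise ValueError("fixed degree must be >= 1")
        elif v != "aicc":
            raise ValueError("degree_policy must be an integer or 'aicc'")
        return v

    @model_validator(mode="after")
    def _windows_ordered(self) -> "RunConfig":
        if self.projection_windows:
            spans = sorted(self.projection_windows.values())
            for (lo, hi) in spans:
                if hi < lo:
                    raise ValueError(f"window ({lo}, {hi}) is reversed")
            for (_lo1, hi1), (lo2, _hi2) in zip(spans, spans[1:]):
                if lo2 <= hi1:
                    raise ValueError("projection windows must not overlap")
        return self

    def scenario_config(self) -> ScenarioConfig:
        kwargs = dict(self.scenario_overrides)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("scenario", self.scenario)
        return ScenarioConfig.from_dict(kwargs)


def load_run_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def config_hash(config: ScenarioConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: ScenarioConfig) -> dict:
    return {"config_hash": config_hash(config), "seed": config.seed,
            "scenario": config.scenario}


# -- gridded ---------------------------------------------------------------


def write_grid(ds: xr.Dataset, path: str | Path, config: ScenarioConfig) -> None:
    ds = ds.copy()
    ds.attrs.update(_provenance(config))
    ds.attrs["Conventions"] = "CF-1.8"
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, engine="scipy")


def read_grid(path: str | Path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")


# -- tabular ---------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, config: ScenarioConfig,
                index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    with open(path, "w") as fh:
        fh.write(f"# drygpp config={prov['config_hash']} seed={prov['seed']} "
                 f"scenario={prov['scenario']}\n")
        df.to_csv(fh, index=index, lineterminator="\n")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


# -- JSON ------------------------------------------------------------------


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj: dict, path: str | Path,
               config: ScenarioConfig | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    if config is not None:
        obj = {"provenance": _provenance(config), **obj}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_fits(fits: dict[str, PolyFit], path: str | Path,
               config: ScenarioConfig) -> None:
    write_json({"fits": {k: f.to_dict() for k, f in fits.items()}}, path, config)


def read_fits(path: str | Path) -> dict[str, PolyFit]:
    data = read_json(path)
    return {k: PolyFit.from_dict(v) for k, v in data["fits"].items()}
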