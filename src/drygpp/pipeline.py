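"""End-to-end orchestration of the dryland GPP variability analysis.

The stages mirror the analysis a practitioner would run on gridded GPP and
aridity data: simulate (or load) climate grids, derive AI, classify
aridity subtypes per analysis window, fit per-region GPP-AI curves on the
baseline window, drive the curves with projected AI, decompose trend and
IAV contributions on the region x subtype partition, and attribute the net
dryland GPP change to subtype-conversion pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from . import aridity, conversions, gpp_ai_model, synthetic_data, variability
from .aridity import DRYLAND_THRESHOLD, SUBTYPE_NAMES
from .synthetic_data import REGION_CODES, ScenarioConfig

__all__ = [
    "PipelineResult",
    "default_windows",
    "simulate_scenario",
    "classify_windows",
    "fit_baseline",
    "predicted_gpp_series",
    "joint_series",
    "window_contributions",
    "run_pipeline",
]

#: Projection terciles used for period-wise contribution tables.
PROJECTION_WINDOWS = {
    "2011-2040": (2011, 2040),
    "2041-2070": (2041, 2070),
    "2071-2100": (2071, 2100),
}

#: End-of-century window for the conversion-attribution ledger.
END_WINDOW = (2085, 2100)


def default_windows(config: ScenarioConfig) -> dict[str, tuple[int, int]]:
    base = config.baseline_years
    return {f"{base[0]}-{base[1]}": tuple(base), **PROJECTION_WINDOWS}


@dataclass
class PipelineResult:
    config: ScenarioConfig
    climate: xr.Dataset
    ai: xr.DataArray
    gpp_obs: xr.DataArray  # baseline-years observed GPP
    sites: list
    subtypes: dict[str, xr.DataArray]
    fits: dict[str, gpp_ai_model.PolyFit]
    projections: dict[str, gpp_ai_model.ProjectionResult]
    contributions: list[variability.ContributionTable]
    joint_shares: dict[str, pd.DataFrame] = field(default_factory=dict)
    driver_fractions: pd.Series | None = None
    site_comparisons: list = field(default_factory=list)
    ledger: conversions.TransitionLedger | None = None
    perarea: pd.DataFrame | None = None
    perarea_trends: dict[str, float] = field(default_factory=dict)


def simulate_scenario(config: ScenarioConfig):
    """Climate grids for the full span, baseline GPP observations, sites."""
    clim = synthetic_data.generate_climate_grids(config)
    ai = aridity.aridity_index(clim["precip"], clim["pet"])
    base_years = np.arange(config.baseline_years[0], config.baseline_years[1] + 1)
    ai_base = ai.sel(time=base_years)
    gpp_obs = synthetic_data.generate_gpp_from_ai(ai_base, config)
    sites = synthetic_data.generate_site_fluxes(config)
    return clim, ai, gpp_obs, sites


def classify_windows(
    ai: xr.DataArray, windows: Mapping[str, tuple[int, int]]
) -> dict[str, xr.DataArray]:
    """Subtype map per analysis window from the window-mean AI climatology."""
    out = {}
    for name, (lo, hi) in windows.items():
        years = [y for y in ai.time.values if lo <= y <= hi]
        clim = ai.sel(time=years).mean("time")
        out[name] = aridity.classify_subtype(clim)
    return out


def fit_baseline(
    ai: xr.DataArray,
    gpp_obs: xr.DataArray,
    config: ScenarioConfig,
    sample_mode: str = "cell_mean",
    degree_policy: int | str = "aicc",
) -> dict[str, gpp_ai_model.PolyFit]:
    """One GPP-AI polynomial per region from the baseline window.

    ``cell_mean`` (default) uses one point per cell: baseline-mean GPP vs
    baseline-mean AI.  ``cell_year`` pools every cell-year sample.
    """
    base_years = gpp_obs.time.values
    ai_base = ai.sel(time=base_years)
    regions = synthetic_data.region_mask(config).values
    fits = {}
    for i, code in enumerate(REGION_CODES, start=1):
        sel = regions == i
        if sample_mode == "cell_mean":
            x = ai_base.mean("time").values[sel]
            y = gpp_obs.mean("time").values[sel]
        elif sample_mode == "cell_year":
            x = ai_base.values[:, sel].ravel()
            y = gpp_obs.values[:, sel].ravel()
        else:
            raise ValueError("sample_mode must be 'cell_mean' or 'cell_year'")
        fits[code] = gpp_ai_model.fit_gpp_ai(
            x, y, degree_policy=degree_policy, region=code
        )
    return fits


def predicted_gpp_series(
    fits: Mapping[str, gpp_ai_model.PolyFit],
    ai: xr.DataArray,
    config: ScenarioConfig,
) -> xr.DataArray:
    """Per-area GPP predicted from the fitted curves at each year's AI.

    NaN outside the fit domain (humid or AI = 0 cells).
    """
    regions = synthetic_data.region_mask(config).values
    out = np.full(ai.shape, np.nan)
    for i, code in enumerate(REGION_CODES, start=1):
        sel = regions == i
        central, _, _ = gpp_ai_model.predict_gpp(fits[code], ai.values[..., sel])
        out[..., sel] = central
    return xr.DataArray(out, coords=ai.coords, dims=ai.dims, name="gpp_pred")


def joint_series(
    gpp: xr.DataArray,
    subtype_map: xr.DataArray,
    config: ScenarioConfig,
    areas,
) -> pd.DataFrame:
    """Annual dryland GPP totals on the region x subtype partition.

    Columns are (region, subtype) MultiIndex; the partition is complete
    over the window's dryland cells, so row sums give the global dryland
    total exactly.
    """
    regions = synthetic_data.region_mask(config).values
    codes = subtype_map.values
    cols = {}
    for i, rcode in enumerate(REGION_CODES, start=1):
        for c in range(4):  # dryland classes only
            mask = (regions == i) & (codes == c)
            tot = aridity.aggregate_total(gpp.fillna(0.0), mask, areas)
            cols[(rcode, SUBTYPE_NAMES[c])] = np.asarray(tot.values)
    df = pd.DataFrame(cols, index=pd.Index(gpp.time.values, name="year"))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["region", "subtype"])
    return df


def window_contributions(
    df: pd.DataFrame, period: str, anomaly_mode: str = "trend_removed"
) -> tuple[list[variability.ContributionTable], pd.DataFrame]:
    """Region and subtype contribution tables from one joint-partition table.

    Both marginal tables derive from the single additive region x subtype
    decomposition: trend shares via OLS-slope additivity, IAV shares via
    the sign-weighted anomaly index against the summed global anomaly.
    """
    regional = df.T.groupby(level="region").sum().T
    by_subtype = df.T.groupby(level="subtype").sum().T
    glob = df.sum(axis=1)
    tables = []
    for label, marg in (("region", regional), ("subtype", by_subtype)):
        tables.append(
            variability.contribution_trend(
                {str(c): marg[c] for c in marg.columns}, period=f"{period}:{label}"
            )
        )
        ganom = variability.annual_anomaly(glob, mode=anomaly_mode, entity="GLOBAL")
        ranoms = [
            variability.annual_anomaly(marg[c], mode=anomaly_mode, entity=str(c))
            for c in marg.columns
        ]
        tables.append(
            variability.contribution_iav(ranoms, ganom, period=f"{period}:{label}")
        )
    joint_trend = variability.contribution_trend(
        {f"{r}|{s}": df[(r, s)] for r, s in df.columns}, period=f"{period}:joint"
    )
    return tables, joint_trend.to_frame()


def run_pipeline(
    config: ScenarioConfig,
    sample_mode: str = "cell_mean",
    degree_policy: int | str = "aicc",
    anomaly_mode: str = "trend_removed",
) -> PipelineResult:
    """Run every stage on one scenario and collect the results."""
    clim, ai, gpp_obs, sites = simulate_scenario(config)
    lats, _ = config.grid_coords()
    areas = aridity.cell_areas(lats, config.resolution)
    windows = default_windows(config)
    end_name = f"{END_WINDOW[0]}-{END_WINDOW[1]}"
    subtypes = classify_windows(ai, {**windows, end_name: END_WINDOW})

    fits = fit_baseline(ai, gpp_obs, config, sample_mode, degree_policy)

    proj_years = np.arange(config.projection_years[0], config.projection_years[1] + 1)
    ai_proj = ai.sel(time=proj_years)
    projections = gpp_ai_model.project_regional_gpp(
        fits,
        ai_proj,
        synthetic_data.region_mask(config),
        areas,
        scenario=config.scenario,
    )

    # Contribution tables per window on the region x subtype partition.
    gpp_pred = predicted_gpp_series(fits, ai, config)
    contributions: list[variability.ContributionTable] = []
    joint_shares: dict[str, pd.DataFrame] = {}
    base_name = list(windows)[0]
    for name, (lo, hi) in windows.items():
        years = [y for y in ai.time.values if lo <= y <= hi]
        if name == base_name:
            gpp_w = gpp_obs.sel(time=[y for y in years if y in gpp_obs.time.values])
        else:
            gpp_w = gpp_pred.sel(time=years)
        df = joint_series(gpp_w, subtypes[name], config, areas)
        tables, joint = window_contributions(df, name, anomaly_mode)
        contributions.extend(tables)
        joint_shares[name] = joint

    # Drivers of the baseline global dryland GPP anomaly.
    base_years = gpp_obs.time.values
    dry_base = aridity.dryland_mask(subtypes[base_name]).values
    glob_obs = aridity.aggregate_total(gpp_obs, dry_base, areas)
    glob_series = pd.Series(np.asarray(glob_obs.values), index=base_years)
    drv = {}
    for var in ("precip", "tair"):
        fld = clim[var].sel(time=base_years)
        mean = fld.values[:, dry_base].mean(axis=1)
        drv[var] = variability.annual_anomaly(
            pd.Series(mean, index=base_years), mode=anomaly_mode, entity=var
        )
    gpp_anom = variability.annual_anomaly(glob_series, mode=anomaly_mode, entity="GLOBAL")
    driver_fractions = variability.driver_variance_partition(gpp_anom, drv)

    site_comparisons = variability.validate_sites(gpp_obs, sites)

    # Conversion attribution: baseline vs end-of-century window.
    gb = gpp_obs.mean("time")
    end_years = [y for y in ai.time.values if END_WINDOW[0] <= y <= END_WINDOW[1]]
    ai_end = ai.sel(time=end_years).mean("time")
    gf = predicted_gpp_series(fits, ai_end, config).fillna(0.0)
    ledger = conversions.attribute_gpp_change(
        gb, gf, subtypes[base_name], subtypes[end_name], areas,
        period_pair=(base_name, end_name),
    )

    dry_by_year = xr.DataArray(
        (ai_proj.values < DRYLAND_THRESHOLD) & (ai_proj.values > 0),
        coords=ai_proj.coords,
        dims=ai_proj.dims,
    )
    perarea, perarea_trends = conversions.per_area_decomposition(
        gpp_pred.sel(time=proj_years).fillna(0.0), dry_by_year, dry_base, areas
    )

    return PipelineResult(
        config=config,
        climate=clim,
        ai=ai,
        gpp_obs=gpp_obs,
        sites=sites,
        subtypes=subtypes,
        fits=fits,
        projections=projections,
        contributions=contributions,
        joint_shares=joint_shares,
        driver_fractions=driver_fractions,
        site_comparisons=site_comparisons,
        ledger=ledger,
        perarea=perarea,
        perarea_trends=perarea_trends,
    )


def end_of_century_increase(result: PipelineResult) -> float:
    """Percent change of end-window dryland GPP relative to the baseline.

    Baseline total uses observed GPP over the baseline classification;
    end-window total is the mean projected global dryland total.
    """
    config = result.config
    lats, _ = config.grid_coords()
    areas = aridity.cell_areas(lats, config.resolution)
    base_name = list(default_windows(config))[0]
    dry_base = aridity.dryland_mask(result.subtypes[base_name]).values
    base_total = float(
        np.asarray(aridity.aggregate_total(result.gpp_obs, dry_base, areas).values).mean()
    )
    glob = result.projections["GLOBAL"]
    sel = (glob.years >= END_WINDOW[0]) & (glob.years <= END_WINDOW[1])
    end_total = float(glob.central[sel].mean())
    return (end_total - base_total) / base_total * 100.0
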