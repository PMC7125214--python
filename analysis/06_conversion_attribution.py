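"""Attribute the net dryland GPP change to expansion/degradation pathways.

Compares the baseline and end-of-century classifications, builds the
transition ledger with the dryland-accounting convention, and decomposes
per-unit-area GPP into historical vs expanded drylands.
"""

import numpy as np
import xarray as xr

from _common import areas_for, load_scenario, parse_args
from drygpp import aridity, conversions, io, pipeline


def main() -> None:
    args = parse_args(__doc__)
    scenario = "rcp45"
    cfg, ds, ai, gpp_obs = load_scenario(args.outdir, scenario)
    fits = io.read_fits(args.outdir / f"fits_{scenario}.json")
    areas = areas_for(cfg)
    windows = pipeline.default_windows(cfg)
    base_name = list(windows)[0]
    end_name = f"{pipeline.END_WINDOW[0]}-{pipeline.END_WINDOW[1]}"
    subtypes = pipeline.classify_windows(
        ai, {base_name: windows[base_name], end_name: pipeline.END_WINDOW})

    gb = gpp_obs.mean("time")
    end_years = [y for y in ai.time.values
                 if pipeline.END_WINDOW[0] <= y <= pipeline.END_WINDOW[1]]
    ai_end = ai.sel(time=end_years).mean("time")
    gf = pipeline.predicted_gpp_series(fits, ai_end, cfg).fillna(0.0)
    ledger = conversions.attribute_gpp_change(
        gb, gf, subtypes[base_name], subtypes[end_name], areas,
        period_pair=(base_name, end_name))
    io.write_table(ledger.table, args.outdir / "ledger.csv", cfg)
    io.write_json({"net_change_PgC_yr": ledger.net_change,
                   "flows": ledger.to_flows()},
                  args.outdir / "flows.json", cfg)

    t = ledger.table.dropna(subset=["percent_share"])
    t = t[t["delta_gpp_PgC_yr"].abs() > 0]
    print(f"net dryland GPP change {ledger.net_change:+.3f} Pg C yr-1; "
          f"pathway shares sum to {t['percent_share'].sum():.1f}%")
    for _, row in t.reindex(t["delta_gpp_PgC_yr"].abs()
                            .sort_values(ascending=False).index).head(5).iterrows():
        print(f"  {row['from']:>9} -> {row['to']:<9} "
              f"{row['delta_gpp_PgC_yr']:+.3f} Pg C yr-1 "
              f"({row['percent_share']:+.1f}%)")

    proj_years = np.arange(cfg.projection_years[0], cfg.projection_years[1] + 1)
    ai_proj = ai.sel(time=proj_years)
    gpp_pred = pipeline.predicted_gpp_series(fits, ai_proj, cfg).fillna(0.0)
    dry_by_year = xr.DataArray(
        (ai_proj.values < aridity.DRYLAND_THRESHOLD) & (ai_proj.values > 0),
        coords=ai_proj.coords, dims=ai_proj.dims)
    dry_base = aridity.dryland_mask(subtypes[base_name]).values
    perarea, trends = conversions.per_area_decomposition(
        gpp_pred, dry_by_year, dry_base, areas)
    io.write_table(perarea.reset_index(), args.outdir / "perarea.csv", cfg)
    print("per-unit-area GPP trends (kg C m-2 yr-1 per yr): "
          + ", ".join(f"{k} {v:+.2e}" for k, v in trends.items()))


if __name__ == "__main__":
    main()
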