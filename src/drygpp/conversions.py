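"""Subtype-transition accounting and dryland expansion/degradation ledgers.

Between a baseline and a future classification, every cell follows one of
25 (from-class, to-class) pathways over {hyperarid, arid, semiarid,
subhumid, humid}.  GPP change is attributed per pathway under the
dryland-accounting convention: a cell entering the drylands contributes its
full future GPP (its humid-era GPP was outside dryland accounting), a cell
leaving contributes minus its full baseline GPP, and a cell staying inside
contributes the ordinary difference.  Pathway changes then conserve the net
dryland GPP change exactly, and their percent shares of that net change sum
to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .aridity import SUBTYPE_NAMES

__all__ = [
    "TransitionLedger",
    "DrylandPartition",
    "subtype_transition",
    "attribute_gpp_change",
    "build_partition",
    "per_area_decomposition",
]

_HUMID = 4


@dataclass
class TransitionLedger:
    """Per-pathway area, GPP change, and share of the net dryland change."""

    table: pd.DataFrame  # columns: from, to, area_km2, delta_gpp_PgC_yr, percent_share
    net_change: float | None = None  # Pg C yr^-1; None for area-only ledgers
    period_pair: tuple[str, str] = ("baseline", "future")

    def entry(self, from_class: str, to_class: str) -> pd.Series:
        t = self.table
        row = t[(t["from"] == from_class) & (t["to"] == to_class)]
        if row.empty:
            raise KeyError((from_class, to_class))
        return row.iloc[0]

    def to_flows(self) -> list[dict]:
        """JSON-friendly flow list for alluvial/Sankey tools."""
        return self.table.to_dict(orient="records")


@dataclass
class DrylandPartition:
    """Historical / expanded / contracted dryland masks on one grid."""

    historical: np.ndarray  # dryland at baseline
    expanded: np.ndarray  # dryland at future, humid at baseline
    contracted: np.ndarray  # dryland at baseline, humid at future

    def __post_init__(self) -> None:
        if (self.historical & self.expanded).any():
            raise ValueError("expanded and historical masks must be disjoint")


def _codes(m) -> np.ndarray:
    c = np.asarray(m.values if isinstance(m, xr.DataArray) else m)
    if ((c < 0) | (c > 4)).any():
        raise ValueError("unclassified cells in subtype map")
    return c


def _area_grid(shape, areas) -> np.ndarray:
    a = np.asarray(areas.values if isinstance(areas, xr.DataArray) else areas,
                   dtype=float)
    if a.ndim == 1:
        a = np.broadcast_to(a[:, None], shape)
    if a.shape != shape:
        raise ValueError("area grid does not match the maps")
    return a


def subtype_transition(baseline, future, areas) -> TransitionLedger:
    """Area (km^2) on each of the 25 class-transition pathways."""
    b, f = _codes(baseline), _codes(future)
    if b.shape != f.shape:
        raise ValueError("baseline and future maps must share a grid")
    a = _area_grid(b.shape, areas)
    rows = []
    for i, from_name in enumerate(SUBTYPE_NAMES):
        for j, to_name in enumerate(SUBTYPE_NAMES):
            sel = (b == i) & (f == j)
            rows.append(
                {
                    "from": from_name,
                    "to": to_name,
                    "area_km2": float(a[sel].sum()),
                    "delta_gpp_PgC_yr": np.nan,
                    "percent_share": np.nan,
                }
            )
    return TransitionLedger(table=pd.DataFrame(rows))


def attribute_gpp_change(
    baseline_gpp,
    future_gpp,
    baseline_map,
    future_map,
    areas,
    period_pair: tuple[str, str] = ("baseline", "future"),
) -> TransitionLedger:
    """Attribute the net dryland GPP change to conversion pathways.

    GPP inputs are window-mean per-area fields (kg C m^-2 yr^-1).  Pathway
    changes in Pg C yr^-1; percent shares are relative to the net dryland
    GPP change (future dryland total minus baseline dryland total) and sum
    to 100% whenever that net change is nonzero.
    """
    b, f = _codes(baseline_map), _codes(future_map)
    if b.shape != f.shape:
        raise ValueError("baseline and future maps must share a grid")
    gb = np.asarray(
        baseline_gpp.values if isinstance(baseline_gpp, xr.DataArray) else baseline_gpp,
        dtype=float,
    )
    gf = np.asarray(
        future_gpp.values if isinstance(future_gpp, xr.DataArray) else future_gpp,
        dtype=float,
    )
    if gb.shape != b.shape or gf.shape != b.shape:
        raise ValueError("GPP fields must align with the maps")
    a = _area_grid(b.shape, areas)

    dry_b = b != _HUMID
    dry_f = f != _HUMID
    # Per-cell contribution to the *dryland* GPP change, kg C yr^-1 (x area).
    contrib = np.zeros_like(gb)
    both = dry_b & dry_f
    enter = ~dry_b & dry_f
    leave = dry_b & ~dry_f
    contrib[both] = gf[both] - gb[both]
    contrib[enter] = gf[enter]
    contrib[leave] = -gb[leave]
    contrib = contrib * a * 1e-6  # -> Pg C yr^-1

    rows = []
    for i, from_name in enumerate(SUBTYPE_NAMES):
        for j, to_name in enumerate(SUBTYPE_NAMES):
            sel = (b == i) & (f == j)
            rows.append(
                {
                    "from": from_name,
                    "to": to_name,
                    "area_km2": float(a[sel].sum()),
                    "delta_gpp_PgC_yr": float(contrib[sel].sum()),
                }
            )
    table = pd.DataFrame(rows)
    net = float(table["delta_gpp_PgC_yr"].sum())
    if net != 0:
        table["percent_share"] = table["delta_gpp_PgC_yr"] / net * 100.0
    else:
        table["percent_share"] = np.nan
    return TransitionLedger(table=table, net_change=net, period_pair=period_pair)


def build_partition(baseline, future) -> DrylandPartition:
    """Historical/expanded/contracted dryland masks from two subtype maps."""
    b, f = _codes(baseline), _codes(future)
    if b.shape != f.shape:
        raise ValueError("baseline and future maps must share a grid")
    dry_b = b != _HUMID
    dry_f = f != _HUMID
    return DrylandPartition(
        historical=dry_b,
        expanded=dry_f & ~dry_b,
        contracted=dry_b & ~dry_f,
    )


def per_area_decomposition(
    gpp: xr.DataArray,
    dryland_by_year: xr.DataArray,
    baseline_dryland,
    areas,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Total and per-unit-area GPP series for all/historical/expanded drylands.

    ``dryland_by_year`` is the (time, lat, lon) boolean dryland mask for
    each year; ``baseline_dryland`` the (lat, lon) baseline mask.  For each
    year, the "historical" group is baseline-dryland cells still dryland
    that year and "expanded" is dryland cells humid at baseline, so the two
    groups partition the year's drylands and their totals add exactly.
    Returns the per-year table (totals in Pg C yr^-1, per-area values in
    kg C m^-2 yr^-1) and the OLS trend of each per-area series.
    """
    base = np.asarray(
        baseline_dryland.values
        if isinstance(baseline_dryland, xr.DataArray)
        else baseline_dryland,
        dtype=bool,
    )
    a = _area_grid(base.shape, areas)
    years = gpp.time.values
    records = []
    for k, year in enumerate(years):
        dry = np.asarray(dryland_by_year.values[k], dtype=bool)
        g = np.nan_to_num(gpp.values[k], nan=0.0)
        groups = {
            "all": dry,
            "historical": dry & base,
            "expanded": dry & ~base,
        }
        rec: dict = {"year": int(year)}
        for name, m in groups.items():
            area = float(a[m].sum())
            total = float((g[m] * a[m]).sum() * 1e-6)
            rec[f"total_{name}"] = total
            rec[f"area_{name}_km2"] = area
            rec[f"perarea_{name}"] = (total * 1e6 / area) if area > 0 else np.nan
        records.append(rec)
    df = pd.DataFrame(records).set_index("year")
    trends = {}
    for name in ("all", "historical", "expanded"):
        s = df[f"perarea_{name}"].dropna()
        if len(s) >= 3 and np.ptp(s.index.values) > 0:
            slope = np.polyfit(s.index.values.astype(float), s.values, 1)[0]
            trends[name] = float(slope)
        else:
            trends[name] = float("nan")
    return df, trends
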