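"""Trend, interannual variability, and contribution decompositions.

A regional (or subtype) annual GPP total is decomposed into an OLS linear
trend and anomalies about it; interannual variability (IAV) is the mean
absolute anomaly.  Regional contributions to the global trend use trend
additivity (the OLS slope of a sum is the sum of slopes); contributions to
the global IAV use the sign-weighted average-relative-anomaly index

    f_i = sum_t x_it * sign(X_t) / sum_t |X_t|,

which sums to one over any complete partition of the global anomaly X_t.
Regions with negative f_i dampen global variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

__all__ = [
    "AnomalySeries",
    "ContributionTable",
    "SiteComparison",
    "annual_anomaly",
    "linear_trend",
    "iav",
    "contribution_iav",
    "contribution_trend",
    "driver_variance_partition",
    "validate_sites",
]


@dataclass
class AnomalySeries:
    """Annual anomalies (Pg C yr^-1) for one spatial aggregate."""

    entity: str
    years: np.ndarray
    values: np.ndarray
    mode: str  # "mean_removed" | "trend_removed"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must align")
        if self.mode not in ("mean_removed", "trend_removed"):
            raise ValueError("mode must be 'mean_removed' or 'trend_removed'")


@dataclass
class ContributionTable:
    """Per-entity shares of a global trend or IAV; shares sum to one."""

    shares: pd.Series  # entity -> f_i
    metric: str  # "trend" | "iav"
    period: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = self.shares.rename("share").rename_axis("entity").reset_index()
        df["metric"] = self.metric
        df["period"] = self.period
        return df


@dataclass
class SiteComparison:
    """Agreement between gridded and tower GPP at one site."""

    site_id: str
    n: int
    r2: float
    rmse: float

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("RMSE must be >= 0")


def _as_year_series(series) -> pd.Series:
    if isinstance(series, AnomalySeries):
        return pd.Series(series.values, index=series.years)
    if isinstance(series, pd.Series):
        return series.astype(float)
    arr = np.asarray(series, dtype=float)
    return pd.Series(arr, index=np.arange(arr.size))


def annual_anomaly(series, mode: str = "trend_removed", entity: str = "") -> AnomalySeries:
    """Anomalies of an annual series: mean-removed or OLS-trend-removed."""
    s = _as_year_series(series)
    if len(s) < 3:
        raise ValueError("need at least 3 years")
    y = s.values
    t = np.asarray(s.index, dtype=float)
    if mode == "mean_removed":
        x = y - y.mean()
    elif mode == "trend_removed":
        slope, intercept = np.polyfit(t, y, 1)
        x = y - (slope * t + intercept)
    else:
        raise ValueError("mode must be 'mean_removed' or 'trend_removed'")
    name = entity or (s.name if s.name is not None else "")
    return AnomalySeries(entity=str(name), years=s.index.values, values=x, mode=mode)


def linear_trend(series) -> tuple[float, float]:
    """OLS slope per year and its two-tailed p-value."""
    s = _as_year_series(series)
    if len(s) < 3:
        raise ValueError("need at least 3 years")
    t = np.asarray(s.index, dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("time axis has zero variance")
    res = stats.linregress(t, s.values)
    # a zero-variance response has slope 0 and no evidence of a trend
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return float(res.slope), p


def iav(anom: AnomalySeries | Sequence[float]) -> float:
    """Interannual variability: mean absolute anomaly."""
    x = anom.values if isinstance(anom, AnomalySeries) else np.asarray(anom, float)
    if x.size == 0:
        raise ValueError("empty anomaly series")
    if not np.isfinite(x).all():
        raise ValueError("anomalies must be finite")
    return float(np.mean(np.abs(x)))


def contribution_iav(
    regional: Sequence[AnomalySeries],
    global_anom: AnomalySeries,
    period: str = "",
    tol: float = 1e-9,
) -> ContributionTable:
    """Regional shares of global IAV via the sign-weighted anomaly index.

    Requires the regional anomalies to be a complete partition of the
    global anomaly (they sum to X_t each year within ``tol``).  Years with
    X_t = 0 are excluded with a warning, since the index's relative anomaly
    is undefined there.
    """
    X = global_anom.values
    years = global_anom.years
    stack = []
    for r in regional:
        if not np.array_equal(r.years, years):
            raise ValueError(f"{r.entity}: year axis differs from global")
        stack.append(r.values)
    M = np.vstack(stack)  # (nregions, nyears)
    if not np.allclose(M.sum(axis=0), X, atol=tol, rtol=0):
        raise ValueError("regional anomalies do not sum to the global anomaly")
    keep = X != 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} years with zero global anomaly")
    if not keep.any():
        raise ValueError("no usable years (global anomaly identically zero)")
    Xk = X[keep]
    denom = np.abs(Xk).sum()
    f = (M[:, keep] * np.sign(Xk)).sum(axis=1) / denom
    shares = pd.Series(f, index=[r.entity for r in regional])
    return ContributionTable(shares=shares, metric="iav", period=period)


def contribution_trend(
    regional_series: Mapping[str, pd.Series], period: str = ""
) -> ContributionTable:
    """Regional shares of the global trend: slope_i over the sum of slopes.

    OLS slopes are additive over a common year axis, so the overall trend
    equals the sum of the per-region trends and the shares sum to one.
    """
    slopes = {}
    axes = None
    for name, s in regional_series.items():
        s = _as_year_series(s)
        if axes is None:
            axes = s.index
        elif not axes.equals(s.index):
            raise ValueError("all series must share one year axis")
        slopes[name], _ = linear_trend(s)
    total = sum(slopes.values())
    if total == 0:
        raise ValueError("sum of slopes is zero; trend shares undefined")
    shares = pd.Series({k: v / total for k, v in slopes.items()})
    return ContributionTable(shares=shares, metric="trend", period=period)


def driver_variance_partition(
    gpp_anomaly: AnomalySeries | pd.Series,
    driver_anomalies: Mapping[str, AnomalySeries | pd.Series],
) -> pd.Series:
    """Sequential incremental-R^2 partition of GPP variance across drivers.

    Drivers enter in the mapping's order (precipitation first by
    convention); each is credited with the R^2 increase from adding it to
    the regression, and the remainder is reported as ``unexplained``.
    Fractions sum to one.  Near-collinear drivers can receive ~0 increments
    (warning, not an error).
    """
    if len(driver_anomalies) < 2:
        raise ValueError("need at least 2 drivers")
    y = _as_year_series(gpp_anomaly)
    cols = {k: _as_year_series(v) for k, v in driver_anomalies.items()}
    df = pd.DataFrame(cols)
    if not df.index.equals(y.index):
        raise ValueError("driver series must share the GPP year axis")
    yv = y.values - y.values.mean()
    tss = float(yv @ yv)
    if tss == 0:
        raise ValueError("GPP anomaly has zero variance")
    fractions: dict[str, float] = {}
    X = np.ones((len(y), 1))
    prev_r2 = 0.0
    for name in df.columns:
        X = np.column_stack([X, df[name].values])
        beta, _, rank, _ = np.linalg.lstsq(X, y.values, rcond=None)
        if rank < X.shape[1]:
            warnings.warn(f"driver {name} is collinear with earlier drivers")
        resid = y.values - X @ beta
        r2 = 1.0 - float(resid @ resid) / tss
        fractions[name] = max(r2 - prev_r2, 0.0)
        prev_r2 = max(r2, prev_r2)
    fractions["unexplained"] = 1.0 - prev_r2
    return pd.Series(fractions)


def validate_sites(
    grid_gpp: xr.DataArray, sites: Sequence
) -> list[SiteComparison]:
    """RMSE and OLS R^2 between gridded and tower annual GPP per site.

    The grid value is taken from the cell nearest the site coordinate;
    RMSE = sqrt(mean((GPP_site - GPP_grid)^2)) over the paired years.
    """
    from .synthetic_data import site_gpp  # local import to avoid a cycle

    lat_v = grid_gpp.lat.values
    lon_v = grid_gpp.lon.values
    res_lat = np.abs(np.diff(lat_v)).max() if lat_v.size > 1 else 1.0
    res_lon = np.abs(np.diff(lon_v)).max() if lon_v.size > 1 else 1.0
    out = []
    for s in sites:
        if not (lat_v.min() - res_lat <= s.lat <= lat_v.max() + res_lat) or not (
            lon_v.min() - res_lon <= s.lon <= lon_v.max() + res_lon
        ):
            raise ValueError(f"site {s.site_id} lies outside the grid")
        cell = grid_gpp.sel(lat=s.lat, lon=s.lon, method="nearest")
        years = np.intersect1d(s.years, cell.time.values)
        if years.size < 2:
            raise ValueError(f"site {s.site_id}: need >= 2 paired years")
        g_site = site_gpp(s)[np.isin(s.years, years)]
        g_grid = cell.sel(time=years).values
        diff = g_site - g_grid
        rmse = float(np.sqrt(np.mean(diff**2)))
        if np.std(g_site) == 0 or np.std(g_grid) == 0:
            r2 = 1.0 if rmse == 0 else 0.0
        else:
            r2 = float(stats.linregress(g_site, g_grid).rvalue ** 2)
        out.append(SiteComparison(site_id=s.site_id, n=years.size, r2=r2, rmse=rmse))
    return out
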