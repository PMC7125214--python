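"""Aridity index, dryland classification, and area-weighted aggregation.

The aridity index AI = P/PET partitions land into five classes:

    hyperarid   AI <= 0.05
    arid        0.05 < AI <= 0.2
    semiarid    0.2 < AI <= 0.5
    subhumid    0.5 < AI < 0.65
    humid       AI >= 0.65

Drylands are the union of the first four classes.  Boundary values map
exactly as the printed inequalities: AI = 0.05 is hyperarid, 0.2 arid,
0.5 semiarid, and 0.65 humid.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

__all__ = [
    "SUBTYPE_NAMES",
    "DRYLAND_THRESHOLD",
    "penman_monteith_pet",
    "aridity_index",
    "classify_subtype",
    "dryland_mask",
    "cell_areas",
    "aggregate_total",
]

#: Class names in increasing AI order; integer codes 0..4.
SUBTYPE_NAMES = ("hyperarid", "arid", "semiarid", "subhumid", "humid")

#: AI at and above which land is humid (not dryland).
DRYLAND_THRESHOLD = 0.65

_CLASS_EDGES = np.array([0.05, 0.2, 0.5])

_EARTH_RADIUS_KM = 6371.0088

# FAO-56 psychrometric constant at standard sea-level pressure, kPa degC^-1.
_GAMMA = 0.0665


def penman_monteith_pet(
    net_radiation,
    soil_heat_flux,
    tair,
    wind_speed,
    e_sat,
    e_act,
    annual: bool = True,
    gamma: float = _GAMMA,
):
    """FAO-56 reference-crop potential evapotranspiration.

    Parameters are daily means: net radiation and soil heat flux in
    MJ m^-2 d^-1, air temperature in degC, wind speed at 2 m in m s^-1,
    saturation and actual vapour pressure in kPa.  Returns PET in mm yr^-1
    (daily rate x 365) by default, or mm d^-1 with ``annual=False``.
    Output is floored at zero (condensation is not "negative demand").
    """
    net_radiation = np.asarray(net_radiation, dtype=float)
    soil_heat_flux = np.asarray(soil_heat_flux, dtype=float)
    tair = np.asarray(tair, dtype=float)
    wind_speed = np.asarray(wind_speed, dtype=float)
    e_sat = np.asarray(e_sat, dtype=float)
    e_act = np.asarray(e_act, dtype=float)
    if np.any(e_act > e_sat):
        raise ValueError("actual vapour pressure exceeds saturation")
    if np.any(wind_speed < 0):
        raise ValueError("wind speed must be >= 0")

    # Slope of the saturation vapour-pressure curve, kPa degC^-1.
    delta = (
        4098.0
        * (0.6108 * np.exp(17.27 * tair / (tair + 237.3)))
        / (tair + 237.3) ** 2
    )
    num = 0.408 * delta * (net_radiation - soil_heat_flux) + gamma * (
        900.0 / (tair + 273.0)
    ) * wind_speed * (e_sat - e_act)
    den = delta + gamma * (1.0 + 0.34 * wind_speed)
    daily = np.maximum(num / den, 0.0)
    out = daily * 365.0 if annual else daily
    return out if out.ndim else float(out)


def aridity_index(p_annual, pet_annual):
    """AI = P/PET elementwise; cells with PET <= 0 become NaN (invalid).

    Accepts scalars, arrays or DataArrays; preserves xarray metadata.
    """
    is_xr = isinstance(p_annual, xr.DataArray)
    p = np.asarray(p_annual.values if is_xr else p_annual, dtype=float)
    pet = np.asarray(
        pet_annual.values if isinstance(pet_annual, xr.DataArray) else pet_annual,
        dtype=float,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(pet > 0, p / np.where(pet > 0, pet, 1.0), np.nan)
    if is_xr:
        return xr.DataArray(ai, coords=p_annual.coords, dims=p_annual.dims, name="ai")
    return ai if ai.ndim else float(ai)


def classify_subtype(ai_climatology) -> xr.DataArray | np.ndarray:
    """Map an AI climatology to integer class codes 0..4.

    NaN cells (invalid AI) are coded -1 and excluded from any partition.
    Negative AI raises, since AI = P/PET cannot be negative.
    """
    is_xr = isinstance(ai_climatology, xr.DataArray)
    ai = np.asarray(
        ai_climatology.values if is_xr else ai_climatology, dtype=float
    )
    valid = np.isfinite(ai)
    if np.any(ai[valid] < 0):
        raise ValueError("AI must be >= 0")
    # searchsorted with side='left' puts the closed-right boundaries
    # (0.05, 0.2, 0.5) into the lower class, exactly as printed.
    codes = np.searchsorted(_CLASS_EDGES, ai, side="left")
    codes = np.where(ai >= DRYLAND_THRESHOLD, 4, codes)
    codes = np.where(valid, codes, -1).astype(np.int8)
    if is_xr:
        out = xr.DataArray(
            codes,
            coords=ai_climatology.coords,
            dims=ai_climatology.dims,
            name="subtype",
        )
        out.attrs["flag_values"] = list(range(5))
        out.attrs["flag_meanings"] = " ".join(SUBTYPE_NAMES)
        return out
    return codes if codes.ndim else int(codes)


def dryland_mask(subtype) -> xr.DataArray | np.ndarray:
    """Boolean mask of dryland cells (any class below humid)."""
    codes = subtype.values if isinstance(subtype, xr.DataArray) else np.asarray(subtype)
    mask = (codes >= 0) & (codes < 4)
    if isinstance(subtype, xr.DataArray):
        return xr.DataArray(
            mask, coords=subtype.coords, dims=subtype.dims, name="dryland"
        )
    return mask


def cell_areas(lats, resolution: float) -> np.ndarray | xr.DataArray:
    """Spherical surface area (km^2) of each grid cell, per latitude row.

    Exact integral of cos(lat) over the cell's latitude bounds, so areas on
    a symmetric grid are hemispherically symmetric and sum exactly.
    Returns a (lat,) vector; broadcast against lon as needed.
    """
    is_xr = isinstance(lats, xr.DataArray)
    lat_c = np.asarray(lats.values if is_xr else lats, dtype=float)
    half = resolution / 2.0
    lat1 = np.radians(lat_c - half)
    lat2 = np.radians(lat_c + half)
    dlon = np.radians(resolution)
    area = _EARTH_RADIUS_KM**2 * dlon * (np.sin(lat2) - np.sin(lat1))
    if is_xr:
        return xr.DataArray(area, coords=lats.coords, dims=lats.dims, name="cell_area")
    return area


def _area_grid(arr: xr.DataArray, areas) -> np.ndarray:
    """Broadcast a per-latitude area vector to the (lat, lon) grid of arr."""
    a = np.asarray(areas.values if isinstance(areas, xr.DataArray) else areas)
    if a.ndim == 1:
        a = np.broadcast_to(a[:, None], (arr.sizes["lat"], arr.sizes["lon"]))
    if a.shape != (arr.sizes["lat"], arr.sizes["lon"]):
        raise ValueError("area grid does not match the field's lat/lon shape")
    return a


def aggregate_total(gpp_grid: xr.DataArray, mask, areas) -> float | xr.DataArray:
    """Total GPP (Pg C yr^-1) over masked cells.

    gpp is kg C m^-2 yr^-1, area km^2; 1 km^2 = 1e6 m^2 and 1 Pg = 1e12 kg,
    so total [Pg] = sum(gpp * area) * 1e-6.  Linear in gpp and additive over
    disjoint masks.  With a time axis, returns the per-year series.
    """
    m = np.asarray(mask.values if isinstance(mask, xr.DataArray) else mask, dtype=bool)
    if m.shape != (gpp_grid.sizes["lat"], gpp_grid.sizes["lon"]):
        raise ValueError("mask does not match the field's lat/lon shape")
    a = _area_grid(gpp_grid, areas)
    weighted = np.where(m, a, 0.0) * 1e-6
    vals = np.nan_to_num(gpp_grid.values, nan=0.0)
    total = np.tensordot(vals, weighted, axes=([-2, -1], [0, 1]))
    if "time" in gpp_grid.dims:
        return xr.DataArray(
            total, coords={"time": gpp_grid.time}, dims=("time",), name="gpp_total"
        )
    return float(total)
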