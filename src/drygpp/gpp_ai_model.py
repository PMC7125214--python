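"""Per-region polynomial GPP-AI response curves, intervals, and projection.

One polynomial is fitted per dryland region between per-area GPP
(kg C m^-2 yr^-1) and the aridity index over AI in (0, 0.65).  The fit
stores the design cross-product inverse so out-of-sample 95% prediction
intervals (t-distribution) can be evaluated anywhere in the domain, and a
projected AI series then drives the curves to produce regional and global
GPP totals with uncertainty bands.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .aridity import DRYLAND_THRESHOLD, aggregate_total

__all__ = [
    "PolyFit",
    "ProjectionResult",
    "fit_gpp_ai",
    "predict_gpp",
    "bias_correct",
    "project_regional_gpp",
]

log = logging.getLogger(__name__)

AI_DOMAIN = (0.0, DRYLAND_THRESHOLD)


@dataclass
class PolyFit:
    """A fitted per-region GPP(AI) polynomial with interval machinery.

    coef are ascending-power coefficients; xtx_inv is (X'X)^-1 for the
    Vandermonde design, which together with resid_sd and n is sufficient to
    evaluate prediction/confidence intervals at any AI in the domain.
    """

    region: str
    degree: int
    coef: np.ndarray
    resid_sd: float
    n: int
    xtx_inv: np.ndarray
    domain: tuple[float, float] = AI_DOMAIN
    n_rejected: int = 0
    ai_mean: float = float("nan")

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.xtx_inv = np.asarray(self.xtx_inv, dtype=float)
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.resid_sd < 0:
            raise ValueError("residual sd must be >= 0")

    @property
    def dof(self) -> int:
        return self.n - (self.degree + 1)

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "degree": self.degree,
            "coef": self.coef.tolist(),
            "resid_sd": self.resid_sd,
            "n": self.n,
            "xtx_inv": self.xtx_inv.tolist(),
            "domain": list(self.domain),
            "n_rejected": self.n_rejected,
            "ai_mean": self.ai_mean,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PolyFit":
        d = dict(d)
        d["domain"] = tuple(d.get("domain", AI_DOMAIN))
        return cls(**d)


@dataclass
class ProjectionResult:
    """Regional (or global) projected GPP totals with a 95% band, Pg C yr^-1."""

    region: str
    years: np.ndarray
    central: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    scenario: str = "rcp45"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        for name in ("central", "lower", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not ((self.lower <= self.central + 1e-12).all()
                and (self.central <= self.upper + 1e-12).all()):
            raise ValueError("band must satisfy lower <= central <= upper")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region,
                "year": self.years,
                "gpp_PgC_yr": self.central,
                "lower95": self.lower,
                "upper95": self.upper,
                "scenario": self.scenario,
            }
        )


def _vander(x: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(x, degree + 1, increasing=True)


def fit_gpp_ai(
    ai_samples,
    gpp_samples,
    degree_policy: int | str = "aicc",
    max_degree: int = 4,
    region: str = "",
) -> PolyFit:
    """Least-squares polynomial fit of GPP against AI for one region.

    degree_policy is either a fixed integer degree or ``"aicc"``, which
    picks the degree in 2..max_degree minimising the small-sample-corrected
    Akaike criterion.  Samples with AI outside [0, 0.65) are rejected and
    counted in ``n_rejected``.
    """
    ai = np.asarray(ai_samples, dtype=float).ravel()
    gpp = np.asarray(gpp_samples, dtype=float).ravel()
    if ai.shape != gpp.shape:
        raise ValueError("ai and gpp samples must align")
    ok = np.isfinite(ai) & np.isfinite(gpp)
    in_dom = ok & (ai >= AI_DOMAIN[0]) & (ai < AI_DOMAIN[1])
    n_rejected = int(ok.sum() - in_dom.sum())
    if n_rejected:
        log.info("%s: rejected %d samples outside AI domain", region or "fit",
                 n_rejected)
    ai, gpp = ai[in_dom], gpp[in_dom]

    if isinstance(degree_policy, int):
        degrees = [degree_policy]
    elif degree_policy == "aicc":
        degrees = list(range(2, max_degree + 1))
    else:
        raise ValueError(f"unknown degree_policy {degree_policy!r}")

    best = None
    for deg in degrees:
        p = deg + 1
        n = ai.size
        if n < p + 1:
            continue
        X = _vander(ai, deg)
        if np.linalg.matrix_rank(X) < p:
            continue
        coef, _, _, _ = np.linalg.lstsq(X, gpp, rcond=None)
        resid = gpp - X @ coef
        rss = float(resid @ resid)
        k = p + 1  # coefficients + error variance
        if n - k - 1 <= 0:
            continue
        aicc = n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        if best is None or aicc < best[0]:
            best = (aicc, deg, coef, rss, X)
    if best is None:
        raise ValueError(
            "rank-deficient or undersized design: need >= degree+2 distinct "
            "AI samples inside the domain"
        )
    _, deg, coef, rss, X = best
    p = deg + 1
    dof = ai.size - p
    resid_sd = float(np.sqrt(rss / dof)) if dof > 0 else 0.0
    xtx_inv = np.linalg.pinv(X.T @ X)
    return PolyFit(
        region=region,
        degree=deg,
        coef=coef,
        resid_sd=resid_sd,
        n=ai.size,
        xtx_inv=xtx_inv,
        n_rejected=n_rejected,
        ai_mean=float(ai.mean()),
    )


def predict_gpp(
    fit: PolyFit,
    ai,
    interval: str = "prediction",
    alpha: float = 0.05,
    clip_zero: bool = True,
):
    """Central GPP and 95% band at the given AI values.

    AI outside the open fit domain (0, 0.65) is excluded: those entries come
    back NaN and are logged.  ``interval`` selects the out-of-sample
    prediction interval (default, the projection-uncertainty case) or the
    confidence interval for the mean curve.  All three outputs are floored
    at zero when ``clip_zero`` (per-area GPP cannot be negative); flooring
    is monotone so lower <= central <= upper is preserved.
    """
    if interval not in ("prediction", "confidence"):
        raise ValueError("interval must be 'prediction' or 'confidence'")
    ai_arr = np.asarray(ai, dtype=float)
    scalar = ai_arr.ndim == 0
    ai_flat = np.atleast_1d(ai_arr).ravel().astype(float)
    valid = (ai_flat > fit.domain[0]) & (ai_flat < fit.domain[1])
    n_out = int((~valid & np.isfinite(ai_flat)).sum())
    if n_out:
        log.info("%s: %d AI values outside (%.2f, %.2f) excluded",
                 fit.region or "fit", n_out, *fit.domain)

    central = np.full(ai_flat.shape, np.nan)
    half = np.full(ai_flat.shape, np.nan)
    V = _vander(ai_flat[valid], fit.degree)
    central[valid] = V @ fit.coef
    if fit.resid_sd == 0 or fit.dof <= 0:
        half[valid] = 0.0
    else:
        tcrit = stats.t.ppf(1 - alpha / 2, fit.dof)
        lev = np.einsum("ij,jk,ik->i", V, fit.xtx_inv, V)
        extra = 1.0 if interval == "prediction" else 0.0
        half[valid] = tcrit * fit.resid_sd * np.sqrt(extra + lev)
    lower, upper = central - half, central + half
    if clip_zero:
        central = np.maximum(central, 0.0)
        lower = np.maximum(lower, 0.0)
        upper = np.maximum(upper, 0.0)
    shape = ai_arr.shape
    out = tuple(a.reshape(shape) for a in (central, lower, upper))
    if scalar:
        return tuple(float(a) for a in out)
    return out


def bias_correct(
    raw_series: pd.Series,
    reference_series: pd.Series,
    overlap_window: tuple[int, int] | None = None,
) -> pd.Series:
    """Affine (mean/variance-matching) correction of a model series.

    The mapping is estimated on the overlap years (>= 5 required) and
    applied to the whole raw series, so the corrected series has exactly the
    reference mean and variance over the overlap.  A zero-variance raw
    series gets a mean-only shift with a warning.
    """
    idx = raw_series.index.intersection(reference_series.index)
    if overlap_window is not None:
        lo, hi = overlap_window
        idx = idx[(idx >= lo) & (idx <= hi)]
    if len(idx) < 5:
        raise ValueError("need at least 5 overlapping years")
    r = raw_series.loc[idx].astype(float)
    ref = reference_series.loc[idx].astype(float)
    s_raw = float(r.std(ddof=1))
    s_ref = float(ref.std(ddof=1))
    if s_raw == 0:
        warnings.warn("zero-variance raw series; applying mean-only correction")
        scale = 1.0
    else:
        scale = s_ref / s_raw
    return (raw_series.astype(float) - r.mean()) * scale + ref.mean()


def project_regional_gpp(
    fits: Mapping[str, PolyFit],
    ai_projection: xr.DataArray,
    region_mask: xr.DataArray,
    areas,
    scenario: str = "rcp45",
    interval: str = "prediction",
) -> dict[str, ProjectionResult]:
    """Drive the fitted curves with a projected AI series.

    Per year and per cell with AI inside (0, 0.65) — the dryland domain the
    curves were fitted on — evaluate central/lower/upper per-area GPP, then
    aggregate with cell areas to regional totals (Pg C yr^-1).  The band is
    summed cell-wise (no independence assumption), which is conservative
    for the total.  The global projection is the exact sum of the regional
    ones.
    """
    years = ai_projection.time.values
    region_codes = region_mask.values
    present = [c for c in np.unique(region_codes) if c > 0]
    names = region_mask.attrs.get("flag_meanings", "").split()
    if len(names) != len(region_mask.attrs.get("flag_values", names)):
        raise ValueError("region mask must carry flag_values/flag_meanings")
    code_to_name = dict(zip(region_mask.attrs["flag_values"], names))

    results: dict[str, ProjectionResult] = {}
    nyears = years.size
    glob = {k: np.zeros(nyears) for k in ("central", "lower", "upper")}
    template = xr.DataArray(
        np.zeros((nyears,) + region_codes.shape),
        coords=ai_projection.coords,
        dims=ai_projection.dims,
    )
    for code in present:
        name = code_to_name[int(code)]
        if name not in fits:
            raise ValueError(f"no fit for region {name}")
        fit = fits[name]
        sel = region_codes == code
        ai_cells = ai_projection.values[:, sel]  # (time, ncells)
        central, lower, upper = predict_gpp(fit, ai_cells, interval=interval)
        series = {}
        for key, arr in (("central", central), ("lower", lower), ("upper", upper)):
            grid = template.copy(deep=True)
            vals = np.zeros_like(grid.values)
            filled = np.nan_to_num(arr, nan=0.0)  # excluded cells contribute 0
            vals[:, sel] = filled
            grid.values = vals
            series[key] = np.asarray(
                aggregate_total(grid, np.ones_like(sel, dtype=bool), areas).values
            )
        results[name] = ProjectionResult(
            region=name, years=years, scenario=scenario, **series
        )
        for k in glob:
            glob[k] += series[k]
    results["GLOBAL"] = ProjectionResult(
        region="GLOBAL", years=years, scenario=scenario, **glob
    )
    return results
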