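"""Anomalies, trends, IAV, contribution indices, drivers, site validation."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from drygpp.synthetic_data import SiteFluxSeries
from drygpp.variability import (
    AnomalySeries,
    annual_anomaly,
    contribution_iav,
    contribution_trend,
    driver_variance_partition,
    iav,
    linear_trend,
    validate_sites,
)


def _anom(values, entity="x", years=None, mode="mean_removed"):
    values = np.asarray(values, float)
    years = np.arange(2000, 2000 + values.size) if years is None else years
    return AnomalySeries(entity=entity, years=years, values=values, mode=mode)


class TestAnomalies:
    def test_constant_series_all_zero_both_modes(self):
        s = pd.Series(7.0, index=np.arange(2000, 2010))
        for mode in ("mean_removed", "trend_removed"):
            assert np.allclose(annual_anomaly(s, mode).values, 0.0)

    def test_linear_series_detrends_to_zero(self):
        t = np.arange(2000, 2015)
        s = pd.Series(2.0 * t + 7, index=t)
        assert np.allclose(annual_anomaly(s, "trend_removed").values, 0.0, atol=1e-8)

    def test_mean_removed_sums_to_zero(self, rng):
        s = pd.Series(rng.normal(size=15), index=np.arange(2000, 2015))
        assert annual_anomaly(s, "mean_removed").values.sum() == pytest.approx(0, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            annual_anomaly(pd.Series([1.0, 2.0], index=[2000, 2001]))


class TestTrend:
    def test_exact_line(self):
        t = np.arange(2000, 2020)
        slope, p = linear_trend(pd.Series(2.0 * t + 7, index=t))
        assert slope == pytest.approx(2.0)
        assert p < 1e-12

    def test_constant_series(self):
        slope, p = linear_trend(pd.Series(3.0, index=np.arange(2000, 2010)))
        assert slope == 0.0
        assert p == 1.0

    def test_additivity_of_slopes(self, rng):
        t = np.arange(2000, 2020)
        a = pd.Series(rng.normal(size=20), index=t)
        b = pd.Series(rng.normal(size=20), index=t)
        sa, _ = linear_trend(a)
        sb, _ = linear_trend(b)
        st_, _ = linear_trend(a + b)
        assert st_ == pytest.approx(sa + sb, abs=1e-12)


class TestIav:
    def test_arithmetic(self):
        assert iav(_anom([1, -1, 2, -2])) == 1.5
        assert iav(_anom([0, 0, 0])) == 0.0

    @given(st.floats(-5, 5), st.lists(st.floats(-10, 10), min_size=3, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_absolute_homogeneity(self, c, xs):
        x = np.asarray(xs)
        assert iav(_anom(c * x)) == pytest.approx(abs(c) * iav(_anom(x)), rel=1e-9, abs=1e-12)

    def test_triangle_inequality_regional_vs_global(self, rng):
        parts = [_anom(rng.normal(size=12), entity=str(i)) for i in range(4)]
        glob = _anom(np.sum([p.values for p in parts], axis=0), entity="G")
        assert iav(glob) <= sum(iav(p) for p in parts) + 1e-12


class TestContributionIav:
    def test_single_region_equals_global(self, rng):
        x = rng.normal(size=10)
        t = contribution_iav([_anom(x, "only")], _anom(x, "G"))
        assert t.shares["only"] == pytest.approx(1.0)

    def test_hand_example(self):
        """x1=[2,-1], x2=[0,-1] -> X=[2,-2]; f1=(2*1 + (-1)*(-1))/4 = 0.75."""
        years = np.array([2000, 2001])
        r1 = _anom([2.0, -1.0], "r1", years)
        r2 = _anom([0.0, -1.0], "r2", years)
        g = _anom([2.0, -2.0], "G", years)
        t = contribution_iav([r1, r2], g)
        assert t.shares["r1"] == pytest.approx(0.75)
        assert t.shares["r2"] == pytest.approx(0.25)

    def test_incomplete_partition_rejected(self, rng):
        x = rng.normal(size=8)
        with pytest.raises(ValueError):
            contribution_iav([_anom(x, "a"), _anom(x, "b")], _anom(x, "G"))

    def test_zero_global_year_excluded_with_warning(self):
        years = np.arange(2000, 2003)
        r1 = _anom([1.0, -1.0, 2.0], "a", years)
        r2 = _anom([-1.0, 1.0, 1.0], "b", years)
        g = _anom([0.0, 0.0, 3.0], "G", years)
        with pytest.warns(UserWarning):
            t = contribution_iav([r1, r2], g)
        assert t.shares.sum() == pytest.approx(1.0)
        assert t.shares["a"] == pytest.approx(2.0 / 3.0)

    @given(
        n_regions=st.integers(2, 8),
        n_years=st.integers(3, 20),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_shares_sum_to_one_for_any_partition(self, n_regions, n_years, seed):
        rng = np.random.default_rng(seed)
        years = np.arange(2000, 2000 + n_years)
        M = rng.normal(size=(n_regions, n_years))
        X = M.sum(axis=0)
        if np.any(X == 0):  # measure-zero; regenerate deterministically
            X = X + 1e-9
            M[0] += 1e-9 / 1
        regional = [_anom(M[i], f"r{i}", years) for i in range(n_regions)]
        t = contribution_iav(regional, _anom(X, "G", years))
        assert t.shares.sum() == pytest.approx(1.0, abs=1e-12)


class TestContributionTrend:
    def test_single_trending_region_gets_all(self, rng):
        t = np.arange(2000, 2015)
        series = {
            "up": pd.Series(0.5 * t, index=t),
            "flat": pd.Series(3.0 + rng.normal(0, 1e-9, t.size), index=t),
        }
        tab = contribution_trend(series)
        assert tab.shares["up"] == pytest.approx(1.0, abs=1e-6)

    def test_ratio_arithmetic(self):
        t = np.arange(2000, 2010)
        tab = contribution_trend(
            {"a": pd.Series(3.0 * t, index=t), "b": pd.Series(1.0 * t, index=t)}
        )
        assert tab.shares["a"] == pytest.approx(0.75)
        assert tab.shares["b"] == pytest.approx(0.25)
        assert tab.shares.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_trend_undefined(self):
        t = np.arange(2000, 2010)
        with pytest.raises(ValueError):
            contribution_trend(
                {"a": pd.Series(1.0 * t, index=t), "b": pd.Series(-1.0 * t, index=t)}
            )


class TestDriverPartition:
    def test_gpp_equal_to_precip_fully_explained(self, rng):
        t = np.arange(2000, 2030)
        p = pd.Series(rng.normal(size=30), index=t)
        temp = pd.Series(rng.normal(size=30), index=t)
        fr = driver_variance_partition(p, {"precip": p, "tair": temp})
        assert fr["precip"] == pytest.approx(1.0, abs=1e-10)
        assert fr["tair"] == pytest.approx(0.0, abs=1e-10)
        assert fr.sum() == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_drivers_recover_variance_shares(self, rng):
        n = 20_000
        t = np.arange(n)
        d1 = rng.normal(size=n)
        d2 = rng.normal(size=n)
        y = 2.0 * d1 + 1.0 * d2 + rng.normal(0, 1.0, n)
        tot = 4.0 + 1.0 + 1.0
        fr = driver_variance_partition(
            pd.Series(y, index=t),
            {"d1": pd.Series(d1, index=t), "d2": pd.Series(d2, index=t)},
        )
        assert fr["d1"] == pytest.approx(4.0 / tot, abs=0.02)
        assert fr["d2"] == pytest.approx(1.0 / tot, abs=0.02)
        assert fr["unexplained"] == pytest.approx(1.0 / tot, abs=0.02)

    def test_invariant_to_driver_rescaling(self, rng):
        t = np.arange(2000, 2040)
        d1 = pd.Series(rng.normal(size=40), index=t)
        d2 = pd.Series(rng.normal(size=40), index=t)
        y = d1 + 0.5 * d2 + pd.Series(rng.normal(0, 0.3, 40), index=t)
        a = driver_variance_partition(y, {"p": d1, "t": d2})
        b = driver_variance_partition(y, {"p": 100 * d1, "t": 0.01 * d2})
        pd.testing.assert_series_equal(a, b, atol=1e-10, rtol=0)


def _grid_from(values, lats, lons, years):
    return xr.DataArray(
        values,
        coords={"time": years, "lat": lats, "lon": lons},
        dims=("time", "lat", "lon"),
        name="gpp",
    )


class TestValidateSites:
    def _setup(self, rng, offset=0.0):
        years = np.arange(2000, 2010)
        lats = np.array([0.25, 0.75])
        lons = np.array([0.25, 0.75])
        g = rng.uniform(0.2, 1.0, size=(10, 2, 2))
        grid = _grid_from(g, lats, lons, years)
        gpp_site = g[:, 0, 0] - offset
        reco = np.full(10, 0.4)
        site = SiteFluxSeries(
            "S", years, nee=gpp_site + reco, reco=reco, biome="SAV",
            lat=0.25, lon=0.25,
        )
        return grid, site

    def test_identical_series(self, rng):
        grid, site = self._setup(rng)
        (c,) = validate_sites(grid, [site])
        assert c.rmse == pytest.approx(0.0, abs=1e-12)
        assert c.r2 == pytest.approx(1.0)

    def test_constant_offset_separates_bias_from_correlation(self, rng):
        grid, site = self._setup(rng, offset=0.3)
        (c,) = validate_sites(grid, [site])
        assert c.rmse == pytest.approx(0.3, abs=1e-12)
        assert c.r2 == pytest.approx(1.0)

    def test_rmse_matches_loop_oracle(self, rng):
        grid, site = self._setup(rng)
        site.nee = site.nee + rng.normal(0, 0.1, site.nee.size)
        (c,) = validate_sites(grid, [site])
        gs = site.nee - site.reco
        gg = grid.values[:, 0, 0]
        acc = 0.0
        for t in range(10):
            acc += (gs[t] - gg[t]) ** 2
        assert c.rmse == pytest.approx(np.sqrt(acc / 10), abs=1e-12)

    def test_site_outside_grid_rejected(self, rng):
        grid, site = self._setup(rng)
        site.lat = 55.0
        with pytest.raises(ValueError):
            validate_sites(grid, [site])
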