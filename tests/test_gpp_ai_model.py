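"""Polynomial GPP-AI fits, intervals, bias correction, and projection."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from numpy.polynomial import polynomial as npoly

from drygpp import aridity, gpp_ai_model, pipeline, synthetic_data
from drygpp.gpp_ai_model import bias_correct, fit_gpp_ai, predict_gpp
from drygpp.synthetic_data import REGION_CODES, ScenarioConfig


class TestFit:
    def test_exact_line_interpolated(self):
        ai = np.linspace(0.05, 0.6, 20)
        f = fit_gpp_ai(ai, 2 + 3 * ai, degree_policy=1)
        assert f.coef == pytest.approx([2.0, 3.0], abs=1e-10)
        assert f.resid_sd == pytest.approx(0.0, abs=1e-10)

    def test_duplicating_samples_leaves_coefficients_unchanged(self, rng):
        ai = rng.uniform(0.01, 0.64, 60)
        y = 0.1 + ai + rng.normal(0, 0.05, 60)
        f1 = fit_gpp_ai(ai, y, degree_policy=2)
        f2 = fit_gpp_ai(np.r_[ai, ai], np.r_[y, y], degree_policy=2)
        assert f2.coef == pytest.approx(f1.coef, rel=1e-8)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            fit_gpp_ai(np.full(30, 0.3), np.ones(30), degree_policy=2)

    def test_out_of_domain_samples_counted(self):
        ai = np.r_[np.linspace(0.05, 0.6, 30), [0.7, 0.9, 1.2]]
        y = np.r_[np.linspace(0.1, 0.9, 30), [1.0, 1.0, 1.0]]
        f = fit_gpp_ai(ai, y, degree_policy=2)
        assert f.n == 30 and f.n_rejected == 3

    def test_noise_free_recovery_to_1e6(self):
        """The generator round-trip with noise -> 0 recovers the true curve."""
        cfg = ScenarioConfig(seed=3, noise_scale=0.0)
        ai = synthetic_data.baseline_ai(cfg)
        gpp = synthetic_data.generate_gpp_from_ai(ai, cfg)
        regions = synthetic_data.region_mask(cfg).values
        for i, code in enumerate(REGION_CODES, start=1):
            truth = np.asarray(cfg.region_coeffs[code])
            sel = regions == i
            f = fit_gpp_ai(ai.values[sel], gpp.values[sel],
                           degree_policy=truth.size - 1, region=code)
            rel = np.abs(f.coef - truth) / np.abs(truth)
            assert np.all(rel <= 1e-6)

    def test_monte_carlo_recovery_within_3se(self, rng):
        truth = np.array([0.05, 0.9, 0.3, 0.4])  # cubic
        hits = 0
        for _ in range(50):
            ai = rng.uniform(0.01, 0.64, 500)
            y = npoly.polyval(ai, truth) + rng.normal(0, 0.05, 500)
            f = fit_gpp_ai(ai, y, degree_policy=3)
            se = f.resid_sd * np.sqrt(np.diag(f.xtx_inv))
            hits += np.all(np.abs(f.coef - truth) <= 3 * se)
        assert hits >= 45

    def test_serialization_roundtrip(self, rng):
        ai = rng.uniform(0.01, 0.64, 100)
        f = fit_gpp_ai(ai, 0.1 + ai**2 + rng.normal(0, 0.02, 100), region="AUS")
        g = gpp_ai_model.PolyFit.from_dict(f.to_dict())
        c1 = predict_gpp(f, np.array([0.1, 0.3, 0.6]))
        c2 = predict_gpp(g, np.array([0.1, 0.3, 0.6]))
        for a, b in zip(c1, c2):
            np.testing.assert_allclose(a, b)


class TestPredict:
    def test_zero_residual_band_collapses(self):
        ai = np.linspace(0.05, 0.6, 20)
        f = fit_gpp_ai(ai, 2 + 3 * ai, degree_policy=1)
        c, lo, hi = predict_gpp(f, np.array([0.1, 0.5]))
        np.testing.assert_allclose(lo, c)
        np.testing.assert_allclose(hi, c)

    def test_band_narrowest_at_sample_mean(self, rng):
        ai = rng.uniform(0.05, 0.6, 200)
        y = 0.2 + ai + rng.normal(0, 0.05, 200)
        f = fit_gpp_ai(ai, y, degree_policy=1)
        grid = np.linspace(0.05, 0.6, 111)
        c, lo, hi = predict_gpp(f, grid, clip_zero=False)
        width = hi - lo
        assert abs(grid[np.argmin(width)] - ai.mean()) < 0.01

    def test_out_of_domain_excluded(self):
        ai = np.linspace(0.05, 0.6, 30)
        f = fit_gpp_ai(ai, 0.2 + ai, degree_policy=1)
        c, lo, hi = predict_gpp(f, np.array([0.3, 0.65, 0.0]))
        assert np.isfinite(c[0])
        assert np.isnan(c[1]) and np.isnan(c[2])

    def test_confidence_narrower_than_prediction(self, rng):
        ai = rng.uniform(0.05, 0.6, 100)
        f = fit_gpp_ai(ai, 0.2 + ai + rng.normal(0, 0.05, 100), degree_policy=1)
        x = np.array([0.3])
        _, lp, up = predict_gpp(f, x, interval="prediction")
        _, lc, uc = predict_gpp(f, x, interval="confidence")
        assert (uc - lc) < (up - lp)


class TestBiasCorrect:
    def _series(self, rng, n=20, start=2000):
        idx = pd.Index(np.arange(start, start + n))
        return pd.Series(rng.normal(10, 2, n), index=idx)

    def test_identity_when_already_matching(self, rng):
        ref = self._series(rng)
        out = bias_correct(ref.copy(), ref)
        pd.testing.assert_series_equal(out, ref.astype(float))

    def test_affine_family_closure(self, rng):
        ref = self._series(rng)
        raw = 2 * ref + 5
        out = bias_correct(raw, ref)
        np.testing.assert_allclose(out.values, ref.values, atol=1e-10)

    def test_overlap_moments_match_reference(self, rng):
        raw = self._series(rng, n=30, start=1995)
        ref = self._series(rng, n=20, start=2000)
        out = bias_correct(raw, ref, overlap_window=(2000, 2014))
        ov = out.loc[2000:2014]
        rv = ref.loc[2000:2014]
        assert ov.mean() == pytest.approx(rv.mean(), abs=1e-10)
        assert ov.std(ddof=1) == pytest.approx(rv.std(ddof=1), abs=1e-10)

    def test_zero_variance_mean_only_with_warning(self, rng):
        ref = self._series(rng)
        raw = pd.Series(5.0, index=ref.index)
        with pytest.warns(UserWarning):
            out = bias_correct(raw, ref)
        assert out.mean() == pytest.approx(ref.mean())

    def test_short_overlap_rejected(self, rng):
        ref = self._series(rng, n=4)
        with pytest.raises(ValueError):
            bias_correct(ref.copy(), ref)


class TestProjection:
    def test_global_equals_sum_of_regions(self, result):
        glob = result.projections["GLOBAL"]
        total = np.zeros_like(glob.central)
        for code in REGION_CODES:
            total += result.projections[code].central
        np.testing.assert_allclose(glob.central, total, rtol=1e-12)

    def test_band_brackets_central(self, result):
        for p in result.projections.values():
            assert np.all(p.lower <= p.central + 1e-12)
            assert np.all(p.central <= p.upper + 1e-12)

    def test_all_humid_region_contributes_zero(self, config):
        lats, lons = config.grid_coords()
        regions = synthetic_data.region_mask(config)
        areas = aridity.cell_areas(lats, config.resolution)
        ai = xr.DataArray(
            np.full((3, lats.size, lons.size), 0.9),
            coords={"time": [2050, 2051, 2052], "lat": lats, "lon": lons},
            dims=("time", "lat", "lon"),
        )
        # one dryland strip in region 1 only
        ai.values[:, :, :5] = 0.3
        fits = {
            code: gpp_ai_model.fit_gpp_ai(
                np.linspace(0.05, 0.6, 30), 0.2 + np.linspace(0.05, 0.6, 30),
                degree_policy=1, region=code,
            )
            for code in REGION_CODES
        }
        proj = gpp_ai_model.project_regional_gpp(fits, ai, regions, areas)
        assert np.all(proj["SAM"].central == 0)  # SAM block is entirely humid
        assert np.all(proj["NAM"].central > 0)

    def test_frozen_ai_projection_matches_baseline_totals(self, config, result):
        """Projecting with baseline AI reproduces the fitted-baseline totals."""
        lats, _ = config.grid_coords()
        areas = aridity.cell_areas(lats, config.resolution)
        base_years = result.gpp_obs.time.values
        ai_base = result.ai.sel(time=base_years)
        proj = gpp_ai_model.project_regional_gpp(
            fits=result.fits,
            ai_projection=ai_base,
            region_mask=synthetic_data.region_mask(config),
            areas=areas,
        )
        # observed totals over the same per-year dryland membership the
        # projection uses (AI inside the fit domain that year)
        dry = (ai_base.values > 0) & (ai_base.values < 0.65)
        lat_areas = np.broadcast_to(areas[:, None], dry.shape[1:])
        obs = np.array(
            [
                (result.gpp_obs.values[k][dry[k]] * lat_areas[dry[k]]).sum() * 1e-6
                for k in range(base_years.size)
            ]
        )
        np.testing.assert_allclose(proj["GLOBAL"].central, obs, rtol=0.05)

    def test_projected_trend_matches_true_curve_quadrature(self, config, result):
        """Projected global trend ~ the trend of the true curves integrated
        over the known (noise-free) AI trajectory."""
        proj_years = np.arange(2011, 2101)
        ai_proj = result.ai.sel(time=proj_years)
        lats, _ = config.grid_coords()
        areas = aridity.cell_areas(lats, config.resolution)
        # oracle: evaluate the *true* polynomials over the same AI fields
        clean = synthetic_data.true_gpp(ai_proj, config)
        dry = (ai_proj.values > 0) & (ai_proj.values < 0.65)
        oracle = np.empty(proj_years.size)
        a = np.broadcast_to(
            aridity.cell_areas(lats, config.resolution)[:, None],
            clean.shape[1:],
        )
        for k in range(proj_years.size):
            oracle[k] = (clean.values[k][dry[k]] * a[dry[k]]).sum() * 1e-6
        t = proj_years.astype(float)
        slope_oracle = np.polyfit(t, oracle, 1)[0]
        slope_proj = np.polyfit(t, result.projections["GLOBAL"].central, 1)[0]
        assert slope_proj == pytest.approx(slope_oracle, rel=0.05)

    def test_high_forcing_scenario_projects_larger_increase(self):
        """Stronger drying -> larger dryland expansion -> larger GPP gain."""
        rcp45 = pipeline.run_pipeline(ScenarioConfig(seed=11, scenario="rcp45"))
        rcp85 = pipeline.run_pipeline(ScenarioConfig(seed=11, scenario="rcp85"))
        inc45 = pipeline.end_of_century_increase(rcp45)
        inc85 = pipeline.end_of_century_increase(rcp85)
        assert inc85 > inc45 > 0
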