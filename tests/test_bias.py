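"""Bilinear regridding and empirical quantile mapping."""

import numpy as np
import pandas as pd
import pytest

from chillgrid import (GridSpec, WeatherGenConfig, apply_eqm, fit_eqm,
                       generate_baseline, regrid_bilinear, seasonal_totals)
from chillgrid.weather import DailyWeatherSeries, from_arrays


def _series_from_field(grid, field_fn, ndays=40, start="1990-01-01"):
    dates = pd.date_range(start, periods=ndays, freq="D")
    la, lo = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    base = field_fn(la, lo)[None, :, :] * np.ones((ndays, 1, 1))
    return from_arrays(grid, dates, base - 1.0, base + 1.0, "observed")


class TestRegrid:
    src = GridSpec(np.linspace(37, 42, 6), np.linspace(-9.4, -6.2, 6))
    tgt = GridSpec(np.linspace(37.3, 41.6, 5), np.linspace(-9.1, -6.5, 5))

    def test_constant_field_stays_constant(self):
        s = _series_from_field(self.src, lambda la, lo: 7.0 * np.ones_like(la))
        out = regrid_bilinear(s, self.tgt)
        np.testing.assert_allclose(out.tmax.values, 8.0, atol=1e-12)

    def test_exact_on_linear_fields(self):
        s = _series_from_field(self.src, lambda la, lo: 2 * la + 3 * lo)
        out = regrid_bilinear(s, self.tgt)
        la, lo = np.meshgrid(self.tgt.lat, self.tgt.lon, indexing="ij")
        np.testing.assert_allclose(out.tmin.values[0], 2 * la + 3 * lo - 1.0,
                                   atol=1e-9)

    def test_two_by_two_center_is_the_hand_value(self):
        src = GridSpec([40.0, 41.0], [-8.0, -7.0])
        dates = pd.date_range("1990-01-01", periods=3, freq="D")
        corners = np.array([[0.0, 1.0], [1.0, 2.0]])
        field = corners[None] * np.ones((3, 1, 1))
        s = from_arrays(src, dates, field, field + 0.5, "observed")
        out = regrid_bilinear(s, GridSpec([40.5], [-7.5]))
        assert out.tmin.values[0, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_outside_targets_use_nearest_edge(self):
        s = _series_from_field(self.src, lambda la, lo: 2 * la + 3 * lo)
        tgt = GridSpec([36.0, 40.0], [-8.0])  # 36.0 south of the source
        out = regrid_bilinear(s, tgt)
        # clamped to lat=37 row, relabelled 36.0
        assert out.tmin.values[0, 0, 0] == pytest.approx(
            2 * 37.0 + 3 * -8.0 - 1.0, abs=1e-9)

    def test_disjoint_grids_rejected(self):
        s = _series_from_field(self.src, lambda la, lo: la)
        with pytest.raises(ValueError, match="disjoint"):
            regrid_bilinear(s, GridSpec([10.0, 11.0], [50.0, 51.0]))


def _noisy(grid, seed, year_end=1994, **kw):
    cfg = WeatherGenConfig(grid=grid, year_start=1989, year_end=year_end,
                           noise_sd=2.0, seed=seed, **kw)
    return generate_baseline(cfg)


class TestFitEQM:
    grid = GridSpec([39.0, 41.0], [-8.0])

    def test_identity_when_sim_equals_obs(self):
        obs = _noisy(self.grid, seed=1)
        qm = fit_eqm(obs, obs)
        for v in ("tasmin", "tasmax"):
            np.testing.assert_allclose(qm.sim_q[v].values, qm.obs_q[v].values)

    def test_additive_shift_appears_at_every_level(self):
        obs = _noisy(self.grid, seed=2)
        shifted = DailyWeatherSeries(obs.data + 3.0, provenance="m:s")
        qm = fit_eqm(obs, shifted)
        for v in ("tasmin", "tasmax"):
            np.testing.assert_allclose(
                qm.sim_q[v].values - qm.obs_q[v].values, 3.0, atol=1e-9)

    def test_small_pool_is_an_error_naming_the_pool(self):
        grid = GridSpec([40.0], [-8.0])
        dates = pd.date_range("1990-01-01", periods=45, freq="D")
        z = np.zeros((45, 1, 1))
        s = from_arrays(grid, dates, z, z + 5, "observed")
        with pytest.raises(ValueError, match="month=2"):
            fit_eqm(s, s)

    def test_non_overlapping_periods_rejected(self):
        obs = _noisy(self.grid, seed=1, year_end=1991)
        cfg = WeatherGenConfig(grid=self.grid, year_start=1995, year_end=1999,
                               noise_sd=1.0, seed=2)
        with pytest.raises(ValueError, match="overlap"):
            fit_eqm(obs, generate_baseline(cfg))


class TestApplyEQM:
    grid = GridSpec([39.0, 41.0], [-8.0])

    def test_identity_map_returns_input(self):
        obs = _noisy(self.grid, seed=3)
        qm = fit_eqm(obs, obs)
        out = apply_eqm(qm, obs)
        np.testing.assert_allclose(out.tmax.values, obs.tmax.values, atol=1e-9)

    def test_additive_bias_removed_in_closed_form(self):
        obs = _noisy(self.grid, seed=4)
        biased = DailyWeatherSeries(obs.data + 3.0, provenance="m:s")
        qm = fit_eqm(obs, biased)
        out = apply_eqm(qm, biased)
        # inside the fitted range the transform is exactly x - 3
        np.testing.assert_allclose(out.tmax.values, obs.tmax.values, atol=1e-9)

    def test_tail_rule_shifts_instead_of_clamping(self):
        obs = _noisy(self.grid, seed=5)
        biased = DailyWeatherSeries(obs.data + 3.0, provenance="m:s")
        qm = fit_eqm(obs, biased)
        extreme = DailyWeatherSeries(biased.data + 30.0, provenance="m:s")
        out = apply_eqm(qm, extreme)
        # values far above the largest fitted quantile: still corrected by
        # the outermost-quantile offset (-3), not clamped to obs maxima
        np.testing.assert_allclose(out.tmax.values,
                                   extreme.tmax.values - 3.0, atol=1e-9)

    def test_transform_is_monotone_per_cell_month(self):
        obs = _noisy(self.grid, seed=6)
        sim = _noisy(self.grid, seed=7, bias_offset=0.0)
        sim = DailyWeatherSeries(sim.data * 1.1 + 1.0, provenance="m:s")
        qm = fit_eqm(obs, sim)
        out = apply_eqm(qm, sim)
        months = sim.dates.month.values
        for m in (1, 7):
            sel = months == m
            x = sim.tmax.values[sel, 0, 0]
            y = out.tmax.values[sel, 0, 0]
            order = np.argsort(x)
            assert np.all(np.diff(y[order]) >= -1e-9)

    def test_self_correction_restores_observed_quantiles(self):
        obs = _noisy(self.grid, seed=8)
        sim = _noisy(self.grid, seed=9)  # independent weather, same climate
        sim = DailyWeatherSeries(sim.data * 1.2, provenance="m:s")
        out = apply_eqm(fit_eqm(obs, sim), sim)
        months = obs.dates.month.values
        for m in (1, 6):
            sel = months == m
            for q in (0.1, 0.5, 0.9):
                a = np.quantile(out.tmax.values[sel, 0, 0], q)
                b = np.quantile(obs.tmax.values[sel, 0, 0], q)
                assert a == pytest.approx(b, abs=0.6)  # sampling tolerance

    def test_multiplicative_bias_corrected_on_held_out_years(self):
        """1.2x bias: after EQM the corrected held-out segment matches the
        truth to < 0.1 degC in the mean, across 20 seeds."""
        grid = GridSpec([40.0], [-8.0])
        errs = []
        for seed in range(20):
            cfg = WeatherGenConfig(grid=grid, year_start=1989, year_end=1998,
                                   noise_sd=2.0, seed=seed)
            truth = generate_baseline(cfg)
            biased = DailyWeatherSeries(truth.data * 1.2, provenance="m:s")
            obs_fit = truth.sel_years(1989, 1993)
            sim_fit = biased.sel_years(1989, 1993)
            held = apply_eqm(fit_eqm(obs_fit, sim_fit),
                             biased.sel_years(1994, 1998))
            target = truth.sel_years(1994, 1998)
            errs.append(float((held.tmax - target.tmax).mean()))
        assert np.abs(np.mean(errs)) < 0.1

    def test_grid_mismatch_rejected(self):
        obs = _noisy(self.grid, seed=1)
        qm = fit_eqm(obs, obs)
        other = _noisy(GridSpec([38.0, 40.0], [-8.0]), seed=1)
        with pytest.raises(ValueError, match="grid"):
            apply_eqm(qm, other)

    def test_roundtrip_netcdf(self, tmp_path):
        from chillgrid import QuantileMap
        obs = _noisy(self.grid, seed=1)
        qm = fit_eqm(obs, obs)
        qm.to_netcdf(tmp_path / "qm.nc")
        back = QuantileMap.from_netcdf(tmp_path / "qm.nc")
        np.testing.assert_allclose(back.levels, qm.levels)
        np.testing.assert_allclose(back.sim_q["tasmax"].values,
                                   qm.sim_q["tasmax"].values)


def test_pipeline_property_bias_corrected_chill_matches_observed():
    """+3 degC simulated bias: CP from corrected data agrees with CP from
    observations within 5% in the regional mean."""
    grid = GridSpec([39.0, 41.0], [-8.0])
    obs = _noisy(grid, seed=12)
    sim = _noisy(grid, seed=13)  # independent realization of the climate
    biased = DailyWeatherSeries(sim.data + 3.0, provenance="m:s")
    corrected = apply_eqm(fit_eqm(obs, biased), biased)
    cp_obs = seasonal_totals(obs, "chill").data.values
    cp_cor = seasonal_totals(corrected, "chill").data.values
    cp_raw = seasonal_totals(biased, "chill").data.values
    assert abs(np.nanmean(cp_cor) / np.nanmean(cp_obs) - 1) < 0.05
    # and correction matters: the raw biased series is far off
    assert abs(np.nanmean(cp_raw) / np.nanmean(cp_obs) - 1) > 0.15
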