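"""Weather generator: determinism, physicality, statistical recovery, morphing."""

import numpy as np
import pytest
from dataclasses import replace

import wheatideo as w
from wheatideo.weather import (MonthlyClimateNormals, MONTH_OF_DOY,
                               read_weather_csv, write_weather_csv)


def uniform_site(p_ww=1.0, p_wd=1.0, shape=2.0, scale=3.0, tmin=5.0, tmax=15.0,
                 t_sd=0.0, rad=10.0, rad_sd=0.0, lat=51.8, co2=364.0):
    months = tuple(MonthlyClimateNormals(
        month=m, tmin_mean=tmin, tmax_mean=tmax, t_sd=t_sd,
        p_wet_wet=p_ww, p_wet_dry=p_wd, rain_shape=shape, rain_scale=scale,
        rad_dry=rad, rad_wet=rad, rad_sd=rad_sd) for m in range(1, 13))
    return w.SiteClimateParams(site_id="X", latitude=lat, months=months, co2=co2)


class TestGeneration:
    def test_deterministic_and_consecutive(self, rr_params):
        a = w.generate_series(rr_params, 3, seed=5)
        b = w.generate_series(rr_params, 3, seed=5)
        for f in ("tmin", "tmax", "rain", "rad"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))
        assert len(a) == 3 * 365
        c = w.generate_series(rr_params, 3, seed=6)
        assert not np.array_equal(a.rain, c.rain)

    def test_physicality(self, rr_weather):
        assert np.all(rr_weather.tmax >= rr_weather.tmin)
        assert np.all(rr_weather.rain >= 0)
        assert np.all(rr_weather.rad >= 0)

    def test_no_wet_days_means_no_rain(self):
        params = uniform_site(p_ww=0.0, p_wd=0.0)
        series = w.generate_series(params, 5, seed=1)
        assert series.rain.sum() == 0.0

    def test_wet_day_amounts_match_gamma_monte_carlo_oracle(self):
        # always-wet chain, gamma(shape 2, scale 3): mean wet amount ~ 6 mm
        params = uniform_site(p_ww=1.0, p_wd=1.0, shape=2.0, scale=3.0)
        series = w.generate_series(params, 100, seed=2)
        oracle = np.random.default_rng(3).gamma(2.0, 3.0, size=10**6).mean()
        assert oracle == pytest.approx(6.0, abs=0.02)
        assert series.rain.mean() == pytest.approx(oracle, rel=0.02)

    def test_rothamsted_annual_normals_recovered(self, rr_params):
        series = w.generate_series(rr_params, 100, seed=11)
        s = w.summarize_series(series)
        assert s["t_mean_c"] == pytest.approx(9.8, abs=0.3)
        assert s["precip_mm_yr"] == pytest.approx(700, rel=0.05)
        assert s["rad_mj_day"] == pytest.approx(9.8, rel=0.05)

    def test_monthly_temperature_recovery(self, rr_params):
        series = w.generate_series(rr_params, 100, seed=12)
        t = 0.5 * (series.tmin + series.tmax)
        months = MONTH_OF_DOY[series.doy - 1]
        for m in range(1, 13):
            target = 0.5 * (rr_params.months[m - 1].tmin_mean
                            + rr_params.months[m - 1].tmax_mean)
            assert t[months == m].mean() == pytest.approx(target, abs=0.5)

    def test_bad_inputs_rejected(self, rr_params):
        with pytest.raises(ValueError, match="n_years"):
            w.generate_series(rr_params, 0, seed=1)
        with pytest.raises(ValueError, match="p_wet_wet"):
            MonthlyClimateNormals(month=1, tmin_mean=0, tmax_mean=5, t_sd=1,
                                  p_wet_wet=1.5, p_wet_dry=0.3, rain_shape=1,
                                  rain_scale=1, rad_dry=5, rad_wet=5, rad_sd=1)
        with pytest.raises(ValueError, match="tmax_mean"):
            MonthlyClimateNormals(month=1, tmin_mean=10, tmax_mean=5, t_sd=1,
                                  p_wet_wet=0.5, p_wet_dry=0.3, rain_shape=1,
                                  rain_scale=1, rad_dry=5, rad_wet=5, rad_sd=1)


class TestScenario:
    def test_identity_scenario_is_identity(self, rr_params):
        ident = w.ClimateScenario(dt=0.0, precip_mult=1.0, rad_mult=1.0,
                                  co2=rr_params.co2)
        assert w.apply_scenario(rr_params, ident) == rr_params

    def test_input_unmodified(self, rr_params):
        before = rr_params.months[0].tmin_mean
        w.apply_scenario(rr_params, w.scenario_2050("UK"))
        assert rr_params.months[0].tmin_mean == before

    def test_uk_2050_shifts_recovered_with_same_seed(self, rr_params):
        morphed = w.apply_scenario(rr_params, w.scenario_2050("UK"))
        base = w.summarize_series(w.generate_series(rr_params, 100, seed=7))
        fut = w.summarize_series(w.generate_series(morphed, 100, seed=7))
        assert fut["t_mean_c"] - base["t_mean_c"] == pytest.approx(2.1, abs=0.2)
        assert fut["rad_mj_day"] / base["rad_mj_day"] == pytest.approx(1.067, abs=0.01)
        assert morphed.co2 == 541.0

    def test_zero_precip_multiplier_annihilates_rain(self, rr_params):
        dry = w.apply_scenario(rr_params, w.ClimateScenario(
            dt=0.0, precip_mult=0.0, rad_mult=1.0, co2=364.0))
        series = w.generate_series(dry, 10, seed=3)
        assert series.rain.sum() == 0.0

    def test_scenario_offsets_are_additive(self, rr_params):
        one = w.ClimateScenario(dt=2.1, precip_mult=1.0, rad_mult=1.0, co2=364.0)
        two = w.ClimateScenario(dt=4.2, precip_mult=1.0, rad_mult=1.0, co2=364.0)
        twice = w.apply_scenario(w.apply_scenario(rr_params, one), one)
        once = w.apply_scenario(rr_params, two)
        for ma, mb in zip(twice.months, once.months):
            assert ma.tmin_mean == pytest.approx(mb.tmin_mean, abs=1e-12)
            assert ma.tmax_mean == pytest.approx(mb.tmax_mean, abs=1e-12)
            assert ma.rain_scale == mb.rain_scale and ma.rad_dry == mb.rad_dry


class TestSummary:
    def test_constant_series(self):
        from conftest import constant_weather
        series = constant_weather(n_years=2, tmin=10, tmax=10, rain=2.0, rad=12.0)
        s = w.summarize_series(series)
        assert s["t_mean_c"] == pytest.approx(10.0)
        assert s["precip_mm_yr"] == pytest.approx(730.0)
        assert s["rad_mj_day"] == pytest.approx(12.0)

    def test_concatenated_series_pools_by_length(self, rr_params):
        a = w.generate_series(rr_params, 2, seed=1)
        b = w.generate_series(rr_params, 3, seed=2)
        both = w.WeatherSeries(
            year=np.concatenate([a.year, b.year + 2]),
            doy=np.concatenate([a.doy, b.doy]),
            tmin=np.concatenate([a.tmin, b.tmin]),
            tmax=np.concatenate([a.tmax, b.tmax]),
            rain=np.concatenate([a.rain, b.rain]),
            rad=np.concatenate([a.rad, b.rad]))
        pooled = w.summarize_series(both)
        # brute-force recomputation from the raw concatenated days
        t = np.concatenate([(a.tmin + a.tmax) / 2, (b.tmin + b.tmax) / 2])
        assert pooled["t_mean_c"] == pytest.approx(t.mean())
        assert pooled["precip_mm_yr"] == pytest.approx(
            (a.rain.sum() + b.rain.sum()) / 5.0)

    def test_empty_series_rejected(self):
        empty = w.WeatherSeries(*(np.array([]) for _ in range(6)))
        with pytest.raises(ValueError, match="empty"):
            w.summarize_series(empty)


def test_weather_csv_round_trip(tmp_path, rr_params):
    series = w.generate_series(rr_params, 2, seed=9)
    path = tmp_path / "weather.csv"
    write_weather_csv(series, path)
    back = read_weather_csv(path)
    np.testing.assert_allclose(back.rain, series.rain)
    np.testing.assert_allclose(back.tmin, series.tmin)
    assert list(back.doy[:3]) == [1, 2, 3]
    with pytest.raises(ValueError, match="missing columns"):
        bad = tmp_path / "bad.csv"
        series.to_frame().drop(columns=["rad_mj"]).to_csv(bad, index=False)
        read_weather_csv(bad)


def test_all_site_annual_normals_recovered():
    for site, (_, _, _, t_ann, p_ann, r_ann) in w.SITE_INFO.items():
        s = w.summarize_series(w.generate_series(w.site_params(site), 100, seed=4))
        assert s["t_mean_c"] == pytest.approx(t_ann, abs=0.3), site
        assert s["precip_mm_yr"] == pytest.approx(p_ann, rel=0.05), site
        assert s["rad_mj_day"] == pytest.approx(r_ann, rel=0.05), site
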