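"""Twilight detection, template fit, SST aggregation and track refinement."""

import logging

import numpy as np
import pandas as pd
import pytest

from physiotag.geolocation import (
    GeoConfig,
    detect_twilights,
    grid_filter_oracle,
    light_positions,
    refine_track,
    tag_sst_daily,
    template_fit_position,
)
from physiotag.series import TagSeries
from physiotag.simulate import (
    DepthParams,
    LightParams,
    StepParams,
    simulate_sensor_series,
    simulate_sst_field,
    simulate_track,
)
from physiotag.solar import day_length_hours


def _fixed_series(lat=35.0, lon=140.0, start="2021-06-15", n_days=5, **kw):
    """Clean series at a fixed position: no depth attenuation, no noise."""
    path = simulate_track(
        (lat, lon), start, n_days, "resident", StepParams(mean_km=1e-9, sd_km=0.0)
    )
    field = simulate_sst_field(
        (lat - 8, lat + 8), (lon - 8, lon + 8),
        pd.date_range(pd.Timestamp(start) - pd.Timedelta(days=1), periods=n_days + 3),
        noise_sd_c=0.0,
    )
    params = dict(
        light_params=LightParams(noise_frac=0.0, attenuation_per_m=0.0),
        depth_params=DepthParams(noise_sd_m=0.0),
        temp_noise_sd_c=0.0,
        sampling_s=30,
        seed=0,
    )
    params.update(kw)
    return simulate_sensor_series(path, field, **params)


CLEAN_CFG = GeoConfig(
    sun_altitude_deg=LightParams().threshold_elevation_deg(0.3), light_threshold=0.3
)


class TestTwilights:
    def test_day_length_matches_astronomy_at_solstice(self):
        s = _fixed_series(start="2021-06-18", n_days=5)
        tw = detect_twilights(s, 0.3, 10.0)
        assert len(tw) >= 4
        for r in tw.itertuples():
            measured = (r.dusk_utc - r.dawn_utc).total_seconds() / 3600.0
            astro = day_length_hours(
                35.0, r.dawn_utc + (r.dusk_utc - r.dawn_utc) / 2,
                CLEAN_CFG.sun_altitude_deg,
            )
            assert abs(measured - astro) * 60.0 < 10.0

    def test_constant_darkness_yields_no_days_and_warnings(self, caplog):
        idx = pd.date_range("2021-06-01", periods=3 * 288, freq="300s")
        data = pd.DataFrame(
            {"depth_m": 1.0, "temp_internal_c": 20.0, "temp_external_c": 20.0,
             "light": 1e-4},
            index=idx,
        )
        s = TagSeries(data=data)
        with caplog.at_level(logging.WARNING, logger="physiotag.geolocation"):
            tw = detect_twilights(s, 0.3)
        assert tw.empty
        assert sum("twilight" in r.message for r in caplog.records) == s.n_days

    def test_short_dives_do_not_move_twilights(self):
        base = _fixed_series(start="2021-06-18", n_days=4)
        tw0 = detect_twilights(base, 0.3, 10.0)
        dived = base.data.copy()
        # 3-minute attenuation spikes (deep dives) through the daylight hours,
        # each far shorter than the 10-minute smoothing window
        local_hour = (
            np.asarray((dived.index - dived.index.normalize()).total_seconds()) / 3600.0
            + 140.0 / 15.0
        ) % 24.0
        spike = np.zeros(len(dived), dtype=bool)
        for k in range(0, len(dived), 120):  # every hour at 30 s sampling
            if 8.0 <= local_hour[k] <= 16.0:
                spike[k : k + 6] = True
        dived.loc[spike, "light"] = dived.loc[spike, "light"] * 0.05
        tw1 = detect_twilights(TagSeries(data=dived), 0.3, 10.0)
        pd.testing.assert_frame_equal(tw0, tw1)


class TestTemplateFit:
    def test_noon_at_greenwich(self):
        # 1 September: equation of time is within ~0.2 min of zero
        r = template_fit_position("2021-09-01 06:00", "2021-09-01 18:00", CLEAN_CFG)
        assert r.lon_light == pytest.approx(0.0, abs=0.3)

    def test_noon_before_utc_maps_to_east(self):
        r = template_fit_position("2021-08-31 20:36", "2021-09-01 08:36", CLEAN_CFG)
        assert r.lon_light == pytest.approx(141.0, abs=0.3)

    def test_latitude_recovered_at_solstice(self):
        s = _fixed_series(start="2021-06-18", n_days=5)
        raw = light_positions(s, CLEAN_CFG)
        ok = raw[raw["lat_valid"]]
        assert len(ok) >= 4
        assert ok["lat_light"].mean() == pytest.approx(35.0, abs=0.5)

    def test_equinox_window_flags_latitude_invalid(self):
        r = template_fit_position("2021-03-21 06:00", "2021-03-21 18:10", CLEAN_CFG)
        assert not r.lat_valid
        assert r.obs_sd_lat == CLEAN_CFG.obs_sd_lat_equinox

    def test_dawn_after_dusk_error(self):
        with pytest.raises(ValueError):
            template_fit_position("2021-06-01 18:00", "2021-06-01 06:00")


class TestTagSST:
    def _series(self, depths, temps):
        idx = pd.date_range("2021-06-01", periods=len(depths), freq="3600s")
        return TagSeries(
            data=pd.DataFrame(
                {"depth_m": depths, "temp_internal_c": temps,
                 "temp_external_c": temps, "light": 1.0},
                index=idx,
            )
        )

    def test_all_shallow_constant(self):
        s = self._series([3.0] * 24, [20.0] * 24)
        out = tag_sst_daily(s)
        assert out["sst_c"].iloc[0] == pytest.approx(20.0)

    def test_depth_cutoff_excludes_deep_samples(self):
        s = self._series([10.0, 2.0] * 12, [25.0, 20.0] * 12)
        out = tag_sst_daily(s)
        assert out["sst_c"].iloc[0] == pytest.approx(20.0)

    def test_matches_bruteforce_groupby(self, resident):
        _, series = resident
        out = tag_sst_daily(series).set_index("date")["sst_c"]
        df = series.data
        expected = (
            df[df["depth_m"] <= 5.0]
            .groupby(df[df["depth_m"] <= 5.0].index.normalize())["temp_external_c"]
            .mean()
        )
        assert np.allclose(out.to_numpy(), expected.to_numpy(), atol=1e-9)


def _linear_scene(n=60, sd_lon=0.5, sd_lat=1.0, sd_sst=0.3, seed=0):
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2021-10-01", periods=n)
    lat_t = 36.0 - 0.08 * np.arange(n)
    lon_t = 141.0 - 0.02 * np.arange(n)
    field = simulate_sst_field((25, 40), (130, 150), dates, noise_sd_c=0.0, seed=0)
    raw = pd.DataFrame(
        {
            "date": dates,
            "lon_light": lon_t + rng.normal(0, sd_lon, n),
            "lat_light": lat_t + rng.normal(0, sd_lat, n),
            "lat_valid": True,
            "obs_sd_lon": max(sd_lon, 1e-3),
            "obs_sd_lat": max(sd_lat, 1e-3),
        }
    )
    sst = pd.DataFrame(
        {
            "date": dates,
            "sst_c": field.value_at(dates.values, lat_t, lon_t)
            + rng.normal(0, sd_sst, n),
        }
    )
    return dates, lat_t, lon_t, field, raw, sst


class TestRefineTrack:
    def test_noiseless_limit_recovers_truth(self):
        _, lat_t, lon_t, field, raw, sst = _linear_scene(sd_lon=0, sd_lat=0, sd_sst=0)
        raw[["obs_sd_lon", "obs_sd_lat"]] = 0.02
        cfg = GeoConfig(process_sigma_km=10.0, obs_sd_sst=0.02)
        tr = refine_track(raw, sst, field, cfg, release=(36.0, 141.0))
        assert (tr.data["lat"].to_numpy() - lat_t).max() < 0.05
        assert np.abs(tr.data["lon"].to_numpy() - lon_t).max() < 0.05

    def test_smoother_never_loses_information(self):
        *_, field, raw, sst = _linear_scene()
        tr = refine_track(raw, sst, field, GeoConfig(process_sigma_km=40.0),
                          release=(36.0, 141.0))
        assert (tr.data["sd_lat"] <= tr.data["sd_lat_filter"] + 1e-9).all()
        assert (tr.data["sd_lon"] <= tr.data["sd_lon_filter"] + 1e-9).all()

    def test_posterior_tighter_than_raw_observation(self):
        *_, field, raw, sst = _linear_scene()
        tr = refine_track(raw, sst, field, GeoConfig(process_sigma_km=40.0),
                          release=(36.0, 141.0))
        assert (tr.data["sd_lat"] <= raw["obs_sd_lat"].iloc[0]).all()
        assert (tr.data["sd_lon"] <= raw["obs_sd_lon"].iloc[0]).all()

    def test_likelihood_history_is_nondecreasing(self):
        *_, field, raw, sst = _linear_scene()
        tr = refine_track(raw, sst, field, GeoConfig(), release=(36.0, 141.0))
        assert all(b >= a - 1e-9 for a, b in zip(tr.ll_history, tr.ll_history[1:]))
        assert 10.0 <= tr.process_sigma_km <= 300.0

    def test_no_observations_error(self):
        raw = pd.DataFrame(
            {"date": pd.date_range("2021-01-01", periods=4),
             "lon_light": np.nan, "lat_light": np.nan,
             "lat_valid": False, "obs_sd_lon": 0.5, "obs_sd_lat": 20.0}
        )
        with pytest.raises(ValueError):
            refine_track(raw, None, None, GeoConfig(process_sigma_km=50.0))

    def test_longitude_estimates_unbiased(self):
        s = _fixed_series(start="2021-05-01", n_days=110, sampling_s=60)
        raw = light_positions(s, CLEAN_CFG)
        assert len(raw) >= 100
        assert abs(raw["lon_light"].mean() - 140.0) < 0.2


class TestGridOracle:
    def test_agrees_with_ukf_smoother(self):
        *_, field, raw, sst = _linear_scene()
        cfg = GeoConfig(process_sigma_km=40.0)
        tr = refine_track(raw, sst, field, cfg, release=(36.0, 141.0))
        go = grid_filter_oracle(raw, sst, field, 0.5, cfg,
                                process_sigma_km=40.0, release=(36.0, 141.0))
        d = np.hypot(tr.data["lat"] - go.data["lat"], tr.data["lon"] - go.data["lon"])
        assert (d <= 2 * 0.5).mean() >= 0.9

    def test_noiseless_limit_within_one_cell(self):
        _, lat_t, lon_t, field, raw, sst = _linear_scene(sd_lon=0, sd_lat=0, sd_sst=0)
        raw[["obs_sd_lon", "obs_sd_lat"]] = 0.1
        go = grid_filter_oracle(raw, sst, field, 0.5,
                                GeoConfig(process_sigma_km=20.0, obs_sd_sst=0.1),
                                process_sigma_km=20.0, release=(36.0, 141.0))
        assert np.abs(go.data["lat"].to_numpy() - lat_t).max() <= 0.5
        assert np.abs(go.data["lon"].to_numpy() - lon_t).max() <= 0.5

    def test_no_information_spreads_from_release(self):
        dates = pd.date_range("2021-10-01", periods=12)
        raw = pd.DataFrame(
            {"date": dates, "lon_light": np.nan, "lat_light": np.nan,
             "lat_valid": False, "obs_sd_lon": 0.5, "obs_sd_lat": 20.0}
        )
        go = grid_filter_oracle(raw, None, None, 0.5, GeoConfig(),
                                process_sigma_km=50.0, release=(35.0, 140.0),
                                extent=(20.0, 50.0, 125.0, 155.0), use_sst=False)
        sd = go.data["sd_lat"].to_numpy()
        assert (np.diff(sd) > 0).all()
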