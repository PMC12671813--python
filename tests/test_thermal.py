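"""Thermal aggregation, clustering and extraordinary-event detection."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from physiotag.series import TagSeries
from physiotag.thermal import (
    PhysioThresholds,
    agglomerative_cluster,
    daily_thermal_summary,
    detect_thermal_events,
    event_interval_stats,
    event_onset,
    monthly_experienced,
    onset_hour_histogram,
)


def _series_from_internal(temps, dt_s=30, start="2021-07-01", external=None):
    idx = pd.date_range(start, periods=len(temps), freq=f"{dt_s}s")
    return TagSeries(
        data=pd.DataFrame(
            {
                "depth_m": 2.0,
                "temp_internal_c": np.asarray(temps, dtype=float),
                "temp_external_c": external if external is not None else 25.0,
                "light": 1.0,
            },
            index=idx,
        )
    )


class TestThresholds:
    def test_event_threshold_is_derived(self):
        th = PhysioThresholds()
        assert th.t_event_c == th.t_redmuscle_max_c - th.gradient_rm_peritoneal_c
        assert th.t_event_c == 31.0

    def test_inconsistent_ordering_rejected(self):
        with pytest.raises(ValueError):
            PhysioThresholds(t_spawn_c=17.0)


class TestDailySummary:
    def test_constant_sensors(self):
        temps = np.full(2880, 20.0)
        out = daily_thermal_summary(_series_from_internal(temps, external=20.0))
        assert out["mean_water_c"].iloc[0] == pytest.approx(20.0)
        assert out["max_body_c"].iloc[0] == pytest.approx(20.0)

    def test_event_day_max_exceeds_threshold_others_do_not(self, event_series):
        _, s = event_series
        daily = daily_thermal_summary(s).set_index("date")
        event_days = set(pd.to_datetime(s.events_truth["onset_utc"]).dt.normalize())
        for day, row in daily.iterrows():
            if day in event_days:
                assert row["max_body_c"] >= 31.0
            else:
                assert row["max_body_c"] < 31.0

    def test_matches_bruteforce_reaggregation(self, migrant):
        _, s = migrant
        out = daily_thermal_summary(s)
        days = s.data.index.normalize()
        expected_mean = s.data.groupby(days)["temp_external_c"].mean()
        expected_max = s.data.groupby(days)["temp_internal_c"].max()
        assert np.allclose(out["mean_water_c"], expected_mean.to_numpy(), atol=1e-9)
        assert np.allclose(out["max_body_c"], expected_max.to_numpy(), atol=1e-9)


class TestMonthly:
    def test_single_fish_constant_month(self):
        temps = np.full(30 * 144, 20.0)
        s = _series_from_internal(temps, dt_s=600, start="2021-03-01", external=20.0)
        daily = daily_thermal_summary(s)
        out = monthly_experienced({"a": daily}, {"a": "residence"})
        assert out["mean_c"].iloc[0] == pytest.approx(20.0)
        assert out["sd_c"].iloc[0] == pytest.approx(0.0)

    def test_resident_winter_sits_at_lethal_limit(self, resident):
        _, s = resident
        daily = daily_thermal_summary(s)
        out = monthly_experienced({s.tag_id: daily}, {s.tag_id: "residence"})
        winter = out[out["month"].isin([1, 2, 3])]
        assert len(winter) == 3
        assert winter["mean_c"].between(17.0, 19.5).all()
        assert winter["flag_lethal_limit"].all()
        assert not out[out["month"].isin([10, 11])]["flag_lethal_limit"].any()

    def test_migrant_months_mostly_spawning_suitable(self, migrant):
        _, s = migrant
        daily = daily_thermal_summary(s)
        out = monthly_experienced({s.tag_id: daily}, {s.tag_id: "spawning_potential"})
        # all full tropical months are suitable; the June transit month may
        # straddle the threshold while the fish leaves temperate water
        south = out[out["month"].isin([7, 8, 9])]
        assert south["flag_spawning_suitable"].all()
        assert out["flag_spawning_suitable"].mean() >= 0.75

    def test_missing_label_errors(self):
        daily = pd.DataFrame({"date": pd.to_datetime(["2021-01-01"]), "mean_water_c": [20.0]})
        with pytest.raises(ValueError):
            monthly_experienced({"a": daily}, {})


class TestClustering:
    def test_two_obvious_pairs(self):
        pts = [(0.0, 0.0), (0.1, 0.0), (10.0, 10.0), (10.1, 10.0)]
        labels = agglomerative_cluster(pts, 2)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(120, 2))
        ours = agglomerative_cluster(pts, 2)
        ref = fcluster(linkage(pts, method="average"), 2, criterion="maxclust")
        same = (ours == ours[0]) == (ref == ref[0])
        assert same.all()

    def test_warm_cool_clouds_recovered(self):
        rng = np.random.default_rng(42)
        warm = rng.normal((29.0, 26.0), 1.0, size=(300, 2))
        cool = rng.normal((24.0, 19.0), 1.0, size=(300, 2))
        pts = np.vstack([warm, cool])
        labels = agglomerative_cluster(pts, 2)
        truth = np.r_[np.zeros(300), np.ones(300)]
        agreement = max((labels == truth).mean(), (labels != truth).mean())
        assert agreement >= 0.95

    def test_permutation_invariance_up_to_label_swap(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(60, 2))
        perm = rng.permutation(60)
        a = agglomerative_cluster(pts, 2)
        b = agglomerative_cluster(pts[perm], 2)
        assert ((a[perm] == a[perm][0]) == (b == b[0])).all()

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            agglomerative_cluster([(0.0, 0.0)], 2)


class TestEventDetection:
    def test_constant_below_threshold_no_events(self):
        ev = detect_thermal_events(_series_from_internal(np.full(2000, 25.0)))
        assert ev.empty

    def test_short_dip_is_merged(self):
        temps = np.full(600, 28.0)
        temps[100:140] = 31.5
        temps[140:146] = 30.5  # 3-minute dip at 30 s sampling
        temps[146:186] = 31.5
        ev = detect_thermal_events(_series_from_internal(temps), merge_gap_min=10.0)
        assert len(ev) == 1

    def test_single_sample_noise_is_discarded(self):
        temps = np.full(600, 28.0)
        temps[300] = 31.5
        ev = detect_thermal_events(_series_from_internal(temps), min_duration_min=1.0)
        assert ev.empty

    def test_lowering_threshold_never_reduces_events(self, event_series):
        _, s = event_series
        n_hi = len(detect_thermal_events(s, PhysioThresholds()))
        lower = PhysioThresholds(gradient_rm_peritoneal_c=5.0)  # event at 30 degC
        assert len(detect_thermal_events(s, lower)) >= n_hi

    def test_prepending_quiet_data_changes_nothing(self):
        temps = np.full(600, 28.0)
        temps[200:280] = 31.8
        s1 = _series_from_internal(temps, start="2021-07-02")
        quiet = np.full(2880, 27.0)
        s2 = _series_from_internal(
            np.r_[quiet, temps], start="2021-07-01"
        )
        e1 = detect_thermal_events(s1)
        e2 = detect_thermal_events(s2)
        assert len(e1) == len(e2) == 1
        assert e1["crossing_utc"].iloc[0] == e2["crossing_utc"].iloc[0]

    def test_every_event_satisfies_ordering_invariants(self, migrant):
        _, s = migrant
        ev = detect_thermal_events(s, track=s.true_path)
        assert (ev["peak_c"] >= 31.0).all()
        assert (ev["onset_utc"] <= ev["crossing_utc"]).all()
        assert (ev["crossing_utc"] <= ev["peak_utc"]).all()
        assert (ev["peak_utc"] <= ev["end_utc"]).all()

    def test_recovers_implanted_events(self, event_series):
        _, s = event_series
        ev = detect_thermal_events(s, track=s.true_path)
        truth = pd.to_datetime(s.events_truth["onset_utc"])
        detected = pd.to_datetime(ev["onset_utc"])
        matched = sum(
            (detected - t).abs().min() <= pd.Timedelta(minutes=60) for t in truth
        )
        assert matched / len(truth) >= 0.95  # recall
        assert matched / len(ev) >= 0.95  # precision


class TestOnset:
    def test_linear_ramp_onset_at_foot(self):
        dt = 30
        temps = np.concatenate(
            [np.full(400, 28.0), 28.0 + 4.0 * np.arange(70) / 70.0, np.full(100, 32.0)]
        )
        s = _series_from_internal(temps, dt_s=dt)
        crossing = s.data.index[400 + int(np.ceil(3.0 / 4.0 * 70))]
        onset = event_onset(s, crossing)
        foot = s.data.index[400]
        assert abs((onset - foot).total_seconds()) <= dt

    def test_instantaneous_step_onset_equals_crossing(self):
        temps = np.r_[np.full(500, 28.0), np.full(100, 32.0)]
        s = _series_from_internal(temps)
        crossing = s.data.index[500]
        onset = event_onset(s, crossing)
        assert abs((onset - crossing).total_seconds()) <= 30

    def test_simulator_ramp_timing_recovered(self, event_series):
        _, s = event_series
        ev = detect_thermal_events(s, track=s.true_path)
        truth = pd.to_datetime(s.events_truth["onset_utc"])
        errs = [
            abs((pd.Timestamp(o) - t).total_seconds()) / 60.0
            for o, t in zip(ev["onset_utc"], truth)
        ]
        assert np.median(errs) <= 5.0


class TestIntervalsAndHours:
    def test_interval_examples(self):
        ev = pd.DataFrame(
            {"onset_utc": pd.to_datetime(["2021-07-01", "2021-07-03", "2021-07-04"])}
        )
        intervals, summary = event_interval_stats(ev)
        assert sorted(intervals) == [1.0, 2.0]
        assert summary["min_days"] == 1.0

    def test_single_event_empty_intervals(self):
        ev = pd.DataFrame({"onset_utc": pd.to_datetime(["2021-07-01"])})
        intervals, summary = event_interval_stats(ev)
        assert len(intervals) == 0
        assert summary["n_intervals"] == 0

    def test_generator_intervals_within_contract(self, event_series):
        _, s = event_series
        intervals, _ = event_interval_stats(s.events_truth)
        eps = 15.0 / 24.0  # onset-hour jitter within the 05:00-20:00 window
        assert (intervals >= 1.0 - eps).all()
        assert (intervals <= 3.0 + eps).all()

    def test_histogram_single_bin(self):
        ev = pd.DataFrame({"onset_local_solar_hour": [15.5, 15.1, 15.9]})
        hist = onset_hour_histogram(ev)
        assert hist[15] == 3
        assert hist.sum() == 3

    def test_histogram_counts_conserved(self, migrant):
        _, s = migrant
        ev = detect_thermal_events(s, track=s.true_path)
        hist = onset_hour_histogram(ev)
        assert hist.sum() == np.isfinite(ev["onset_local_solar_hour"]).sum()

    def test_afternoon_mode_recovered(self, migrant):
        _, s = migrant
        ev = detect_thermal_events(s, track=s.true_path)
        hist = onset_hour_histogram(ev)
        assert 14 <= int(np.argmax(hist)) <= 18
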