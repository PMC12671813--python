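"""Canonical simulation scenarios for the two observed movement strategies.

The scenarios bundle a field, a path and a sensor series whose statistics
mirror the study system:

``resident_scenario``
    An October release at ~36.7 degN that stays in the northern habitat,
    shifting its home range south to ~31 degN through November-January as
    seasonal cooling pushes the 18 degC limit southward, with undirected
    34.6 +/- 27.6 km/day movements, a ~3 degC thermal excess in cool water
    and no extraordinary thermal events.

``migrant_scenario``
    A June release at ~31.6 degN moving south at ~77 km/day with a
    southward bearing preference, a small (~1 degC) thermal excess in warm
    water, and implanted extraordinary body-temperature events (32 degC
    peak, 35 min ramp, 15 min plateau, 1-3 day intervals, afternoon-mode
    onsets).

``tracking_benchmark_scenario``
    A long (250-day) migrant deployment over an uncapped 0.5 degC/deg SST
    gradient, used to benchmark geolocation recovery across an equinox.

``event_benchmark_series``
    A stationary deployment in intermediate water with a fixed number of
    implanted events, used to score event detection and onset timing.

The SST field in the residence/migrant scenarios saturates at a 29.5 degC
tropical maximum so that event-free body temperature stays a safe margin
below the 31 degC event threshold, as observed.
"""

from __future__ import annotations

import pandas as pd

from .simulate import (
    EventParams,
    StepParams,
    simulate_sensor_series,
    simulate_sst_field,
    simulate_track,
)

__all__ = [
    "resident_scenario",
    "migrant_scenario",
    "tracking_benchmark_scenario",
    "event_benchmark_series",
]


def _field_dates(release_date, n_days):
    start = pd.Timestamp(release_date) - pd.Timedelta(days=1)
    return pd.date_range(start, periods=n_days + 3, freq="D")


def resident_scenario(seed: int = 0, n_days: int = 200, sampling_s: int = 30):
    """Residence-group scenario; returns ``(field, series)``."""
    release = (36.7, 141.4)
    release_date = pd.Timestamp("2021-10-25")
    field = simulate_sst_field(
        lat_range=(24.0, 45.0),
        lon_range=(128.0, 155.0),
        dates=_field_dates(release_date, n_days),
        max_c=29.5,
        seed=seed + 11,
    )
    steps = StepParams(
        mean_km=34.6,
        sd_km=27.6,
        bearing_kappa=0.0,
        home_waypoints=[
            (0, 36.7, 141.4),
            (21, 36.7, 141.4),
            (97, 31.0, 138.5),
            (max(n_days, 98), 31.0, 138.5),
        ],
        home_strength=0.1,
    )
    path = simulate_track(release, release_date, n_days, "resident", steps, seed=seed + 21)
    series = simulate_sensor_series(
        path,
        field,
        thermal_excess_c=3.0,
        event_params=None,
        sampling_s=sampling_s,
        tag_id="resident-sim",
        seed=seed + 31,
    )
    return field, series


def migrant_scenario(
    seed: int = 0, n_days: int = 100, sampling_s: int = 30, events: bool = True
):
    """Spawning-potential-group scenario; returns ``(field, series)``."""
    release = (31.59, 144.23)
    release_date = pd.Timestamp("2014-06-02")
    field = simulate_sst_field(
        lat_range=(-31.0, 45.0),
        lon_range=(100.0, 180.0),
        dates=_field_dates(release_date, n_days),
        max_c=29.5,
        seed=seed + 12,
    )
    path = simulate_track(release, release_date, n_days, "migrant", seed=seed + 22)
    series = simulate_sensor_series(
        path,
        field,
        thermal_excess_c=1.0,
        event_params=EventParams() if events else None,
        sampling_s=sampling_s,
        tag_id="migrant-sim",
        seed=seed + 32,
    )
    return field, series


def tracking_benchmark_scenario(seed: int = 0, n_days: int = 250, sampling_s: int = 30):
    """Geolocation benchmark: 250-day migrant over a 0.5 degC/deg gradient."""
    release = (31.59, 144.23)
    release_date = pd.Timestamp("2014-06-02")
    field = simulate_sst_field(
        lat_range=(-31.0, 45.0),
        lon_range=(100.0, 180.0),
        dates=_field_dates(release_date, n_days),
        lat_gradient_c_per_deg=0.5,
        max_c=None,
        seed=seed + 13,
    )
    path = simulate_track(release, release_date, n_days, "migrant", seed=seed + 23)
    series = simulate_sensor_series(
        path,
        field,
        thermal_excess_c=1.0,
        event_params=None,
        sampling_s=sampling_s,
        tag_id="benchmark-sim",
        seed=seed + 33,
    )
    return field, path, series


def event_benchmark_series(seed: int = 0, n_events: int = 20, sampling_s: int = 30):
    """Stationary deployment with exactly ``n_events`` implanted events.

    Sited at 26 degN in spring so the ramp amplitude (baseline to 32 degC
    peak) is several degrees -- a clean shape benchmark for the detector and
    the onset-tracing rule.
    """
    release = (26.0, 135.0)
    release_date = pd.Timestamp("2021-04-15")
    n_days = 3 * n_events + 6
    field = simulate_sst_field(
        lat_range=(20.0, 32.0),
        lon_range=(128.0, 142.0),
        dates=_field_dates(release_date, n_days),
        max_c=29.5,
        seed=seed + 14,
    )
    steps = StepParams(mean_km=10.0, sd_km=5.0, home_waypoints=[(0, 26.0, 135.0), (n_days, 26.0, 135.0)], home_strength=0.2)
    path = simulate_track(release, release_date, n_days, "resident", steps, seed=seed + 24)
    series = simulate_sensor_series(
        path,
        field,
        thermal_excess_c=1.0,
        event_params=EventParams(n_events=n_events),
        sampling_s=sampling_s,
        tag_id="event-benchmark",
        seed=seed + 34,
    )
    return field, series
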