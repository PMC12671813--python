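"""End-to-end pipeline: simulate -> geolocate -> classify -> thermal -> summarise.

Each stage's runtime is logged and its warnings counted; any stage failure
aborts the run with the stage name.  All randomness flows from the single
seed in the configuration, so identical configurations produce identical
artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io
from .cohort import decadal_summary, filter_southward
from .config import PipelineConfig
from .geolocation import GeoConfig, light_positions, refine_track, tag_sst_daily
from .scenarios import migrant_scenario, resident_scenario
from .simulate import LightParams, simulate_pdt_cohort
from .thermal import (
    PhysioThresholds,
    daily_thermal_summary,
    detect_thermal_events,
    monthly_experienced,
    onset_hour_histogram,
)
from .track_metrics import classify_movement_group

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


class _WarningCounter(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record):  # noqa: D102
        self.count += 1


def _geo_config(cfg: PipelineConfig) -> GeoConfig:
    sigma = None if cfg.process_sigma_km < 0 else cfg.process_sigma_km
    return GeoConfig(
        obs_sd_lon=cfg.obs_sd_lon,
        obs_sd_lat=cfg.obs_sd_lat,
        obs_sd_lat_equinox=cfg.obs_sd_lat_equinox,
        obs_sd_sst=cfg.obs_sd_sst,
        declination_min_deg=cfg.declination_min_deg,
        sun_altitude_deg=LightParams().threshold_elevation_deg(
            cfg.light_threshold, depth_m=3.0
        ),
        light_threshold=cfg.light_threshold,
        smooth_window_min=cfg.twilight_smooth_min,
        process_sigma_km=sigma,
    )


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full analysis on a simulated deployment; returns the report dict.

    Writes seven artifacts into ``out_dir``: track.csv, group.json,
    daily_thermal.csv, events.csv, monthly.csv, decadal.csv and report.json.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counter = _WarningCounter()
    logging.getLogger("physiotag").addHandler(counter)
    report: dict = {"scenario": config.scenario, "seed": config.seed}
    thresholds = PhysioThresholds(
        t_spawn_c=config.t_spawn_c,
        t_lethal_low_c=config.t_lethal_low_c,
        t_redmuscle_max_c=config.t_redmuscle_max_c,
        gradient_rm_peritoneal_c=config.gradient_rm_peritoneal_c,
        boundary_lat_deg=config.boundary_lat_deg,
    )
    try:
        stage = "simulate"
        t0 = time.perf_counter()
        if config.scenario == "resident":
            field, series = resident_scenario(config.seed, config.n_days, config.sampling_s)
        elif config.scenario == "migrant":
            field, series = migrant_scenario(config.seed, config.n_days, config.sampling_s)
        else:
            raise ValueError(f"unknown scenario {config.scenario!r}")
        logger.info("stage %s: %.1f s", stage, time.perf_counter() - t0)

        stage = "geolocate"
        t0 = time.perf_counter()
        geo = _geo_config(config)
        raw = light_positions(series, geo)
        sst_obs = tag_sst_daily(series)
        track = refine_track(
            raw, sst_obs, field, geo, release=(series.release_lat, series.release_lon)
        )
        io.write_track(track, out / "track.csv")
        report["n_track_days"] = len(track)
        report["process_sigma_km"] = track.process_sigma_km
        logger.info("stage %s: %.1f s", stage, time.perf_counter() - t0)

        stage = "classify"
        group = classify_movement_group(
            track.data["lat"].to_numpy(), boundary_deg=config.boundary_lat_deg
        )
        group_dict = {
            "label": group.label,
            "basis": group.basis,
            "minimum_latitude_deg": round(group.minimum_latitude_deg, 3),
            "boundary_deg": config.boundary_lat_deg,
        }
        (out / "group.json").write_text(json.dumps(group_dict, indent=2))
        report["group"] = group_dict

        stage = "thermal"
        t0 = time.perf_counter()
        daily = daily_thermal_summary(series)
        daily.to_csv(out / "daily_thermal.csv", index=False)
        events = detect_thermal_events(
            series,
            thresholds,
            merge_gap_min=config.merge_gap_min,
            min_duration_min=config.min_duration_min,
            track=track.data,
            smooth_window_min=config.event_smooth_min,
        )
        events.to_csv(out / "events.csv", index=False)
        monthly = monthly_experienced(
            {series.tag_id: daily}, {series.tag_id: group.label}, thresholds
        )
        monthly.to_csv(out / "monthly.csv", index=False)
        hist = onset_hour_histogram(events)
        report["n_events"] = int(len(events))
        report["event_modal_hour"] = int(np.argmax(hist)) if hist.sum() else None
        report["months_at_lethal_limit"] = [
            int(m) for m in monthly.loc[monthly["flag_lethal_limit"], "month"]
        ]
        report["months_spawning_suitable"] = [
            int(m) for m in monthly.loc[monthly["flag_spawning_suitable"], "month"]
        ]
        logger.info("stage %s: %.1f s", stage, time.perf_counter() - t0)

        stage = "summarize"
        cohort = simulate_pdt_cohort(
            config.pdt_n_per_year,
            range(config.pdt_years_start, config.pdt_years_end + 1),
            config.pdt_p_spawning_potential,
            config.pdt_recapture_rate,
            seed=config.seed + 41,
        )
        kept = filter_southward(cohort)
        decadal = decadal_summary(kept, config.boundary_lat_deg)
        decadal.to_csv(out / "decadal.csv", index=False)
        report["decadal"] = decadal.drop(columns=["min_recapture_lat"]).to_dict("records")
    except Exception as exc:  # noqa: BLE001
        logging.getLogger("physiotag").removeHandler(counter)
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    logging.getLogger("physiotag").removeHandler(counter)
    report["n_warnings"] = counter.count
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
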