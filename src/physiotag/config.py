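"""Flat, single-file pipeline configuration.

One TOML file of scalar keys reproduces a full pipeline run; unknown keys
are rejected so that typos fail loudly rather than silently falling back to
defaults.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, in one flat record."""

    scenario: str = "resident"  # "resident" | "migrant"
    seed: int = 0
    n_days: int = 200
    sampling_s: int = 30
    # classification / physiology thresholds
    boundary_lat_deg: float = 25.0
    t_spawn_c: float = 24.0
    t_lethal_low_c: float = 18.0
    t_redmuscle_max_c: float = 35.0
    gradient_rm_peritoneal_c: float = 4.0
    # geolocation
    obs_sd_lon: float = 0.5
    obs_sd_lat: float = 1.0
    obs_sd_lat_equinox: float = 20.0
    obs_sd_sst: float = 0.3
    declination_min_deg: float = 3.0
    light_threshold: float = 0.3
    twilight_smooth_min: float = 10.0
    process_sigma_km: float = -1.0  # negative -> maximum-likelihood search
    # thermal events
    merge_gap_min: float = 10.0
    min_duration_min: float = 1.0
    event_smooth_min: float = 5.0
    # dart-tag cohort
    pdt_n_per_year: int = 300
    pdt_years_start: int = 1980
    pdt_years_end: int = 1989
    pdt_p_spawning_potential: float = 0.22
    pdt_recapture_rate: float = 0.25
    out_dir: str = "physiotag_out"

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_toml(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, str):
                    fh.write(f'{f.name} = "{v}"\n')
                elif isinstance(v, bool):
                    fh.write(f"{f.name} = {str(v).lower()}\n")
                else:
                    fh.write(f"{f.name} = {v}\n")
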