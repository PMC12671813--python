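"""CSV / NetCDF interchange for tag series, tracks and cohort tables.

Tag series CSVs have columns ``timestamp_utc`` (ISO-8601), ``depth_m``,
``temp_internal_c``, ``temp_external_c``, ``light``; tracks have ``date``,
``lat``, ``lon``, ``sd_lat``, ``sd_lon``.  SST fields round-trip through
NetCDF (scipy backend) with a long-format CSV fallback; see
:class:`physiotag.simulate.SSTField`.
"""

from __future__ import annotations

import pandas as pd

from .series import REQUIRED_COLUMNS, TagSeries
from .geolocation import Track

__all__ = [
    "read_tag_series",
    "write_tag_series",
    "read_track",
    "write_track",
    "read_pdt_table",
    "read_gonad_samples",
]


def read_tag_series(path, tag_id: str | None = None) -> TagSeries:
    """Read a tag series CSV; rows are sorted by time, duplicates rejected."""
    df = pd.read_csv(path)
    missing = [c for c in ["timestamp_utc", *REQUIRED_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"tag series CSV missing column(s): {', '.join(missing)}")
    df["timestamp_utc"] = pd.to_datetime(df["timestamp_utc"])
    df = df.sort_values("timestamp_utc").set_index("timestamp_utc")
    return TagSeries(data=df[REQUIRED_COLUMNS], tag_id=tag_id or str(path))


def write_tag_series(series: TagSeries, path, events_path=None, path_path=None) -> None:
    """Write a series CSV, optionally with ground-truth sidecar CSVs."""
    out = series.data.copy()
    out.index.name = "timestamp_utc"
    out.reset_index().assign(
        timestamp_utc=lambda d: d["timestamp_utc"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    ).to_csv(path, index=False)
    if events_path is not None and series.events_truth is not None:
        series.events_truth.to_csv(events_path, index=False)
    if path_path is not None and series.true_path is not None:
        series.true_path.to_csv(path_path, index=False)


def write_track(track: Track, path) -> None:
    track.data.assign(date=lambda d: pd.to_datetime(d["date"]).dt.strftime("%Y-%m-%d")).to_csv(
        path, index=False
    )


def read_track(path) -> Track:
    df = pd.read_csv(path, parse_dates=["date"])
    needed = {"date", "lat", "lon"}
    if not needed <= set(df.columns):
        raise ValueError(f"track CSV missing column(s): {', '.join(sorted(needed - set(df.columns)))}")
    return Track(data=df)


def read_pdt_table(path) -> pd.DataFrame:
    """Release/recapture table with ``release_date``/``recapture_date`` parsed."""
    df = pd.read_csv(path)
    for col in ("release_date", "recapture_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def read_gonad_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "capture_date" in df.columns:
        df["capture_date"] = pd.to_datetime(df["capture_date"])
    return df
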