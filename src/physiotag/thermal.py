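"""Thermal physiology: daily aggregation, threshold flags, clustering, events.

Skipjack tuna maintain body (peritoneal) temperature above ambient, but the
core red muscle is thought to overheat near 35 degC; with an estimated 4 degC
gradient between red muscle and the peritoneal cavity, peritoneal records
above 31 degC mark extraordinary thermal events.  This module aggregates a
tag's records to daily means/maxima, compares experienced temperatures with
the 24 degC spawning threshold and the 18 degC lower lethal limit, clusters
(daily max body temperature, daily mean water temperature) pairs into two
groups with an in-repo group-average (UPGMA) agglomerative algorithm, and
extracts and characterises above-threshold events (onset, peak, duration,
local-solar onset hour, inter-event intervals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .series import TagSeries
from .geolocation import tag_sst_daily

__all__ = [
    "PhysioThresholds",
    "daily_thermal_summary",
    "monthly_experienced",
    "agglomerative_cluster",
    "detect_thermal_events",
    "event_onset",
    "event_interval_stats",
    "onset_hour_histogram",
]


@dataclass(frozen=True)
class PhysioThresholds:
    """Physiologically meaningful temperatures and spatial rules.

    The event threshold is derived, not free: red-muscle overheating limit
    (35 degC) minus the red-muscle-to-peritoneal gradient (4 degC) = 31 degC.
    """

    t_spawn_c: float = 24.0
    t_lethal_low_c: float = 18.0
    t_redmuscle_max_c: float = 35.0
    gradient_rm_peritoneal_c: float = 4.0
    boundary_lat_deg: float = 25.0
    release_min_lat_deg: float = 35.0
    southward_min_deg: float = 0.1

    @property
    def t_event_c(self) -> float:
        return self.t_redmuscle_max_c - self.gradient_rm_peritoneal_c

    def __post_init__(self) -> None:
        if not self.t_lethal_low_c < self.t_spawn_c < self.t_event_c:
            raise ValueError("thresholds must satisfy lethal < spawn < event")


def daily_thermal_summary(series: TagSeries, depth_cutoff_m: float = 5.0) -> pd.DataFrame:
    """Daily mean water and max body temperature (days bound by UTC midnight).

    Returns columns ``date``, ``mean_water_c``, ``max_body_c``, ``sst_c``
    (shallow-sample mean, NaN where no sample is above the depth cutoff)
    and ``n_samples``.
    """
    if len(series.data) == 0:
        raise ValueError("empty tag series")
    day = series.data.index.normalize()
    agg = series.data.groupby(day).agg(
        mean_water_c=("temp_external_c", "mean"),
        max_body_c=("temp_internal_c", "max"),
        n_samples=("temp_external_c", "size"),
    )
    sst = tag_sst_daily(series, depth_cutoff_m).set_index("date")["sst_c"]
    agg["sst_c"] = sst.reindex(agg.index)
    return agg.reset_index(names="date")[
        ["date", "mean_water_c", "max_body_c", "sst_c", "n_samples"]
    ]


def monthly_experienced(
    daily_tables: dict[str, pd.DataFrame],
    group_labels: dict[str, str],
    thresholds: PhysioThresholds | None = None,
) -> pd.DataFrame:
    """Monthly water temperature experienced, pooled within movement group.

    Daily mean water temperatures from all individuals of a group are pooled
    by calendar month (1-12).  ``flag_spawning_suitable`` marks months whose
    pooled mean is at or above the 24 degC spawning threshold;
    ``flag_lethal_limit`` marks months in contact with the 18 degC lower
    lethal limit, i.e. whose mean minus one daily sd reaches it (a typical
    day dips to the limit even when the monthly mean sits just above).
    """
    th = thresholds or PhysioThresholds()
    frames = []
    for tag_id, table in daily_tables.items():
        if tag_id not in group_labels:
            raise ValueError(f"no group label for tag {tag_id!r}")
        f = table[["date", "mean_water_c"]].copy()
        f["group"] = group_labels[tag_id]
        frames.append(f)
    pooled = pd.concat(frames, ignore_index=True)
    pooled["month"] = pd.to_datetime(pooled["date"]).dt.month
    out = (
        pooled.groupby(["month", "group"])["mean_water_c"]
        .agg(mean_c="mean", sd_c="std", n_days="size")
        .reset_index()
    )
    out["sd_c"] = out["sd_c"].fillna(0.0)
    out["flag_spawning_suitable"] = out["mean_c"] >= th.t_spawn_c
    out["flag_lethal_limit"] = (out["mean_c"] - out["sd_c"]) <= th.t_lethal_low_c
    return out


# ---------------------------------------------------------------------------
# Agglomerative clustering (UPGMA), implemented in-repo
# ---------------------------------------------------------------------------


def agglomerative_cluster(points, k: int = 2, linkage: str = "average") -> np.ndarray:
    """Group-average (UPGMA) agglomerative clustering into ``k`` clusters.

    Naive O(n^3) implementation on the full Euclidean distance matrix; at
    each step the pair of clusters with the smallest average inter-cluster
    distance is merged, ties broken by the lexicographically smallest index
    pair, which makes the labelling deterministic for a given input order.
    Labels are integers 0..k-1 assigned in order of each cluster's first
    member.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be a 2-D array (n, d)")
    n = len(X)
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} points")
    if linkage != "average":
        raise ValueError("only group-average (UPGMA) linkage is implemented")

    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    members = {i: [i] for i in range(n)}

    for _ in range(n - k):
        flat = np.argmin(D)  # row-major argmin = lowest (i, j) on ties
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        # group-average update: weighted by cluster sizes
        new_row = (sizes[i] * D[i] + sizes[j] * D[j]) / (sizes[i] + sizes[j])
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        sizes[i] += sizes[j]
        active[j] = False
        members[i].extend(members.pop(j))

    labels = np.empty(n, dtype=int)
    roots = sorted((min(m), r) for r, m in members.items())
    for label, (_, root) in enumerate(roots):
        labels[members[root]] = label
    return labels


# ---------------------------------------------------------------------------
# Extraordinary thermal events
# ---------------------------------------------------------------------------


def _smoothed_internal(series: TagSeries, smooth_window_min: float) -> pd.Series:
    window = max(int(round(smooth_window_min * 60.0 / series.sampling_s)), 1)
    return (
        series.data["temp_internal_c"].rolling(window, center=True, min_periods=1).mean()
    )


def event_onset(
    series: TagSeries,
    crossing_utc,
    smooth_window_min: float = 5.0,
    max_back_min: float = 120.0,
) -> pd.Timestamp:
    """Trace an event back from its threshold crossing to the start of the rise.

    Walks backward from the crossing along the centred moving-average body
    temperature while the backward difference stays positive (the smoothed
    curve is still rising when read forward), bounded at ``max_back_min``
    before the crossing.  The centred window advances the apparent start of
    a rise by half a window, so half a window is added back to the stopping
    time (capped at the crossing) -- an instantaneous step then yields
    onset == crossing and a clean ramp yields its true foot.
    """
    s = _smoothed_internal(series, smooth_window_min).to_numpy()
    idx = series.data.index
    c = int(idx.get_indexer([pd.Timestamp(crossing_utc)], method="nearest")[0])
    dt_s = series.sampling_s
    max_back = int(round(max_back_min * 60.0 / dt_s))
    i = c
    while i > 0 and (c - i) < max_back and s[i] - s[i - 1] > 0:
        i -= 1
    onset = idx[i] + pd.Timedelta(seconds=smooth_window_min * 60.0 / 2.0)
    return min(onset, idx[c])


def detect_thermal_events(
    series: TagSeries,
    thresholds: PhysioThresholds | None = None,
    merge_gap_min: float = 10.0,
    min_duration_min: float = 1.0,
    track: pd.DataFrame | None = None,
    smooth_window_min: float = 5.0,
) -> pd.DataFrame:
    """Extract maximal runs of body temperature at or above the event threshold.

    Runs separated by a below-threshold gap shorter than ``merge_gap_min``
    are merged; merged runs spanning less than ``min_duration_min`` are
    discarded (single-sample noise guards -- the physiological criterion is
    the 31 degC threshold itself).  Each event carries its onset (see
    :func:`event_onset`), peak, end, minutes spent at or above threshold and
    the onset hour in local solar time from the day's estimated longitude
    (NaN when no position is available).

    Returns a DataFrame with columns ``onset_utc``, ``crossing_utc``,
    ``peak_c``, ``peak_utc``, ``end_utc``, ``duration_above_min``,
    ``onset_local_solar_hour``.
    """
    th = thresholds or PhysioThresholds()
    cols = [
        "onset_utc", "crossing_utc", "peak_c", "peak_utc", "end_utc",
        "duration_above_min", "onset_local_solar_hour",
    ]
    temp = series.data["temp_internal_c"].to_numpy()
    idx = series.data.index
    dt_s = series.sampling_s
    above = temp >= th.t_event_c
    if not above.any():
        return pd.DataFrame(columns=cols)
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(temp) - 1)

    # merge runs separated by short dips
    merged = [[starts[0], ends[0]]]
    for s0, e0 in zip(starts[1:], ends[1:]):
        gap_min = (s0 - merged[-1][1] - 1) * dt_s / 60.0
        if gap_min < merge_gap_min:
            merged[-1][1] = e0
        else:
            merged.append([s0, e0])

    lon_by_date = None
    if track is not None and len(track):
        lon_by_date = pd.Series(
            track["lon"].to_numpy(), index=pd.to_datetime(track["date"]).dt.normalize()
        )

    rows = []
    for s0, e0 in merged:
        n_samp = e0 - s0 + 1
        if n_samp * dt_s / 60.0 < min_duration_min:
            continue
        seg = temp[s0 : e0 + 1]
        peak_i = s0 + int(np.argmax(seg))
        crossing = idx[s0]
        onset = event_onset(series, crossing, smooth_window_min)
        local_hour = np.nan
        if lon_by_date is not None:
            day = onset.normalize()
            if day in lon_by_date.index:
                lon = float(lon_by_date.loc[day]) if np.ndim(lon_by_date.loc[day]) == 0 else float(np.asarray(lon_by_date.loc[day])[0])
                t_local = onset + pd.Timedelta(hours=lon / 15.0)
                local_hour = (
                    t_local.hour + t_local.minute / 60.0 + t_local.second / 3600.0
                )
        rows.append(
            {
                "onset_utc": onset,
                "crossing_utc": crossing,
                "peak_c": float(seg.max()),
                "peak_utc": idx[peak_i],
                "end_utc": idx[e0],
                "duration_above_min": n_samp * dt_s / 60.0,
                "onset_local_solar_hour": local_hour,
            }
        )
    return pd.DataFrame(rows, columns=cols)


def event_interval_stats(events: pd.DataFrame):
    """Successive onset-to-onset intervals in days, with a min/median/max summary."""
    if len(events) < 2:
        return np.array([]), {"n_intervals": 0}
    onsets = pd.to_datetime(events["onset_utc"]).sort_values()
    intervals = onsets.diff().dropna().dt.total_seconds().to_numpy() / 86400.0
    summary = {
        "n_intervals": len(intervals),
        "min_days": float(intervals.min()),
        "median_days": float(np.median(intervals)),
        "max_days": float(intervals.max()),
    }
    return intervals, summary


def onset_hour_histogram(events: pd.DataFrame) -> np.ndarray:
    """24-bin histogram of event onset hours (local solar time)."""
    counts = np.zeros(24, dtype=int)
    if len(events) == 0:
        return counts
    hours = events["onset_local_solar_hour"].to_numpy(dtype=float)
    hours = hours[np.isfinite(hours)]
    for h in np.floor(hours).astype(int) % 24:
        counts[h] += 1
    return counts
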