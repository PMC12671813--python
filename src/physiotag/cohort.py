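"""Mark-recapture cohort summaries for plastic-dart-tag (PDT) records.

A PDT yields only a release and (sometimes) a recapture date/position.  The
southward-movement analysis keeps fish released north of 35 degN whose
recapture latitude lies at least 0.1 deg south of the release latitude,
classifies each recapture as spawning-potential (south of 25 degN) or
residence, and summarises counts, proportions and recapture rates by decade
of release.  With yearly recapture counts as weights, the weighted mean of
yearly spawning-potential proportions collapses algebraically to the pooled
proportion -- kept as a tested identity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .track_metrics import classify_movement_group

__all__ = [
    "filter_southward",
    "recapture_rate",
    "decadal_group_counts",
    "pooled_proportion",
    "weighted_proportion",
    "decadal_summary",
]


def filter_southward(
    records: pd.DataFrame,
    release_min_lat: float = 35.0,
    southward_min_deg: float = 0.1,
) -> pd.DataFrame:
    """Keep recaptured fish released north of ``release_min_lat`` that moved south.

    A record passes when ``release_lat >= release_min_lat`` and
    ``release_lat - recapture_lat >= southward_min_deg``.  Unrecaptured
    records (missing recapture position) are dropped.  Idempotent.
    """
    rec = records.dropna(subset=["recapture_lat"])
    keep = (rec["release_lat"] >= release_min_lat) & (
        (rec["release_lat"] - rec["recapture_lat"]) >= southward_min_deg
    )
    return rec[keep].reset_index(drop=True)


def recapture_rate(n_released: int, n_recaptured: int) -> float:
    """Recapture rate in percent, rounded to one decimal (table precision)."""
    if n_released <= 0:
        raise ValueError("no releases")
    if not 0 <= n_recaptured <= n_released:
        raise ValueError("recaptures must lie between 0 and releases")
    return round(100.0 * n_recaptured / n_released, 1)


def _decade_label(year: int) -> str:
    return f"{(year // 10) * 10}s"


def decadal_group_counts(records: pd.DataFrame, boundary_deg: float = 25.0) -> pd.DataFrame:
    """Spawning-potential / residence counts per release decade.

    Records are expected to have passed :func:`filter_southward`.  The
    decade comes from the release date (the only date guaranteed present);
    the group from the recapture latitude.  Also reports the minimum
    recapture latitude per decade.
    """
    cols = ["decade", "n_spawning_potential", "n_residence", "min_recapture_lat"]
    if records.empty:
        return pd.DataFrame(columns=cols)
    df = records.copy()
    df["decade"] = pd.to_datetime(df["release_date"]).dt.year.map(_decade_label)
    df["group"] = [
        classify_movement_group([lat], basis="recapture_latitude", boundary_deg=boundary_deg).label
        for lat in df["recapture_lat"]
    ]
    rows = []
    for decade, sub in df.groupby("decade", sort=True):
        rows.append(
            {
                "decade": decade,
                "n_spawning_potential": int((sub["group"] == "spawning_potential").sum()),
                "n_residence": int((sub["group"] == "residence").sum()),
                "min_recapture_lat": float(sub["recapture_lat"].min()),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def pooled_proportion(n_sp: int, n_res: int) -> float:
    """Pooled spawning-potential percentage, rounded to two decimals."""
    if n_sp + n_res <= 0:
        raise ValueError("no records")
    return round(100.0 * n_sp / (n_sp + n_res), 2)


def weighted_proportion(yearly_props, weights) -> tuple[float, float]:
    """Weighted mean and population-form weighted sd of yearly percentages.

    ``mean = sum(w*p)/sum(w)``; ``sd = sqrt(sum(w*(p - mean)^2)/sum(w))``.
    With yearly recapture counts as weights and ``p = 100*n_sp/count``, the
    mean equals the pooled proportion exactly.
    """
    p = np.asarray(yearly_props, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape:
        raise ValueError("props and weights must have matching length")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() == 0:
        raise ValueError("weights sum to zero")
    mean = float((w * p).sum() / w.sum())
    sd = float(np.sqrt((w * (p - mean) ** 2).sum() / w.sum()))
    return mean, sd


def decadal_summary(records: pd.DataFrame, boundary_deg: float = 25.0) -> pd.DataFrame:
    """Group counts plus pooled and recapture-weighted proportions per decade."""
    counts = decadal_group_counts(records, boundary_deg)
    if counts.empty:
        return counts.assign(pooled_pct=[], weighted_mean_pct=[], weighted_sd_pct=[])
    df = records.copy()
    df["year"] = pd.to_datetime(df["release_date"]).dt.year
    df["decade"] = df["year"].map(_decade_label)
    df["sp"] = df["recapture_lat"] < boundary_deg
    pooled, wmean, wsd = [], [], []
    for decade in counts["decade"]:
        sub = df[df["decade"] == decade]
        yearly = sub.groupby("year")["sp"].agg(["sum", "size"])
        props = 100.0 * yearly["sum"] / yearly["size"]
        m, s = weighted_proportion(props.to_numpy(), yearly["size"].to_numpy(dtype=float))
        pooled.append(pooled_proportion(int(sub["sp"].sum()), int((~sub["sp"]).sum())))
        wmean.append(m)
        wsd.append(s)
    counts["pooled_pct"] = pooled
    counts["weighted_mean_pct"] = wmean
    counts["weighted_sd_pct"] = wsd
    return counts
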