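"""Published summary tables from the Japanese skipjack tagging program.

These small tables are the printed, public summaries of half a century of
plastic-dart-tag (PDT) releases north of 35 degN and of the archival-tag
deployments analysed by this package; they are inputs to the desk-scale
statistics (recapture rates, pooled spawning-potential proportions, days at
liberty), not fixtures derived from this package's own output.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["pdt_decadal_releases", "pdt_decadal_groups", "archival_deployments"]


def pdt_decadal_releases() -> pd.DataFrame:
    """Decadal PDT release and recapture counts (releases north of 35 degN)."""
    return pd.DataFrame(
        {
            "decade": ["1980s", "1990s", "2000s", "2010s", "2020s"],
            "n_released": [1029, 12837, 8804, 2350, 7168],
            "n_recaptured": [257, 643, 999, 180, 301],
        }
    )


def pdt_decadal_groups() -> pd.DataFrame:
    """Decadal spawning-potential / residence counts among southward recaptures."""
    return pd.DataFrame(
        {
            "decade": ["1980s", "1990s", "2000s", "2010s", "2020s"],
            "n_spawning_potential": [18, 53, 15, 1, 2],
            "n_residence": [63, 359, 152, 61, 138],
            "min_recapture_lat": [2.18, 0.60, 5.97, 22.08, 16.73],
        }
    )


def archival_deployments() -> pd.DataFrame:
    """Release/recapture endpoints of the analysed archival-tag deployments."""
    rows = [
        ("8943", "2021-10-25", 36.72, 141.47, 54.0, "2022-04-28", 33.54, 136.52),
        ("8950", "2021-10-25", 36.43, 141.47, 53.0, "2022-05-19", 30.83, 138.67),
        ("9222", "2021-11-04", 36.85, 141.32, 54.0, "2022-05-23", 32.48, 133.20),
        ("9244", "2021-11-03", 36.70, 141.33, 54.0, "2022-06-08", 33.75, 139.97),
        ("8947", "2021-10-25", 36.72, 141.47, 54.0, "2022-07-04", 33.50, 136.08),
        ("9147", "2021-10-25", 36.43, 141.47, 56.0, "2022-07-07", 33.94, 138.82),
        ("9149", "2021-10-25", 36.72, 141.47, 55.0, "2022-07-14", 34.52, 139.27),
        ("8312", "2020-10-16", 40.98, 150.90, 35.5, "2021-05-11", 32.33, 136.83),
        ("6977", "2019-10-03", 39.17, 143.98, 50.0, "2020-05-07", 34.30, 137.30),
        ("6955", "2019-10-07", 39.52, 143.70, 53.0, "2020-05-16", 33.50, 139.77),
        ("6962", "2019-10-07", 39.52, 143.70, 49.0, "2020-06-02", 33.42, 139.58),
        ("6949", "2019-10-07", 39.68, 143.62, 54.0, "2020-07-07", 36.00, 147.00),
        ("2737", "2014-06-02", 31.59, 144.23, 44.0, "2014-09-09", 27.37, 129.43),
        ("2815", "2014-06-02", 31.59, 144.23, 43.0, "2016-03-30", 22.58, 149.42),
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "tag_id", "release_date", "release_lat", "release_lon", "fl_release_cm",
            "recapture_date", "recapture_lat", "recapture_lon",
        ],
    )
    df["release_date"] = pd.to_datetime(df["release_date"])
    df["recapture_date"] = pd.to_datetime(df["recapture_date"])
    return df
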