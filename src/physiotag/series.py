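"""The archival-tag record container.

A :class:`TagSeries` holds one tag's regularly sampled sensor records
(depth, internal/peritoneal temperature, external/ambient temperature and
light level) plus whatever deployment metadata is known.  Synthetic series
additionally carry the simulator's ground truth (implanted thermal events
and the true daily path) so detectors can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

REQUIRED_COLUMNS = ["depth_m", "temp_internal_c", "temp_external_c", "light"]


@dataclass
class TagSeries:
    """One tag's timestamped sensor records.

    ``data`` is indexed by UTC timestamp (tz-naive, interpreted as UTC) and
    has columns ``depth_m``, ``temp_internal_c``, ``temp_external_c`` and
    ``light``.  ``events_truth`` and ``true_path`` are populated only for
    simulated series.
    """

    data: pd.DataFrame
    tag_id: str = "tag"
    release_lat: float | None = None
    release_lon: float | None = None
    events_truth: pd.DataFrame | None = field(default=None, repr=False)
    true_path: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"tag series missing column(s): {', '.join(missing)}")
        if not self.data.index.is_monotonic_increasing:
            self.data = self.data.sort_index()
        if self.data.index.has_duplicates:
            raise ValueError("tag series has duplicate timestamps")

    @property
    def sampling_s(self) -> float:
        dt = self.data.index.to_series().diff().dropna()
        return float(dt.median().total_seconds())

    @property
    def n_days(self) -> int:
        return int(self.data.index.normalize().nunique())

    def __len__(self) -> int:
        return len(self.data)
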