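"""The per-county daily series container used by every analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DailySeries", "SERIES_COLUMNS", "POLLUTANTS"]

POLLUTANTS = ("pm25", "o3", "no2")
SERIES_COLUMNS = ("date", "pm25", "o3", "no2", "temp", "rh", "count")


@dataclass
class DailySeries:
    """One county's aligned daily exposures, weather and ED counts.

    ``frame`` columns: date (datetime), pm25 (ug/m3, 24-h mean), o3 (ppb,
    8-h max), no2 (ppb, 1-h max), temp (daily mean), rh (%, daily mean),
    count (non-negative integer respiratory ED visits). Dates are strictly
    increasing with no duplicates; calendar gaps are tolerated for real
    data but never produced by the simulator. Simulated series carry the
    injected ground truth in ``true_rr_per_iqr`` / ``true_beta_per_unit``.
    """

    county_id: str
    frame: pd.DataFrame
    true_rr_per_iqr: dict[str, float] | None = None
    true_beta_per_unit: dict[str, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.frame
        missing = set(SERIES_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"series frame missing columns: {sorted(missing)}")
        dates = pd.to_datetime(df["date"])
        if not dates.is_monotonic_increasing or dates.duplicated().any():
            dup = dates[dates.duplicated()]
            raise ValueError(
                f"dates must be strictly increasing without duplicates"
                + (f"; duplicated: {list(dup.dt.date.unique())}" if len(dup) else "")
            )
        self.frame = df.assign(date=dates).reset_index(drop=True)
        cnt = self.frame["count"]
        ok = cnt.dropna()
        if (ok < 0).any() or not np.allclose(ok, np.round(ok)):
            raise ValueError("counts must be non-negative integers")
        for pol in POLLUTANTS:
            if (self.frame[pol].dropna() < 0).any():
                raise ValueError(f"negative concentrations in {pol}")
        rh = self.frame["rh"].dropna()
        if ((rh < 0) | (rh > 100)).any():
            raise ValueError("relative humidity must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def is_gap_free(self) -> bool:
        d = self.frame["date"]
        return bool((d.diff().dropna() == pd.Timedelta(days=1)).all())
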