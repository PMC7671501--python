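"""Air Quality Index computation.

The U.S. AQI is a single-pollutant, regulatory index: each pollutant's
concentration maps through piecewise-linear breakpoint segments (anchored
to the NAAQS) to a dimensionless sub-index, and the day's AQI is the
maximum sub-index across pollutants.  Within a segment
``[C_lo, C_hi] -> [I_lo, I_hi]``,

    I = (I_hi - I_lo) / (C_hi - C_lo) * (C - C_lo) + I_lo,

rounded to the nearest integer (half away from zero), after the
concentration has been truncated to the pollutant's reporting precision.

Breakpoints live in a versioned CSV data file, not in code; the shipped
default is the table in force during 2012-2014 for the three pollutants
used here (24-h PM2.5 in ug/m3, 8-h max O3 in ppb, 1-h max NO2 in ppb).
Breakpoint tables have since been revised, so analyses of other periods
should load the appropriate file.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Breakpoint",
    "BreakpointTable",
    "DailyIndexValue",
    "sub_index",
    "daily_aqi",
    "daily_aqi_series",
    "AQITransformer",
    "TIE_BREAK_PRIORITY",
]

log = logging.getLogger(__name__)

# deterministic tie-break when two pollutants share the maximum sub-index
TIE_BREAK_PRIORITY = ("pm25", "o3", "no2")


@dataclass(frozen=True)
class Breakpoint:
    conc_lo: float
    conc_hi: float
    index_lo: int
    index_hi: int
    category: str = ""


@dataclass
class BreakpointTable:
    """Per-pollutant piecewise-linear AQI segments.

    ``segments`` maps pollutant -> ordered list of :class:`Breakpoint`;
    ``decimals`` maps pollutant -> concentration truncation precision.
    Segments must be contiguous (each ``conc_lo`` equals the previous
    ``conc_hi`` plus one truncation unit) with non-decreasing index ranges.
    """

    segments: dict[str, list[Breakpoint]]
    decimals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for pol, segs in self.segments.items():
            if not segs:
                raise ValueError(f"no breakpoint segments for {pol!r}")
            segs.sort(key=lambda s: s.conc_lo)
            unit = 10.0 ** -self.decimals.get(pol, 0)
            for prev, cur in zip(segs, segs[1:]):
                if not math.isclose(cur.conc_lo, prev.conc_hi + unit, rel_tol=0, abs_tol=unit * 1e-6):
                    raise ValueError(
                        f"{pol}: segment starting at {cur.conc_lo} is not contiguous "
                        f"with previous segment ending at {prev.conc_hi}"
                    )
                if cur.index_lo < prev.index_hi:
                    raise ValueError(f"{pol}: index ranges must be non-decreasing")
            for s in segs:
                if s.index_lo > s.index_hi:
                    raise ValueError(f"{pol}: index_lo > index_hi in segment {s}")

    @property
    def pollutants(self) -> list[str]:
        return list(self.segments)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BreakpointTable":
        required = {"pollutant", "conc_lo", "conc_hi", "index_lo", "index_hi"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"breakpoint table missing columns: {sorted(missing)}")
        segments: dict[str, list[Breakpoint]] = {}
        decimals: dict[str, int] = {}
        for _, row in df.iterrows():
            pol = str(row["pollutant"])
            segments.setdefault(pol, []).append(
                Breakpoint(
                    float(row["conc_lo"]),
                    float(row["conc_hi"]),
                    int(row["index_lo"]),
                    int(row["index_hi"]),
                    str(row.get("category", "")),
                )
            )
            decimals[pol] = int(row.get("decimals", 0))
        return cls(segments, decimals)

    @classmethod
    def from_csv(cls, path) -> "BreakpointTable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def default(cls) -> "BreakpointTable":
        """The breakpoint table in force 2012-2014 (shipped data file)."""
        ref = importlib.resources.files("aqindex.data") / "aqi_breakpoints_2012.csv"
        with importlib.resources.as_file(ref) as p:
            return cls.from_csv(p)


@dataclass(frozen=True)
class DailyIndexValue:
    """One day's AQI: the maximum sub-index and the pollutant driving it."""

    date: object
    value: float  # integer-valued; NaN when no pollutant was available
    responsible_pollutant: str | None
    sub_indices: dict[str, float]


def _truncate(conc: float, decimals: int) -> float:
    scale = 10.0**decimals
    return math.floor(conc * scale + 1e-9) / scale


def sub_index(conc: float, pollutant: str, table: BreakpointTable | None = None) -> int:
    """Piecewise-linear AQI sub-index for one pollutant concentration.

    The concentration is truncated to the pollutant's reporting precision
    before segment lookup. Concentrations above the last segment clamp to
    the top index with a logged warning.
    """
    if table is None:
        table = BreakpointTable.default()
    if pollutant not in table.segments:
        raise KeyError(f"unknown pollutant {pollutant!r}; table has {table.pollutants}")
    if not conc >= 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    c = _truncate(float(conc), table.decimals.get(pollutant, 0))
    segs = table.segments[pollutant]
    if c > segs[-1].conc_hi:
        log.warning(
            "%s concentration %.4g above top breakpoint %.4g; clamping to index %d",
            pollutant, conc, segs[-1].conc_hi, segs[-1].index_hi,
        )
        return segs[-1].index_hi
    for s in segs:
        if c <= s.conc_hi + 1e-12:
            frac = 0.0 if s.conc_hi == s.conc_lo else (c - s.conc_lo) / (s.conc_hi - s.conc_lo)
            val = s.index_lo + (s.index_hi - s.index_lo) * frac
            return int(math.floor(val + 0.5))  # half away from zero (val >= 0)
    raise AssertionError("unreachable: contiguous segments cover [0, top]")


def daily_aqi(record, table: BreakpointTable | None = None) -> DailyIndexValue:
    """AQI for one day's record (mapping or Series with pollutant fields).

    Missing pollutants are excluded; if every pollutant is missing the index
    value is NaN (missing, never zero). Ties at the maximum are broken by
    the fixed priority pm25 > o3 > no2.
    """
    if table is None:
        table = BreakpointTable.default()
    subs: dict[str, float] = {}
    for pol in table.pollutants:
        try:
            conc = record[pol]
        except (KeyError, IndexError):
            continue
        if conc is None or (isinstance(conc, float) and math.isnan(conc)):
            continue
        subs[pol] = sub_index(conc, pol, table)
    date = record.get("date") if hasattr(record, "get") else None
    if not subs:
        return DailyIndexValue(date, float("nan"), None, subs)
    order = {p: i for i, p in enumerate(TIE_BREAK_PRIORITY)}
    best = max(subs, key=lambda p: (subs[p], -order.get(p, len(order))))
    return DailyIndexValue(date, float(subs[best]), best, subs)


def daily_aqi_series(frame: pd.DataFrame, table: BreakpointTable | None = None) -> pd.DataFrame:
    """Vectorized daily AQI over a series frame with pollutant columns.

    Returns a frame with ``date`` (if present), ``value`` and
    ``responsible_pollutant`` columns.
    """
    if table is None:
        table = BreakpointTable.default()
    n = len(frame)
    pols = [p for p in table.pollutants if p in frame.columns]
    if not pols:
        raise ValueError(f"no pollutant columns among {table.pollutants} in frame")
    subs = np.full((n, len(pols)), np.nan)
    for j, pol in enumerate(pols):
        col = frame[pol].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        subs[ok, j] = [sub_index(c, pol, table) for c in col[ok]]
    # tie-break: order columns by priority so argmax on the reversed check
    prio = {p: i for i, p in enumerate(TIE_BREAK_PRIORITY)}
    col_order = sorted(range(len(pols)), key=lambda j: prio.get(pols[j], len(prio)))
    values = np.full(n, np.nan)
    responsible = np.array([None] * n, dtype=object)
    for j in col_order:
        s = subs[:, j]
        better = (~np.isnan(s)) & (np.isnan(values) | (s > values))
        values[better] = s[better]
        responsible[better] = pols[j]
    out = pd.DataFrame({"value": values, "responsible_pollutant": responsible})
    if "date" in frame.columns:
        out.insert(0, "date", frame["date"].to_numpy())
    return out


class AQITransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping pollutant concentrations to daily AQI.

    ``transform`` accepts a DataFrame with pollutant columns and returns an
    ``(n, 1)`` array of AQI values; composes with sklearn pipelines.
    """

    def __init__(self, table: BreakpointTable | None = None):
        self.table = table

    def fit(self, X, y=None):
        self.table_ = self.table if self.table is not None else BreakpointTable.default()
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "table_"):
            self.fit(X)
        return daily_aqi_series(X, self.table_)["value"].to_numpy().reshape(-1, 1)

    def get_feature_names_out(self, input_features=None):
        return np.array(["aqi"])
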