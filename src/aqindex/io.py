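"""Tabular readers and writers.

All interchange is headered CSV with ISO-8601 dates; missing values are
empty fields, never sentinel numbers. Floats are written at full
round-trip precision so write-then-read reproduces a series exactly.
"""

from __future__ import annotations

import importlib.resources
import logging

import numpy as np
import pandas as pd

from .health import EXPECTED_UNITS, CoefficientSet, PooledCoefficient
from .series import SERIES_COLUMNS, DailySeries

__all__ = [
    "read_daily_series",
    "write_daily_series",
    "read_coefficient_studies",
    "write_pooled_coefficients",
    "read_pooled_coefficients",
    "load_demographic_counts",
    "load_region_map",
]

log = logging.getLogger(__name__)

_CSV_COLUMNS = ("county",) + SERIES_COLUMNS[:1] + SERIES_COLUMNS[1:]  # county,date,...


def read_daily_series(path) -> list[DailySeries]:
    """Read per-county daily series from a CSV with the standard header.

    Required columns: county,date,pm25,o3,no2,temp,rh,count. Rows are
    date-sorted per county; a duplicated county-date pair is an error
    naming the offender. An empty (but headered) file yields an empty list
    with a warning.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"county", *SERIES_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    if df.empty:
        log.warning("%s contains a header but no rows", path)
        return []
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except ValueError as exc:
        raise ValueError(f"unparseable date in {path}: {exc}") from exc
    dup = df.duplicated(subset=["county", "date"])
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate county-date pair: {first['county']} {first['date'].date()}"
        )
    out = []
    for county, grp in df.groupby("county", sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        if not grp["count"].isna().all():
            bad = grp["count"].dropna() % 1 != 0
            if bad.any():
                idx = grp["count"].dropna()[bad].index[0]
                raise ValueError(
                    f"non-integer count for {county} on {grp.loc[idx, 'date'].date()}"
                )
        out.append(DailySeries(str(county), grp[list(SERIES_COLUMNS)].copy()))
    return out


def write_daily_series(series_list: list[DailySeries], path) -> None:
    """Write series as county,date,pm25,o3,no2,temp,rh,count CSV."""
    frames = []
    for s in series_list:
        f = s.frame.copy()
        f.insert(0, "county", s.county_id)
        frames.append(f)
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_CSV_COLUMNS)
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format="%.17g")


def read_coefficient_studies(path) -> pd.DataFrame:
    """Read a study-level coefficient table: pollutant,study_id,beta,se,units.

    Hard-fails when a pollutant's units do not match the daily-series
    units (ug/m3 for pm25, ppb for o3 and no2).
    """
    df = pd.read_csv(path)
    required = {"pollutant", "beta", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coefficient file missing column(s): {sorted(missing)}")
    if (df["se"] <= 0).any():
        raise ValueError("all coefficient standard errors must be positive")
    if "units" in df.columns:
        for pol, grp in df.groupby("pollutant"):
            expected = EXPECTED_UNITS.get(str(pol))
            got = set(grp["units"].astype(str))
            if expected is not None and got != {expected}:
                raise ValueError(
                    f"units mismatch for {pol}: file says {sorted(got)}, series are in {expected}"
                )
    return df


def write_pooled_coefficients(coeffs: CoefficientSet, path) -> None:
    coeffs.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_pooled_coefficients(path, scaling_constant: float = 1.0) -> CoefficientSet:
    df = pd.read_csv(path)
    coeffs = {
        str(r.pollutant): PooledCoefficient(
            str(r.pollutant), float(r.beta), float(r.se),
            float(getattr(r, "tau2", 0.0)), int(getattr(r, "k", 1)),
        )
        for r in df.itertuples()
    }
    return CoefficientSet(coeffs, scaling_constant)


def _package_csv(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("aqindex.data") / name
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


def load_demographic_counts() -> pd.DataFrame:
    """Published demographic totals of adult respiratory ED visits, three
    California regions, 2012-2014 (tidy: region,variable,category,count)."""
    return _package_csv("ca_respiratory_ed_demographics_2012_2014.csv")


def load_region_map() -> pd.DataFrame:
    """Default county-to-region grouping for the three California regions."""
    return _package_csv("region_counties.csv")
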