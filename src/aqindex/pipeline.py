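"""End-to-end run: series -> indices -> county fits -> pooled estimates.

One config drives the whole workflow; outputs are deterministic given
config + seed, and a run manifest records the config hash, seed, package
version and a checksum for every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .aqi import BreakpointTable, daily_aqi_series
from .association import estimate_association, pool_counties, spearman_table
from .glm import ModelSpec
from .health import CoefficientSet, health_index_series
from .io import read_coefficient_studies, read_daily_series
from .health import pool_study_table
from .series import POLLUTANTS, DailySeries

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

KNOWN_EXPOSURES = POLLUTANTS + ("aqi", "hbi")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    series_path: str
    output_dir: str
    coefficients_path: Optional[str] = None
    breakpoints_path: Optional[str] = None
    region_map: Optional[dict] = None  # county -> region
    seasons: tuple = ("cool", "warm")
    exposures: tuple = ("pm25", "o3", "no2", "aqi")
    lags: tuple = ((0, 3),)
    temp_df: object = 3
    lagtemp_df: object = 3
    rh_df: object = 3
    dow_coding: str = "indicators"
    seed: int = 0

    def __post_init__(self):
        unknown = [e for e in self.exposures if e not in KNOWN_EXPOSURES]
        if unknown:
            raise ValueError(f"unknown exposure(s) {unknown}; known: {list(KNOWN_EXPOSURES)}")
        bad = [s for s in self.seasons if s not in ("cool", "warm", "all")]
        if bad:
            raise ValueError(f"unknown season(s): {bad}")
        if "hbi" in self.exposures and not self.coefficients_path:
            raise ValueError("exposure 'hbi' requires coefficients_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("seasons", "exposures"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "lags" in raw:
            raw["lags"] = tuple(tuple(l) for l in raw["lags"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to disk).

    Per county x season x exposure x lag an association row is produced;
    counties sharing a region are pooled per season/exposure/lag; Spearman
    correlation tables are written per region and season. Failures are
    isolated per county-task and logged; the manifest lists them, and the
    caller decides the exit status.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_list = read_daily_series(config.series_path)
    if not series_list:
        raise ValueError(f"no series found in {config.series_path}")

    table = (
        BreakpointTable.from_csv(config.breakpoints_path)
        if config.breakpoints_path
        else BreakpointTable.default()
    )
    coeffs: Optional[CoefficientSet] = None
    if config.coefficients_path:
        coeffs = pool_study_table(read_coefficient_studies(config.coefficients_path))

    region_of = config.region_map or {}

    index_values: dict[tuple[str, str], pd.Series] = {}
    assoc_rows, failures = [], []
    estimates: dict[tuple, list] = {}
    enriched_frames = []
    for s in series_list:
        frame = s.frame
        aqi_vals = daily_aqi_series(frame, table).set_index("date")["value"]
        index_values[(s.county_id, "aqi")] = aqi_vals
        enrich = frame.assign(aqi=aqi_vals.to_numpy())
        if coeffs is not None:
            hbi = health_index_series(frame, coeffs)
            index_values[(s.county_id, "hbi")] = pd.Series(
                hbi.to_numpy(), index=frame["date"]
            )
            enrich = enrich.assign(hbi=hbi.to_numpy())
        enrich = enrich.assign(county=s.county_id, region=region_of.get(s.county_id, "all"))
        enriched_frames.append(enrich)
        for season in config.seasons:
            for exposure in config.exposures:
                for lag in config.lags:
                    spec = ModelSpec(
                        exposure=exposure, season=season, lag=tuple(lag),
                        temp_df=config.temp_df, lagtemp_df=config.lagtemp_df,
                        rh_df=config.rh_df, dow_coding=config.dow_coding,
                    )
                    iv = index_values.get((s.county_id, exposure))
                    try:
                        est = estimate_association(s, spec, iv)
                    except Exception as exc:  # isolate per county-task
                        log.error("fit failed for %s/%s/%s/%s: %s",
                                  s.county_id, season, exposure, lag, exc)
                        failures.append(
                            {"county": s.county_id, "season": season,
                             "exposure": exposure, "lag": list(lag), "error": str(exc)}
                        )
                        continue
                    assoc_rows.append({
                        "county": est.county_id,
                        "region": region_of.get(s.county_id, "all"),
                        "season": est.season, "exposure": est.exposure,
                        "lag_min": est.lag[0], "lag_max": est.lag[1],
                        "rr_per_iqr": est.rr_per_iqr, "ci_low": est.ci_low,
                        "ci_high": est.ci_high, "iqr": est.iqr_used,
                        "log_rr": est.log_rr, "se_log_rr": est.se_log_rr,
                        "phi": est.dispersion, "n_used": est.n_used,
                        "adj_r2": est.adj_r2,
                    })
                    key = (region_of.get(s.county_id, "all"), season, exposure, tuple(lag))
                    estimates.setdefault(key, []).append(est)

    written = []

    assoc_path = out_dir / "associations.csv"
    pd.DataFrame(assoc_rows).to_csv(assoc_path, index=False, float_format="%.17g")
    written.append(assoc_path)

    pooled_rows = []
    for (region, season, exposure, lag), ests in sorted(estimates.items()):
        if len(ests) < 2:
            continue
        pa = pool_counties(ests, region=region)
        pooled_rows.append({
            "region": pa.region, "season": pa.season, "exposure": pa.exposure,
            "lag_min": pa.lag[0], "lag_max": pa.lag[1], "k": pa.k,
            "combined_rr": pa.combined_rr, "ci_low": pa.ci_low,
            "ci_high": pa.ci_high, "tau2": pa.tau2, "Q": pa.Q, "i2": pa.i2,
        })
    pooled_path = out_dir / "pooled.csv"
    pd.DataFrame(pooled_rows).to_csv(pooled_path, index=False, float_format="%.17g")
    written.append(pooled_path)

    all_days = pd.concat(enriched_frames, ignore_index=True)
    month = all_days["date"].dt.month
    all_days["season"] = pd.Series(
        pd.Categorical.from_codes(((month >= 11) | (month <= 2)).astype(int),
                                  categories=["warm", "cool"])
    )
    corr_vars = [v for v in ("aqi", "hbi", "pm25", "no2", "o3", "temp", "rh")
                 if v in all_days.columns]
    corr_frames = []
    for (region, season), grp in all_days.groupby(["region", "season"], observed=True):
        rho = spearman_table(grp, corr_vars)
        rho.insert(0, "variable", rho.index)
        rho.insert(0, "season", season)
        rho.insert(0, "region", region)
        corr_frames.append(rho)
    corr_path = out_dir / "spearman.csv"
    pd.concat(corr_frames, ignore_index=True).to_csv(corr_path, index=False, float_format="%.6g")
    written.append(corr_path)

    if coeffs is not None:
        coef_path = out_dir / "pooled_coefficients.csv"
        coeffs.to_frame().to_csv(coef_path, index=False, float_format="%.17g")
        written.append(coef_path)

    cfg_serial = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        sort_keys=True, default=str,
    )
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_serial.encode()).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in written},
        "n_associations": len(assoc_rows),
        "n_pooled": len(pooled_rows),
        "failures": failures,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
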