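"""The estimation pipeline: seasons, county associations, pooling, tables.

Each county-season association is summarized as a relative risk per
inter-quartile-range (IQR) increase of the exposure metric: with the
fitted log-linear exposure coefficient ``b`` and its quasi-scaled standard
error ``se``,

    RR = exp(b * IQR),    95% CI = exp((b +/- 1.959964 * se) * IQR),

where the IQR is taken over the analysis-ready lagged exposure within the
same county-season (a region-level IQR can be supplied for cross-county
comparability). County estimates for one region/exposure/season/lag are
pooled on the log scale with the DerSimonian-Laird random-effects model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .glm import ModelSpec, build_design, fit_quasipoisson, select_df_aic
from .meta import dersimonian_laird
from .series import DailySeries

__all__ = [
    "Z_95",
    "AssociationEstimate",
    "PooledAssociation",
    "season_split",
    "aggregate_monitors",
    "estimate_association",
    "pool_counties",
    "spearman_table",
    "demographic_table",
    "summarize_demographic_counts",
    "AGE_GROUPS",
    "SEX_CATEGORIES",
    "RACE_CATEGORIES",
]

log = logging.getLogger(__name__)

Z_95 = 1.959964  # standard normal 97.5% quantile

AGE_GROUPS = ("18-40", "41-64", "65+")
SEX_CATEGORIES = ("female", "male")
RACE_CATEGORIES = (
    "white",
    "hispanic",
    "black",
    "asian_pacific_islander",
    "native_american",
    "other",
)
_CATEGORY_DICT = {"age_group": AGE_GROUPS, "sex": SEX_CATEGORIES, "race": RACE_CATEGORIES}


@dataclass(frozen=True)
class AssociationEstimate:
    """RR per IQR with 95% CI for one county/season/exposure/lag."""

    county_id: str
    season: str
    exposure: str
    lag: tuple
    rr_per_iqr: float
    ci_low: float
    ci_high: float
    iqr_used: float
    log_rr: float  # log RR per IQR
    se_log_rr: float
    dispersion: float = float("nan")
    n_used: int = 0
    adj_r2: float = float("nan")

    def __post_init__(self):
        if not self.ci_low <= self.rr_per_iqr <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class PooledAssociation:
    """Random-effects combination of county estimates within a region."""

    region: str
    season: str
    exposure: str
    lag: tuple
    k: int
    combined_rr: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    i2: float


def season_split(series: DailySeries) -> dict[str, DailySeries]:
    """Partition a series into cool (Nov-Feb) and warm (Mar-Oct) sub-series.

    Every day belongs to exactly one season; cool blocks are labelled by
    season-year (the year of their November, so Jan-Feb attach to the
    preceding year's block) in a ``season_year`` column.
    """
    df = series.frame.copy()
    month = df["date"].dt.month
    year = df["date"].dt.year
    cool = (month >= 11) | (month <= 2)
    df["season_year"] = np.where(cool & (month <= 2), year - 1, year)
    out = {}
    for name, mask in (("cool", cool), ("warm", ~cool)):
        out[name] = DailySeries(
            county_id=series.county_id,
            frame=df.loc[mask].reset_index(drop=True),
            true_rr_per_iqr=series.true_rr_per_iqr,
            true_beta_per_unit=series.true_beta_per_unit,
            meta=dict(series.meta, season=name),
        )
    return out


def aggregate_monitors(monitors: dict[str, pd.Series], min_completeness: float = 0.75) -> pd.DataFrame:
    """Combine per-monitor daily values into county-level daily series.

    ``monitors`` maps monitor id -> date-indexed daily values. Within each
    season x season-year block, monitors reporting fewer than
    ``min_completeness`` of the block's days are excluded for that block;
    remaining monitors are combined per day as both the cross-monitor mean
    (``value_mean``, the analysis default) and maximum (``value_max``).
    Blocks where every monitor fails the filter come back missing, with a
    warning.
    """
    if not monitors:
        raise ValueError("need at least one monitor")
    wide = pd.DataFrame({mid: s for mid, s in monitors.items()})
    wide.index = pd.to_datetime(wide.index)
    wide = wide.reindex(pd.date_range(wide.index.min(), wide.index.max(), freq="D")).sort_index()

    month = wide.index.month
    year = wide.index.year
    cool = (month >= 11) | (month <= 2)
    season = np.where(cool, "cool", "warm")
    season_year = np.where(cool & (month <= 2), year - 1, year)
    block = pd.Series(list(zip(season, season_year)), index=wide.index)

    mean_out = pd.Series(np.nan, index=wide.index)
    max_out = pd.Series(np.nan, index=wide.index)
    for blk, idx in block.groupby(block).groups.items():
        sub = wide.loc[idx]
        frac = sub.notna().mean(axis=0)
        keep = frac[frac >= min_completeness].index
        if len(keep) == 0:
            log.warning("all %d monitors below %.0f%% completeness in block %s",
                        wide.shape[1], 100 * min_completeness, blk)
            continue
        mean_out.loc[idx] = sub[keep].mean(axis=1)
        max_out.loc[idx] = sub[keep].max(axis=1)
    return pd.DataFrame({"value_mean": mean_out, "value_max": max_out})


def estimate_association(
    series: DailySeries,
    spec: ModelSpec,
    index_values: Optional[pd.Series] = None,
    iqr: Optional[float] = None,
) -> AssociationEstimate:
    """Fit the county-season model and express the exposure effect per IQR.

    The IQR defaults to the inter-quartile range of the analysis-ready
    lagged exposure within this county-season (rows actually used in the
    fit); pass ``iqr`` to standardize to a common (e.g. region-level) IQR.
    AIC selection of weather-spline dfs runs first when the spec asks for
    it.
    """
    if spec.needs_aic:
        spec = select_df_aic(series, spec, index_values)
    X, y, n_dropped = build_design(series, spec, index_values)
    res = fit_quasipoisson(X, y, n_dropped=n_dropped)
    beta = float(res.params["exposure"])
    se = float(res.bse["exposure"])
    if iqr is None:
        q75, q25 = np.percentile(X["exposure"], [75, 25])
        iqr = float(q75 - q25)
    if iqr <= 0:
        raise ValueError("exposure IQR is not positive; cannot standardize")
    log_rr = beta * iqr
    se_log_rr = se * iqr
    return AssociationEstimate(
        county_id=getattr(series, "county_id", ""),
        season=spec.season,
        exposure=spec.exposure,
        lag=tuple(spec.lag),
        rr_per_iqr=float(np.exp(log_rr)),
        ci_low=float(np.exp(log_rr - Z_95 * se_log_rr)),
        ci_high=float(np.exp(log_rr + Z_95 * se_log_rr)),
        iqr_used=iqr,
        log_rr=log_rr,
        se_log_rr=se_log_rr,
        dispersion=res.dispersion,
        n_used=res.n_used,
        adj_r2=res.adj_r2_observed_vs_fitted,
    )


def pool_counties(estimates: list[AssociationEstimate], region: str = "region") -> PooledAssociation:
    """DerSimonian-Laird pooling of county log-RR-per-IQR estimates."""
    if len(estimates) < 2:
        raise ValueError("pooling requires at least two county estimates")
    keys = {(e.exposure, e.season, tuple(e.lag)) for e in estimates}
    if len(keys) != 1:
        raise ValueError(f"cannot pool mixed exposure/season/lag combinations: {sorted(keys)}")
    res = dersimonian_laird([e.log_rr for e in estimates], [e.se_log_rr for e in estimates])
    exposure, season, lag = next(iter(keys))
    return PooledAssociation(
        region=region,
        season=season,
        exposure=exposure,
        lag=lag,
        k=res.k,
        combined_rr=float(np.exp(res.beta)),
        ci_low=float(np.exp(res.beta - Z_95 * res.se)),
        ci_high=float(np.exp(res.beta + Z_95 * res.se)),
        tau2=res.tau2,
        Q=res.Q,
        i2=res.i2,
    )


def spearman_table(frame: pd.DataFrame, variables: list[str], min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise Spearman rank correlations (mid-rank ties, pairwise-complete).

    Cells with fewer than ``min_pairs`` paired observations or a constant
    variable come back missing; the matrix is symmetric with unit diagonal.
    """
    missing = [v for v in variables if v not in frame.columns]
    if missing:
        raise ValueError(f"variables not in frame: {missing}")
    sub = frame[variables]
    rho = sub.corr(method="spearman", min_periods=min_pairs)
    # constant variables: pandas may emit NaN already; enforce unit diagonal
    # only where the variable is genuinely non-degenerate
    for v in variables:
        col = sub[v].dropna()
        if col.nunique() <= 1:
            rho.loc[v, :] = np.nan
            rho.loc[:, v] = np.nan
        else:
            rho.loc[v, v] = 1.0
    return rho


def demographic_table(records: pd.DataFrame, region_col: str = "region") -> pd.DataFrame:
    """Counts and within-region percentages by age group, sex and race.

    ``records`` holds one row per visit with ``age_group``, ``sex`` and
    ``race`` columns (and optionally a region column; absent, a single
    region "all" is assumed). Unknown categories are counted under
    ``other`` with a warning. Returns a tidy frame (region, variable,
    category, count, pct) which :func:`summarize_demographic_counts` turns
    into the summary percentages.
    """
    df = records.copy()
    if region_col not in df.columns:
        df[region_col] = "all"
    rows = []
    for region, grp in df.groupby(region_col, sort=False):
        for var, cats in _CATEGORY_DICT.items():
            if var not in grp.columns:
                continue
            vals = grp[var].astype(str)
            unknown = ~vals.isin(cats)
            if unknown.any():
                log.warning("%d records with unknown %s categories counted as 'other'",
                            int(unknown.sum()), var)
                vals = vals.where(~unknown, "other")
            counts = vals.value_counts()
            for cat in cats:
                rows.append({"region": region, "variable": var, "category": cat,
                             "count": int(counts.get(cat, 0))})
    table = pd.DataFrame(rows, columns=["region", "variable", "category", "count"])
    return summarize_demographic_counts(table)


def summarize_demographic_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach within-region percentages (1 decimal) to a tidy count table.

    Input columns: region, variable, category, count. Region totals are
    the per-variable sums (each variable partitions the same visits).
    """
    out = counts.copy()
    if out.empty:
        out["pct"] = []
        return out
    totals = out.groupby(["region", "variable"])["count"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pct"] = np.where(totals > 0, np.round(100.0 * out["count"] / totals, 1), 0.0)
    return out


def region_totals(table: pd.DataFrame, variable: str = "age_group") -> pd.Series:
    """Total visits per region, read off one categorical variable's counts."""
    sub = table[table["variable"] == variable]
    return sub.groupby("region")["count"].sum()


def overall_percentage(table: pd.DataFrame, variable: str, categories) -> float:
    """Share (percent, 1 decimal) of visits in the given categories across regions."""
    sub = table[table["variable"] == variable]
    total = sub["count"].sum()
    if total == 0:
        return 0.0
    hit = sub[sub["category"].isin(list(categories))]["count"].sum()
    return round(100.0 * hit / total, 1)
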