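"""Statistical calibration studies for the estimation pipeline.

These simulation studies verify, end to end, that the generator and the
quasi-Poisson estimation machinery are mutually consistent:

* **parameter recovery** — counties simulated with a known RR per IQR on
  the 4-day moving average of PM2.5; the fitted 95% CI should cover the
  injected truth for ~95% of counties and the point estimates should
  average to the truth;
* **null calibration** — with a true RR of 1.0 the nominal two-sided 5%
  test should reject ~5% of the time.

Each replicate is one independent county over three years of daily data
(the study period length), fit with the full-year model so the IQR used
for standardization coincides with the one the generator injected truth
on.
"""

from __future__ import annotations

import numpy as np

from .association import Z_95, estimate_association, overall_percentage
from .glm import ModelSpec
from .io import load_demographic_counts
from .simulate import default_config, simulate_county

__all__ = ["recovery_study", "null_calibration_study", "demographic_summary"]

_RECOVERY_SPEC = ModelSpec(
    exposure="pm25", season="all", lag=(0, 3), temp_df=3, lagtemp_df=3, rh_df=3
)


def _replicate(seed: int, true_rr: float, baseline: float, phi: float):
    cfg = default_config(
        n_counties=1,
        seed=int(seed),
        baseline_count=baseline,
        overdispersion=phi,
        true_rr_per_iqr={"pm25": true_rr, "o3": 1.0, "no2": 1.0},
    )
    series = simulate_county(cfg, 0)
    est = estimate_association(series, _RECOVERY_SPEC)
    truth_log_rr = series.true_beta_per_unit["pm25"] * est.iqr_used
    return est, truth_log_rr


def recovery_study(
    n_replicates: int = 300,
    true_rr: float = 1.03,
    baseline: float = 100.0,
    phi: float = 1.3,
    seed: int = 0,
) -> dict:
    """CI coverage and mean point estimate across simulated counties.

    Returns ``{"coverage": ..., "mean_rr": ..., "n": n_replicates}``:
    the fraction of replicates whose quasi-scaled 95% CI covers the
    injected log-RR truth, and the average RR-per-IQR point estimate.
    """
    covered = 0
    rrs = []
    for r in range(n_replicates):
        est, truth = _replicate((seed + 1) * 100_000 + r, true_rr, baseline, phi)
        lo = est.log_rr - Z_95 * est.se_log_rr
        hi = est.log_rr + Z_95 * est.se_log_rr
        covered += lo <= truth <= hi
        rrs.append(est.rr_per_iqr)
    return {
        "coverage": covered / n_replicates,
        "mean_rr": float(np.mean(rrs)),
        "n": n_replicates,
    }


def null_calibration_study(
    n_replicates: int = 500,
    baseline: float = 100.0,
    phi: float = 1.3,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the nominal two-sided 5% test at RR = 1."""
    rejected = 0
    for r in range(n_replicates):
        est, _ = _replicate((seed + 2) * 200_000 + r, 1.0, baseline, phi)
        rejected += abs(est.log_rr / est.se_log_rr) > Z_95
    return {"rejection_rate": rejected / n_replicates, "n": n_replicates}


def demographic_summary(counts=None) -> dict:
    """Region totals and headline percentages from a demographic count table.

    Defaults to the shipped published totals for the three California
    regions, 2012-2014. Everything is recomputed from the raw category
    counts (nothing is read off pre-computed percentage columns).
    """
    if counts is None:
        counts = load_demographic_counts()
    age = counts[counts["variable"] == "age_group"]
    region_totals = age.groupby("region")["count"].sum().to_dict()
    grand_total = int(age["count"].sum())
    sj = age[age["region"] == "San Joaquin Valley"]
    sj_young = int(sj[sj["category"] == "18-40"]["count"].sum())
    return {
        "region_totals": {k: int(v) for k, v in region_totals.items()},
        "grand_total": grand_total,
        "pct_age_over_40": overall_percentage(counts, "age_group", ["41-64", "65+"]),
        "pct_female": overall_percentage(counts, "sex", ["female"]),
        "pct_hispanic": overall_percentage(counts, "race", ["hispanic"]),
        "pct_black": overall_percentage(counts, "race", ["black"]),
        "pct_san_joaquin_18_40": round(100.0 * sj_young / sj["count"].sum(), 1),
    }
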