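import numpy as np
import pandas as pd
import pytest

import aqindex as aq
from aqindex.association import (
    AssociationEstimate,
    aggregate_monitors,
    demographic_table,
    overall_percentage,
    pool_counties,
    season_split,
    spearman_table,
)
from conftest import dl_hand_oracle, spearman_midrank_oracle


class TestSeasonSplit:
    def test_calendar_assignment(self, sim_series):
        parts = season_split(sim_series)
        cool_dates = parts["cool"].frame["date"]
        warm_dates = parts["warm"].frame["date"]
        assert pd.Timestamp("2013-11-15") in set(cool_dates)
        assert pd.Timestamp("2013-03-01") in set(warm_dates)
        assert cool_dates.dt.month.isin([11, 12, 1, 2]).all()
        assert warm_dates.dt.month.isin(range(3, 11)).all()

    def test_partition_is_exact(self, sim_series):
        parts = season_split(sim_series)
        merged = pd.concat([parts["cool"].frame, parts["warm"].frame])
        assert len(merged) == len(sim_series.frame)
        assert set(merged["date"]) == set(sim_series.frame["date"])

    def test_cool_blocks_span_year_boundary(self, sim_series):
        cool = season_split(sim_series)["cool"].frame
        jan_2013 = cool[cool["date"] == "2013-01-15"]
        assert (jan_2013["season_year"] == 2012).all()


class TestMonitorAggregation:
    def test_incomplete_monitor_excluded_per_season(self):
        dates = pd.date_range("2013-11-01", "2014-02-28")
        complete = pd.Series(10.0, index=dates)
        half = pd.Series(20.0, index=dates)
        half.iloc[::2] = np.nan  # 50% completeness in the cool block
        out = aggregate_monitors({"full": complete, "half": half})
        assert (out["value_mean"] == 10.0).all()

    def test_single_complete_monitor_passthrough(self):
        dates = pd.date_range("2013-03-01", "2013-10-31")
        vals = pd.Series(np.arange(len(dates), dtype=float), index=dates)
        out = aggregate_monitors({"m": vals})
        pd.testing.assert_series_equal(
            out["value_mean"], vals, check_names=False, check_freq=False
        )

    def test_mean_and_max_combination(self):
        dates = pd.date_range("2013-06-01", "2013-09-30")
        a = pd.Series(10.0, index=dates)
        b = pd.Series(20.0, index=dates)
        out = aggregate_monitors({"a": a, "b": b})
        assert (out["value_mean"] == 15.0).all()
        assert (out["value_max"] == 20.0).all()

    def test_all_monitors_excluded_yields_missing_block(self, caplog):
        dates = pd.date_range("2013-11-01", "2014-02-28")
        sparse = pd.Series(np.nan, index=dates)
        sparse.iloc[:10] = 5.0
        import logging

        with caplog.at_level(logging.WARNING, logger="aqindex.association"):
            out = aggregate_monitors({"m": sparse})
        assert out["value_mean"].isna().all()
        assert any("completeness" in r.message for r in caplog.records)


class TestEstimateAssociation:
    def test_rr_is_exp_beta_times_iqr(self, sim_series, fixed_spec):
        est = aq.estimate_association(sim_series, fixed_spec)
        assert est.rr_per_iqr == pytest.approx(np.exp(est.log_rr), rel=1e-12)
        assert est.ci_low <= est.rr_per_iqr <= est.ci_high

    def test_supplied_iqr_standardizes_the_scale(self, sim_series, fixed_spec):
        est1 = aq.estimate_association(sim_series, fixed_spec)
        est2 = aq.estimate_association(sim_series, fixed_spec, iqr=2 * est1.iqr_used)
        assert est2.log_rr == pytest.approx(2 * est1.log_rr, rel=1e-9)

    def test_exposure_rescaling_leaves_rr_unchanged(self, sim_series, fixed_spec):
        est1 = aq.estimate_association(sim_series, fixed_spec)
        scaled = aq.DailySeries(
            sim_series.county_id, sim_series.frame.assign(pm25=sim_series.frame["pm25"] * 3.7)
        )
        est2 = aq.estimate_association(scaled, fixed_spec)
        assert abs(est2.rr_per_iqr - est1.rr_per_iqr) < 1e-12
        assert abs(est2.ci_low - est1.ci_low) < 1e-12
        assert abs(est2.ci_high - est1.ci_high) < 1e-12


def make_estimate(log_rr, se, exposure="pm25", season="cool", county="c"):
    return AssociationEstimate(
        county_id=county, season=season, exposure=exposure, lag=(0, 3),
        rr_per_iqr=float(np.exp(log_rr)),
        ci_low=float(np.exp(log_rr - 1.959964 * se)),
        ci_high=float(np.exp(log_rr + 1.959964 * se)),
        iqr_used=1.0, log_rr=log_rr, se_log_rr=se,
    )


class TestPoolCounties:
    def test_two_identical_estimates_pool_to_themselves(self):
        ests = [make_estimate(0.02, 0.01, county=c) for c in "ab"]
        pooled = pool_counties(ests)
        assert pooled.combined_rr == pytest.approx(np.exp(0.02))
        assert pooled.tau2 == 0.0

    def test_symmetric_spread_centres_on_the_middle(self):
        centre = np.log(1.02)
        ests = [make_estimate(centre + d, 0.01, county=str(d)) for d in (-0.004, 0.0, 0.004)]
        pooled = pool_counties(ests)
        assert pooled.combined_rr == pytest.approx(1.02, rel=1e-10)

    def test_three_county_example_matches_hand_oracle(self):
        logs, ses = [0.030, 0.010, 0.045], [0.012, 0.015, 0.010]
        ests = [make_estimate(l, s, county=str(i)) for i, (l, s) in enumerate(zip(logs, ses))]
        pooled = pool_counties(ests)
        beta_o, se_o, tau2_o, Q_o = dl_hand_oracle(logs, ses)
        assert pooled.combined_rr == pytest.approx(np.exp(beta_o), rel=1e-12)
        assert pooled.tau2 == pytest.approx(tau2_o, rel=1e-12)
        assert pooled.Q == pytest.approx(Q_o, rel=1e-12)
        assert pooled.i2 == pytest.approx(max(0.0, (Q_o - 2) / Q_o), rel=1e-12)

    def test_pooled_se_not_larger_than_worst_county(self):
        ests = [make_estimate(l, s, county=str(i))
                for i, (l, s) in enumerate(zip([0.01, 0.08, -0.02], [0.01, 0.03, 0.02]))]
        pooled = pool_counties(ests)
        width = np.log(pooled.ci_high / pooled.combined_rr) / 1.959964
        assert width <= max(e.se_log_rr for e in ests) + 1e-12

    def test_mixed_exposures_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            pool_counties([make_estimate(0.01, 0.01), make_estimate(0.01, 0.01, exposure="o3")])


class TestSpearmanTable:
    def test_monotone_transforms(self):
        x = np.arange(30.0)
        frame = pd.DataFrame({"a": x, "b": 2 * x, "c": -x})
        rho = spearman_table(frame, ["a", "b", "c"])
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_midrank_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(12)
        x = rng.integers(0, 10, size=50).astype(float)  # heavy ties
        y = rng.integers(0, 10, size=50).astype(float)
        frame = pd.DataFrame({"x": x, "y": y})
        rho = spearman_table(frame, ["x", "y"])
        assert rho.loc["x", "y"] == pytest.approx(spearman_midrank_oracle(x, y), rel=1e-12)

    def test_constant_variable_gives_missing_cell(self):
        frame = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        rho = spearman_table(frame, ["a", "b"])
        assert np.isnan(rho.loc["a", "b"]) and np.isnan(rho.loc["b", "b"])

    def test_matrix_symmetric_unit_diagonal(self, sim_series):
        rho = spearman_table(sim_series.frame, ["pm25", "o3", "no2", "temp", "rh"])
        np.testing.assert_allclose(rho.to_numpy(), rho.to_numpy().T, atol=1e-12)
        assert np.allclose(np.diag(rho.to_numpy()), 1.0)


class TestDemographicTable:
    DEMO = {
        "age_group": {"18-40": 0.5, "41-64": 0.35, "65+": 0.15},
        "sex": {"female": 0.6, "male": 0.4},
        "race": {"white": 0.4, "hispanic": 0.35, "black": 0.15, "other": 0.10},
    }

    def test_counts_conserved_and_percentages_sum(self, sim_series):
        recs = aq.simulate_visit_records(sim_series, self.DEMO, seed=6)
        table = demographic_table(recs)
        total = sim_series.frame["count"].sum()
        for var in ("age_group", "sex", "race"):
            sub = table[table["variable"] == var]
            assert sub["count"].sum() == total
            assert sub["pct"].sum() == pytest.approx(100.0, abs=0.3)

    def test_unknown_category_counted_as_other(self):
        recs = pd.DataFrame({"age_group": ["18-40"], "sex": ["female"], "race": ["martian"]})
        table = demographic_table(recs)
        other = table[(table["variable"] == "race") & (table["category"] == "other")]
        assert other["count"].iloc[0] == 1

    def test_empty_input_gives_all_zero_table(self):
        recs = pd.DataFrame({"age_group": [], "sex": [], "race": []})
        table = demographic_table(recs)
        assert (table["count"] == 0).all() if len(table) else True

    def test_overall_percentage_aggregates_across_regions(self):
        rows = [
            {"region": "A", "variable": "sex", "category": "female", "count": 60},
            {"region": "A", "variable": "sex", "category": "male", "count": 40},
            {"region": "B", "variable": "sex", "category": "female", "count": 30},
            {"region": "B", "variable": "sex", "category": "male", "count": 70},
        ]
        assert overall_percentage(pd.DataFrame(rows), "sex", ["female"]) == 45.0
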