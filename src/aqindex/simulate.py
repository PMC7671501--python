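"""Synthetic multi-county daily series with known ground-truth effects.

The real inputs of this kind of study — restricted emergency-department
records and regulatory monitor downloads — cannot ship with a package, so
every downstream stage is exercised on simulated data that carries the
statistical structure the analysis assumes:

* pollutant series: annual sinusoidal cycle + AR(1) noise, cross-pollutant
  rank correlation induced by a Gaussian copula on the innovations,
  truncated at zero;
* weather series (temperature, relative humidity) with the same
  seasonal+AR(1) construction, RH clipped to [0, 100];
* overdispersed daily ED counts whose log-mean contains a smooth seasonal
  term, an optional linear trend, day-of-week factors, linear weather
  terms, and a log-linear exposure term on the 4-day moving average of
  each pollutant, with configurable true RR per realized IQR.

The exposure coefficient injected for pollutant p is
``beta_p = log(true_rr_per_iqr[p]) / IQR_p`` where ``IQR_p`` is the
realized inter-quartile range of p's lagged exposure over the simulated
period, so "true RR per IQR" is exact by construction.  The linear
predictor is centred so that the mean of the daily expected counts equals
``baseline_count`` exactly.  Overdispersion uses a gamma-mixed Poisson
(negative binomial with variance = overdispersion x mean);
``overdispersion = 1`` draws pure Poisson counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .series import POLLUTANTS, DailySeries

__all__ = [
    "SeasonalAR1",
    "SimulationConfig",
    "default_config",
    "simulate_county",
    "simulate_region",
    "simulate_visit_records",
]

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class SeasonalAR1:
    """Seasonal-sinusoid-plus-AR(1) settings for one daily variable.

    ``noise_sd`` is the *stationary* standard deviation of the AR(1)
    component; ``peak_day_of_year`` (1-366) locates the seasonal maximum.
    """

    annual_mean: float
    seasonal_amplitude: float = 0.0
    peak_day_of_year: int = 1
    ar1_rho: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.noise_sd < 0 or self.seasonal_amplitude < 0:
            raise ValueError("amplitudes and noise sd must be non-negative")
        if not 1 <= self.peak_day_of_year <= 366:
            raise ValueError("peak_day_of_year must lie in 1..366")


@dataclass
class SimulationConfig:
    """Full specification of a simulated multi-county study."""

    n_counties: int = 3
    start_date: str = "2012-01-01"
    end_date: str = "2014-12-31"
    pollutant_params: dict[str, SeasonalAR1] = field(default_factory=dict)
    cross_corr: np.ndarray | None = None  # target Spearman among pollutants
    weather_params: dict[str, SeasonalAR1] = field(default_factory=dict)
    baseline_count: float = 100.0
    dow_effects: tuple = (1.10, 1.00, 0.97, 0.96, 0.97, 0.98, 1.02)  # Mon..Sun
    true_rr_per_iqr: dict[str, float] = field(default_factory=dict)
    overdispersion: float = 1.3
    # log-scale seasonality/trend and linear weather terms of the count mean
    count_seasonal_amplitude: float = 0.2
    count_peak_day: int = 15
    count_trend_per_year: float = 0.0
    temp_beta: float = -0.003
    rh_beta: float = 0.001
    exposure_lag: tuple = (0, 3)  # moving-average window the truth acts on
    seed: int = 0

    def __post_init__(self):
        if self.n_counties < 1:
            raise ValueError("n_counties must be positive")
        if pd.Timestamp(self.end_date) < pd.Timestamp(self.start_date):
            raise ValueError(f"end_date {self.end_date} precedes start_date {self.start_date}")
        if self.overdispersion < 1:
            raise ValueError("overdispersion must be >= 1")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Mon..Sun)")
        if any(f <= 0 for f in self.dow_effects):
            raise ValueError("dow_effects must be positive multiplicative factors")
        for rr in self.true_rr_per_iqr.values():
            if not rr > 0:
                raise ValueError("true_rr_per_iqr entries must be > 0")
        if self.cross_corr is not None:
            c = np.asarray(self.cross_corr, dtype=float)
            p = len(self.pollutant_params)
            if c.shape != (p, p):
                raise ValueError(f"cross_corr must be {p}x{p} for {p} pollutants")
            if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise ValueError("cross_corr must be symmetric with unit diagonal")
            _copula_cholesky(c)  # raises if not positive semi-definite


def default_config(**overrides) -> SimulationConfig:
    """Study-like defaults: 2012-2014 daily series for three pollutants.

    Magnitudes are set so medians/IQRs and cross-pollutant rank
    correlations land in the ranges typical of the California regions the
    analysis emulates (winter-peaking PM2.5 and NO2, summer-peaking O3).
    """
    cfg = SimulationConfig(
        pollutant_params={
            "pm25": SeasonalAR1(11.0, 5.0, 15, 0.6, 4.0),
            "o3": SeasonalAR1(45.0, 14.0, 196, 0.5, 8.0),
            "no2": SeasonalAR1(25.0, 8.0, 15, 0.6, 6.0),
        },
        cross_corr=np.array([[1.0, 0.25, 0.35], [0.25, 1.0, 0.1], [0.35, 0.1, 1.0]]),
        weather_params={
            "temp": SeasonalAR1(60.0, 15.0, 196, 0.7, 3.0),
            "rh": SeasonalAR1(60.0, 10.0, 15, 0.6, 8.0),
        },
        true_rr_per_iqr={"pm25": 1.03, "o3": 1.0, "no2": 1.0},
    )
    return replace(cfg, **overrides) if overrides else cfg


def _copula_cholesky(spearman: np.ndarray) -> np.ndarray:
    """Cholesky factor of the Pearson matrix matching target Spearman corr.

    Gaussian-copula conversion r = 2 sin(pi * rho_s / 6); a non-PSD target
    is rejected with a diagnostic.
    """
    pearson = 2.0 * np.sin(np.pi * np.asarray(spearman, float) / 6.0)
    np.fill_diagonal(pearson, 1.0)
    try:
        return np.linalg.cholesky(pearson)
    except np.linalg.LinAlgError:
        eig = np.linalg.eigvalsh(pearson)
        raise ValueError(
            "cross_corr is not positive semi-definite after copula conversion; "
            f"eigenvalues of the implied Pearson matrix: {np.round(eig, 6)}"
        ) from None


def _seasonal_ar1(params: SeasonalAR1, doy: np.ndarray, innov: np.ndarray) -> np.ndarray:
    phase = 2.0 * np.pi * (doy - params.peak_day_of_year) / _DAYS_PER_YEAR
    seasonal = params.annual_mean + params.seasonal_amplitude * np.cos(phase)
    e = np.empty_like(innov)
    scale = params.noise_sd * np.sqrt(1.0 - params.ar1_rho**2)
    prev = params.noise_sd * innov[0]  # start at stationary scale
    e[0] = prev
    for t in range(1, len(innov)):
        prev = params.ar1_rho * prev + scale * innov[t]
        e[t] = prev
    return seasonal + e


def _moving_average(x: np.ndarray, lag_min: int, lag_max: int) -> np.ndarray:
    s = pd.Series(x).shift(lag_min).rolling(lag_max - lag_min + 1).mean()
    return s.to_numpy()


def simulate_county(config: SimulationConfig, county_index: int) -> DailySeries:
    """Simulate one county's complete daily series.

    Deterministic given ``(config.seed, county_index)``; counties use
    independent random substreams.  Pollutants and weather are simulated
    with a burn-in long enough that every output day has a fully defined
    lagged exposure and lag-1..3 temperature.
    """
    if county_index >= config.n_counties:
        raise ValueError(f"county_index {county_index} >= n_counties {config.n_counties}")
    rng = np.random.default_rng([int(config.seed), int(county_index)])
    lag_min, lag_max = config.exposure_lag
    burn = max(int(lag_max), 3)
    start = pd.Timestamp(config.start_date)
    dates_ext = pd.date_range(start - pd.Timedelta(days=burn), config.end_date, freq="D")
    n_ext = len(dates_ext)
    doy = dates_ext.dayofyear.to_numpy()

    pols = list(config.pollutant_params)
    if pols:
        if config.cross_corr is not None:
            L = _copula_cholesky(np.asarray(config.cross_corr, float))
        else:
            L = np.eye(len(pols))
        z = rng.standard_normal((n_ext, len(pols))) @ L.T
    conc = {}
    for j, pol in enumerate(pols):
        conc[pol] = np.clip(_seasonal_ar1(config.pollutant_params[pol], doy, z[:, j]), 0.0, None)

    weather = {}
    for var in ("temp", "rh"):
        params = config.weather_params.get(var, SeasonalAR1(60.0))
        w = _seasonal_ar1(params, doy, rng.standard_normal(n_ext))
        if var == "rh":
            w = np.clip(w, 0.0, 100.0)
        weather[var] = w

    out = slice(burn, n_ext)
    n_out = n_ext - burn
    dates = dates_ext[out]

    # exposure truth acts on the lagged (moving-average) concentrations
    eta = np.zeros(n_out)
    true_beta = {}
    true_rr = {}
    for pol in pols:
        ma = _moving_average(conc[pol], lag_min, lag_max)[out]
        rr = float(config.true_rr_per_iqr.get(pol, 1.0))
        q75, q25 = np.percentile(ma, [75, 25])
        iqr = q75 - q25
        beta = np.log(rr) / iqr if iqr > 0 else 0.0
        eta += beta * ma
        true_beta[pol] = beta
        true_rr[pol] = rr

    phase = 2.0 * np.pi * (dates.dayofyear.to_numpy() - config.count_peak_day) / _DAYS_PER_YEAR
    eta += config.count_seasonal_amplitude * np.cos(phase)
    years = (dates - start).days.to_numpy() / _DAYS_PER_YEAR
    eta += config.count_trend_per_year * years
    eta += config.temp_beta * weather["temp"][out] + config.rh_beta * weather["rh"][out]
    eta += np.log(np.asarray(config.dow_effects))[dates.dayofweek.to_numpy()]

    # centre so the average expected count equals baseline_count exactly
    mu = np.exp(eta)
    mu *= config.baseline_count / mu.mean()

    phi = float(config.overdispersion)
    if phi == 1.0:
        counts = rng.poisson(mu)
    else:
        counts = rng.negative_binomial(mu / (phi - 1.0), 1.0 / phi)

    frame = pd.DataFrame(
        {
            "date": dates,
            **{pol: conc[pol][out] for pol in pols},
            "temp": weather["temp"][out],
            "rh": weather["rh"][out],
            "count": counts,
        }
    )
    return DailySeries(
        county_id=f"county_{county_index:03d}",
        frame=frame,
        true_rr_per_iqr=true_rr,
        true_beta_per_unit=true_beta,
        meta={"seed": config.seed, "county_index": county_index,
              "overdispersion": phi, "exposure_lag": tuple(config.exposure_lag)},
    )


def simulate_region(config: SimulationConfig) -> list[DailySeries]:
    """One independent series per county, with distinct county ids."""
    return [simulate_county(config, i) for i in range(config.n_counties)]


def simulate_visit_records(series: DailySeries, demographics: dict, seed: int = 0) -> pd.DataFrame:
    """Expand daily counts into visit-level records with categorical attributes.

    ``demographics`` maps each variable (``age_group``, ``sex``, ``race``)
    to a category->probability dict; each probability table must sum to 1
    (tolerance 1e-9). Attributes are drawn independently per visit, so
    marginal frequencies converge to the tables. The number of records
    equals the sum of daily counts exactly.
    """
    for var, table in demographics.items():
        total = sum(table.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities for {var!r} sum to {total!r}, expected 1")
    counts = series.frame["count"].fillna(0).astype(int).to_numpy()
    dates = np.repeat(series.frame["date"].to_numpy(), counts)
    n = int(counts.sum())
    rng = np.random.default_rng([int(seed), 982451653])
    cols = {"date": dates}
    for var, table in demographics.items():
        cats = np.array(list(table.keys()), dtype=object)
        probs = np.array(list(table.values()), dtype=float)
        probs = probs / probs.sum()  # remove rounding residue within tolerance
        cols[var] = cats[rng.choice(len(cats), size=n, p=probs)] if n else np.array([], object)
    return pd.DataFrame(cols)
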