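"""Quasi-Poisson time-series regression for daily counts.

The analysis model is a log-link Poisson GLM for daily ED counts with
natural-spline adjustment for long-term trend/seasonality (df per season
per year), same-day temperature, the mean of temperature at lags 1-3, and
relative humidity, plus parametric day-of-week terms and a single lagged
exposure term.  Quasi-likelihood handles overdispersion: point estimates
are the ordinary Poisson MLEs, and the covariance is inflated by the
Pearson dispersion ``phi = X^2 / (n - p)``.

``QuasiPoissonRegressor`` is a scikit-learn style estimator (fit/predict,
``coef_``, ``cov_params_``, ``dispersion_``) solving the score equations
by iteratively reweighted least squares; design construction, AIC-guided
degrees-of-freedom selection and the observed-vs-fitted adjusted R^2
diagnostic live alongside it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr
from scipy.special import gammaln
from sklearn.base import BaseEstimator, RegressorMixin

from .series import POLLUTANTS, DailySeries
from .splines import natural_spline_basis

__all__ = [
    "ModelSpec",
    "FitResult",
    "QuasiPoissonRegressor",
    "ConvergenceError",
    "natural_spline_basis",
    "moving_average_exposure",
    "build_design",
    "fit_quasipoisson",
    "select_df_aic",
    "adjusted_r2_observed_fitted",
]

log = logging.getLogger(__name__)

INDEX_EXPOSURES = ("aqi", "hbi")
AIC_GRID_DEFAULT = (2, 3, 4, 5)


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one county-season analysis model.

    ``lag`` is a ``(lag_min, lag_max)`` moving-average window; the primary
    metric is the 4-day moving average ``(0, 3)`` and single-day lags d in
    0..5 are the degenerate window ``(d, d)``. ``trend_df_per_season_year``
    defaults to 8 for the cool season (Nov-Feb), 16 for the warm season
    (Mar-Oct) and 12 for full-year fits. Weather spline dfs may be
    integers or ``"aic"`` to select from ``aic_grid`` by AIC.
    """

    exposure: str = "pm25"
    season: str = "cool"  # cool | warm | all
    lag: tuple = (0, 3)
    trend_df_per_season_year: Optional[int] = None
    temp_df: object = "aic"
    lagtemp_df: object = "aic"
    rh_df: object = "aic"
    dow_coding: str = "indicators"  # indicators | linear
    aic_grid: tuple = AIC_GRID_DEFAULT

    def __post_init__(self):
        if self.season not in ("cool", "warm", "all"):
            raise ValueError(f"season must be cool, warm or all, got {self.season!r}")
        lo, hi = self.lag
        if lo < 0 or hi < lo:
            raise ValueError(f"lag window must satisfy 0 <= lag_min <= lag_max, got {self.lag}")
        if self.dow_coding not in ("indicators", "linear"):
            raise ValueError("dow_coding must be 'indicators' or 'linear'")
        for name in ("temp_df", "lagtemp_df", "rh_df"):
            v = getattr(self, name)
            if v != "aic" and (not isinstance(v, (int, np.integer)) or v < 1):
                raise ValueError(f"{name} must be a positive integer or 'aic'")
        if self.trend_df_per_season_year is not None and self.trend_df_per_season_year < 1:
            raise ValueError("trend_df_per_season_year must be >= 1")

    @property
    def resolved_trend_df(self) -> int:
        if self.trend_df_per_season_year is not None:
            return int(self.trend_df_per_season_year)
        return {"cool": 8, "warm": 16, "all": 12}[self.season]

    @property
    def needs_aic(self) -> bool:
        return "aic" in (self.temp_df, self.lagtemp_df, self.rh_df)


class ConvergenceError(RuntimeError):
    pass


@dataclass
class FitResult:
    """A fitted quasi-Poisson model: estimates, scaled covariance, diagnostics."""

    params: pd.Series
    cov_params: pd.DataFrame
    dispersion: float
    n_used: int
    deviance: float
    quasi_aic: float
    fitted_values: pd.Series
    adj_r2_observed_vs_fitted: float
    n_dropped: int = 0
    n_iter: int = 0

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    def summary_frame(self) -> pd.DataFrame:
        se = self.bse
        return pd.DataFrame({"estimate": self.params, "se": se, "z": self.params / se})


def moving_average_exposure(series, lag_min: int, lag_max: int) -> pd.Series:
    """Trailing moving average: element t is mean(series[t-lag_max .. t-lag_min]).

    The first ``lag_max`` elements are missing, and any missing input day
    inside the window propagates to the output.
    """
    if lag_min < 0 or lag_max < lag_min:
        raise ValueError("need 0 <= lag_min <= lag_max")
    s = pd.Series(np.asarray(series, dtype=float))
    out = s.shift(lag_min).rolling(lag_max - lag_min + 1).mean()
    out.index = series.index if isinstance(series, pd.Series) else out.index
    return out


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(mu), 0.0)
    return float(np.sum(term - mu - gammaln(y + 1.0)))


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(ylogy - (y - mu)))


def adjusted_r2_observed_fitted(counts, fitted, p: int) -> float:
    """Adjusted R^2 of the least-squares regression of observed on fitted.

    ``p`` is the number of model parameters used in the adjustment. Returns
    NaN when the fitted values have zero variance.
    """
    y = np.asarray(counts, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if len(y) != len(f):
        raise ValueError("counts and fitted must have equal length")
    n = len(y)
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    if np.var(f) == 0:
        return float("nan")
    r = np.corrcoef(y, f)[0, 1]
    r2 = r * r
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


class QuasiPoissonRegressor(BaseEstimator, RegressorMixin):
    """Log-link Poisson regression with quasi-likelihood dispersion.

    Fitted by iteratively reweighted least squares, initialized at
    ``log(mean(y))`` for a constant linear predictor with all slopes zero,
    iterating to a relative deviance change below ``tol`` (default 1e-9,
    max ``max_iter`` iterations). Point estimates equal the unscaled
    Poisson MLE; ``cov_params_`` is the inverse Fisher information scaled
    by the Pearson dispersion, so quasi standard errors are exactly the
    Poisson ones times ``sqrt(dispersion_)``.

    Attributes (post-fit): ``coef_``, ``cov_params_``, ``bse_``,
    ``dispersion_``, ``deviance_``, ``aic_``, ``fitted_values_``,
    ``n_iter_``, ``feature_names_in_``.
    """

    def __init__(self, tol: float = 1e-9, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else [
            f"x{j}" for j in range(np.asarray(X).shape[1])
        ]
        X_ = np.asarray(X, dtype=float)
        y_ = np.asarray(y, dtype=float)
        if X_.ndim != 2 or len(y_) != X_.shape[0]:
            raise ValueError("X must be 2-D with one row per element of y")
        if np.any(y_ < 0) or not np.allclose(y_, np.round(y_)):
            raise ValueError("counts must be non-negative integers")
        n, p = X_.shape
        if n < p:
            raise ValueError(f"fewer rows ({n}) than columns ({p})")
        self._check_rank(X_, names)

        ybar = max(y_.mean(), 1e-12)
        eta = np.full(n, np.log(ybar))
        mu = np.exp(eta)
        dev = _poisson_deviance(y_, mu)
        trace = [dev]
        beta = None
        polish = 0  # extra Newton steps after the tolerance is met
        for it in range(1, self.max_iter + 1):
            w = mu
            z = eta + (y_ - mu) / mu
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(X_ * sw[:, None], z * sw, rcond=None)
            eta = X_ @ beta
            eta = np.clip(eta, -30, 30)
            mu = np.exp(eta)
            dev_new = _poisson_deviance(y_, mu)
            trace.append(dev_new)
            if abs(dev_new - dev) / (abs(dev_new) + 0.1) < self.tol:
                dev = dev_new
                # IRLS is Newton-like: one refinement step past the stopping
                # rule pushes the estimate to machine-precision MLE
                if polish >= 1:
                    break
                polish += 1
                continue
            dev = dev_new
        else:
            raise ConvergenceError(
                f"IRLS did not converge in {self.max_iter} iterations; deviance trace: "
                f"{np.array2string(np.asarray(trace), precision=6)}"
            )

        pearson = float(np.sum((y_ - mu) ** 2 / mu))
        phi = pearson / (n - p) if n > p else float("nan")
        # covariance via QR of the weighted design: inverting X'WX directly
        # squares the condition number of spline-heavy designs
        _, R = np.linalg.qr(X_ * np.sqrt(mu)[:, None])
        Rinv = np.linalg.solve(R, np.eye(p))
        cov_unscaled = Rinv @ Rinv.T
        self.coef_ = beta
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = p
        self.cov_params_ = pd.DataFrame(phi * cov_unscaled, index=names, columns=names)
        self.bse_ = pd.Series(np.sqrt(np.diag(self.cov_params_)), index=names)
        self.dispersion_ = phi
        self.deviance_ = dev
        self.loglik_ = _poisson_loglik(y_, mu)
        self.aic_ = 2.0 * p - 2.0 * self.loglik_
        self.fitted_values_ = pd.Series(mu, index=(y.index if isinstance(y, pd.Series) else None))
        self.n_iter_ = it
        self.n_used_ = n
        return self

    @staticmethod
    def _check_rank(X: np.ndarray, names) -> None:
        _, R, piv = _qr(X, mode="economic", pivoting=True)
        d = np.abs(np.diag(R))
        tol = d[0] * max(X.shape) * np.finfo(float).eps if d.size else 0.0
        rank = int(np.sum(d > tol))
        if rank < X.shape[1]:
            bad = [names[j] for j in piv[rank:]]
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    def predict(self, X) -> np.ndarray:
        return np.exp(np.asarray(X, dtype=float) @ self.coef_)

    def to_result(self, y, n_dropped: int = 0) -> FitResult:
        y_ = np.asarray(y, dtype=float)
        params = pd.Series(self.coef_, index=self.feature_names_in_)
        return FitResult(
            params=params,
            cov_params=self.cov_params_,
            dispersion=self.dispersion_,
            n_used=self.n_used_,
            deviance=self.deviance_,
            quasi_aic=self.aic_,
            fitted_values=self.fitted_values_,
            adj_r2_observed_vs_fitted=adjusted_r2_observed_fitted(
                y_, self.fitted_values_.to_numpy(), len(params)
            ),
            n_dropped=n_dropped,
            n_iter=self.n_iter_,
        )


def fit_quasipoisson(design: pd.DataFrame, counts, tol: float = 1e-9,
                     max_iter: int = 100, n_dropped: int = 0) -> FitResult:
    """Fit the quasi-Poisson GLM of ``counts`` on ``design`` (thin wrapper)."""
    est = QuasiPoissonRegressor(tol=tol, max_iter=max_iter).fit(design, counts)
    return est.to_result(counts, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# design construction


def _orthonormal(basis: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(basis)
    return q


def _season_labels(dates: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """(season, season_year) per day: cool = Nov-Feb labelled by November's year."""
    month = dates.dt.month.to_numpy()
    year = dates.dt.year.to_numpy()
    cool = (month >= 11) | (month <= 2)
    season = np.where(cool, "cool", "warm")
    season_year = np.where(cool & (month <= 2), year - 1, year)
    return season, season_year


def build_design(series, spec: ModelSpec, index_values: Optional[pd.Series] = None):
    """Assemble the season-restricted design matrix and response.

    ``series`` is the *full* county series (a :class:`DailySeries` or its
    frame): lagged exposures and lag-1..3 temperature are computed on the
    complete calendar before the season subset is taken, so early-season
    days keep valid lags. Internally the series is re-indexed to a gap-free
    daily calendar (gap days become missing and are dropped later).

    Returns ``(X, y, n_dropped)`` where ``X`` has columns: const, exposure,
    day-of-week terms, and natural-spline bases for the sequential
    within-season day index (df = trend df per season-year x number of
    season-years), same-day temperature, mean temperature of lags 1-3 and
    same-day relative humidity. Rows with any missing value are dropped
    and counted in ``n_dropped``.
    """
    df = series.frame.copy() if isinstance(series, DailySeries) else series.copy()
    df["date"] = pd.to_datetime(df["date"])
    full = pd.DataFrame({"date": pd.date_range(df["date"].min(), df["date"].max(), freq="D")})
    df = full.merge(df, on="date", how="left")

    if spec.exposure in INDEX_EXPOSURES:
        if index_values is None:
            raise ValueError(f"exposure {spec.exposure!r} requires index_values")
        iv = index_values
        if isinstance(iv, pd.DataFrame):
            iv = iv.set_index("date")["value"]
        if isinstance(iv.index, pd.DatetimeIndex):
            raw = df["date"].map(iv)
        else:
            raw = pd.Series(np.asarray(iv, dtype=float))
            if len(raw) != len(df):
                raise ValueError("index_values length does not match the daily calendar")
    elif spec.exposure in df.columns:
        raw = df[spec.exposure]
    else:
        raise ValueError(f"unknown exposure {spec.exposure!r}")

    lag_min, lag_max = spec.lag
    df["_exposure"] = moving_average_exposure(raw.reset_index(drop=True), lag_min, lag_max).to_numpy()
    df["_lagtemp"] = moving_average_exposure(df["temp"].reset_index(drop=True), 1, 3).to_numpy()

    season, season_year = _season_labels(df["date"])
    if spec.season == "all":
        mask = np.ones(len(df), dtype=bool)
        blocks = df["date"].dt.year.to_numpy()
    else:
        mask = season == spec.season
        blocks = season_year
    sub = df.loc[mask].reset_index(drop=True)
    blocks = blocks[mask]

    needed = ["_exposure", "temp", "_lagtemp", "rh", "count"]
    complete = sub[needed].notna().all(axis=1).to_numpy()
    n_dropped = int((~complete).sum())
    sub = sub.loc[complete].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no complete rows for season {spec.season!r}")
    n_season_years = len(np.unique(blocks))

    cols: dict[str, np.ndarray] = {"const": np.ones(len(sub))}
    cols["exposure"] = sub["_exposure"].to_numpy()

    dow = sub["date"].dt.dayofweek.to_numpy()
    if spec.dow_coding == "indicators":
        labels = ["Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]  # Monday is reference
        for d, lab in enumerate(labels, start=1):
            cols[f"dow_{lab}"] = (dow == d).astype(float)
    else:
        cols["dow"] = dow.astype(float)

    trend_df = spec.resolved_trend_df * n_season_years
    t = np.arange(len(sub), dtype=float)
    # spline blocks are orthonormalized (QR) for numerical conditioning;
    # the spanned adjustment space, and hence the exposure estimate, is
    # unchanged
    for j, col in enumerate(
        _orthonormal(natural_spline_basis(t, trend_df, name="trend")).T, start=1
    ):
        cols[f"trend_s{j}"] = col
    for var, src, df_spec in (
        ("temp", "temp", spec.temp_df),
        ("lagtemp", "_lagtemp", spec.lagtemp_df),
        ("rh", "rh", spec.rh_df),
    ):
        if df_spec == "aic":
            raise ValueError(
                f"{var} df is 'aic'; resolve the spec with select_df_aic before build_design"
            )
        basis = natural_spline_basis(sub[src].to_numpy(), int(df_spec), name=var)
        for j, col in enumerate(_orthonormal(basis).T, start=1):
            cols[f"{var}_s{j}"] = col

    X = pd.DataFrame(cols)
    if len(X) < X.shape[1]:
        raise ValueError(f"fewer rows ({len(X)}) than design columns ({X.shape[1]})")
    y = sub["count"].astype(float)
    return X, y, n_dropped


def select_df_aic(series, spec: ModelSpec, index_values: Optional[pd.Series] = None,
                  criterion: str = "aic") -> ModelSpec:
    """Resolve any ``"aic"`` weather-spline dfs by AIC over the candidate grid.

    AIC is ``2p - 2*loglik`` with the Poisson log-likelihood evaluated at
    the quasi-Poisson point estimates; ties break toward the smaller total
    df. A joint grid search is run over exactly the terms marked ``"aic"``.
    ``criterion="qaic"`` divides the log-likelihood by the estimated
    dispersion (``2p - 2*loglik/phi``) instead.
    """
    if criterion not in ("aic", "qaic"):
        raise ValueError("criterion must be 'aic' or 'qaic'")
    free = [n for n in ("temp_df", "lagtemp_df", "rh_df") if getattr(spec, n) == "aic"]
    if not free:
        return spec
    grid = spec.aic_grid if spec.aic_grid else AIC_GRID_DEFAULT
    best = None
    failures = []
    for combo in itertools.product(grid, repeat=len(free)):
        cand = replace(spec, **dict(zip(free, combo)))
        try:
            X, y, nd = build_design(series, cand, index_values)
            res = fit_quasipoisson(X, y, n_dropped=nd)
        except (ValueError, ConvergenceError) as exc:
            failures.append((combo, str(exc)))
            continue
        p = len(res.params)
        value = res.quasi_aic if criterion == "aic" else (
            2.0 * p - (2.0 * p - res.quasi_aic) / res.dispersion
        )
        key = (value, sum(combo))
        if best is None or key < best[0]:
            best = (key, cand)
    if best is None:
        raise RuntimeError(f"every AIC candidate failed to fit: {failures}")
    return best[1]
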