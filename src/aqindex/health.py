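"""Multi-pollutant health-based air-quality index (AQHI-style).

Where the AQI reports the single worst pollutant relative to its
regulatory standard, a health-based index sums the *excess relative risk*
contributed by each pollutant, with log-linear risk coefficients pooled
from epidemiological studies by random-effects meta-analysis:

    index(x) = s * sum_p 100 * (exp(beta_p * x_p) - 1)

where ``beta_p`` is the pooled log-RR per concentration unit for pollutant
``p``, ``x_p`` the day's concentration, and ``s`` an optional positive
scaling constant.  The scale is analysis-neutral: associations per IQR are
invariant to ``s``, so the default is the raw excess-risk sum (s = 1);
``calibrate_scaling`` maps a reference quantile onto a banded scale (e.g.
the Canadian 10-point band) for presentation.

Coefficients are an input file, never hard-coded. The shipped example file
(``health_coefficients_synthetic.csv``) contains synthetic study-level
estimates with plausible magnitudes for illustration and testing only.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .meta import DLResult, dersimonian_laird

__all__ = [
    "StudyEstimate",
    "PooledCoefficient",
    "CoefficientSet",
    "pool_random_effects",
    "health_index_value",
    "health_index_series",
    "calibrate_scaling",
    "HealthIndexTransformer",
    "EXPECTED_UNITS",
]

log = logging.getLogger(__name__)

# concentration units each pollutant's coefficient must be expressed in,
# matching the daily series columns
EXPECTED_UNITS = {"pm25": "ug/m3", "o3": "ppb", "no2": "ppb"}


@dataclass(frozen=True)
class StudyEstimate:
    """One study-level log-RR estimate for a single pollutant."""

    pollutant: str
    beta: float  # log-RR per concentration unit
    se: float
    study_id: str = ""

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError(f"standard error must be > 0, got {self.se}")


@dataclass(frozen=True)
class PooledCoefficient:
    pollutant: str
    beta: float
    se: float
    tau2: float
    k: int


@dataclass
class CoefficientSet:
    """Pooled per-pollutant coefficients plus the index scaling constant."""

    coefficients: dict[str, PooledCoefficient]
    scaling_constant: float = 1.0

    def __post_init__(self):
        if not self.scaling_constant > 0:
            raise ValueError("scaling_constant must be positive")

    @property
    def pollutants(self) -> list[str]:
        return list(self.coefficients)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"pollutant": c.pollutant, "beta": c.beta, "se": c.se, "tau2": c.tau2, "k": c.k}
                for c in self.coefficients.values()
            ]
        )


def pool_random_effects(estimates: list[StudyEstimate]) -> PooledCoefficient:
    """DerSimonian-Laird pooling of study estimates for one pollutant."""
    if not estimates:
        raise ValueError("cannot pool an empty list of study estimates")
    pollutants = {e.pollutant for e in estimates}
    if len(pollutants) != 1:
        raise ValueError(f"estimates mix pollutants: {sorted(pollutants)}")
    res: DLResult = dersimonian_laird([e.beta for e in estimates], [e.se for e in estimates])
    return PooledCoefficient(estimates[0].pollutant, res.beta, res.se, res.tau2, res.k)


def pool_study_table(studies: pd.DataFrame) -> CoefficientSet:
    """Pool a study table (pollutant, study_id, beta, se) per pollutant."""
    coeffs = {}
    for pol, grp in studies.groupby("pollutant", sort=False):
        ests = [
            StudyEstimate(str(pol), float(r.beta), float(r.se), str(getattr(r, "study_id", "")))
            for r in grp.itertuples()
        ]
        coeffs[str(pol)] = pool_random_effects(ests)
    return CoefficientSet(coeffs)


def _excess_risk(conc: np.ndarray, beta: float) -> np.ndarray:
    return 100.0 * (np.exp(beta * conc) - 1.0)


def health_index_value(record, coeffs: CoefficientSet) -> float:
    """Health-based index for one day's record.

    Requires every pollutant in the coefficient set; any missing
    concentration yields a missing (NaN) index value.
    """
    total = 0.0
    for pol, c in coeffs.coefficients.items():
        try:
            x = record[pol]
        except (KeyError, IndexError):
            return float("nan")
        if x is None or (isinstance(x, float) and np.isnan(x)):
            return float("nan")
        total += _excess_risk(np.float64(x), c.beta)
    return float(coeffs.scaling_constant * total)


def health_index_series(frame: pd.DataFrame, coeffs: CoefficientSet) -> pd.Series:
    """Vectorized health-based index over a series frame.

    Days with any missing pollutant get NaN.
    """
    missing_cols = [p for p in coeffs.pollutants if p not in frame.columns]
    if missing_cols:
        raise ValueError(f"frame lacks pollutant columns {missing_cols}")
    total = np.zeros(len(frame))
    for pol, c in coeffs.coefficients.items():
        total = total + _excess_risk(frame[pol].to_numpy(dtype=float), c.beta)
    return pd.Series(coeffs.scaling_constant * total, index=frame.index, name="hbi")


def calibrate_scaling(raw_values, target_max: float, reference_quantile: float = 0.99) -> float:
    """Scaling constant mapping a reference quantile of raw values to ``target_max``.

    Used to present the raw excess-risk sum on a banded scale (e.g. 0-10).
    """
    raw = np.asarray(raw_values, dtype=float)
    raw = raw[~np.isnan(raw)]
    if raw.size == 0:
        raise ValueError("no non-missing raw index values to calibrate on")
    ref = np.quantile(raw, reference_quantile)
    if ref <= 0:
        raise ValueError("reference quantile of raw index values is not positive")
    return float(target_max / ref)


def load_example_coefficients() -> pd.DataFrame:
    """The shipped *synthetic* study-level coefficient table (illustrative only)."""
    ref = importlib.resources.files("aqindex.data") / "health_coefficients_synthetic.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


class HealthIndexTransformer(BaseEstimator, TransformerMixin):
    """Transformer computing the additive excess-risk index from pollutant columns.

    ``fit`` optionally calibrates the scaling constant so that
    ``reference_quantile`` of the training-data index equals ``target_max``;
    with ``target_max=None`` (default) the raw excess-risk sum is used.
    """

    def __init__(self, coefficients: CoefficientSet | None = None,
                 target_max: float | None = None, reference_quantile: float = 0.99):
        self.coefficients = coefficients
        self.target_max = target_max
        self.reference_quantile = reference_quantile

    def fit(self, X, y=None):
        if self.coefficients is None:
            raise ValueError("a CoefficientSet is required")
        coeffs = self.coefficients
        if self.target_max is not None:
            raw = health_index_series(X, CoefficientSet(coeffs.coefficients, 1.0))
            s = calibrate_scaling(raw, self.target_max, self.reference_quantile)
            coeffs = CoefficientSet(coeffs.coefficients, s)
        self.coefficients_ = coeffs
        self.scaling_constant_ = coeffs.scaling_constant
        return self

    def transform(self, X) -> np.ndarray:
        return health_index_series(X, self.coefficients_).to_numpy().reshape(-1, 1)

    def get_feature_names_out(self, input_features=None):
        return np.array(["hbi"])
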