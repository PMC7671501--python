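"""DerSimonian-Laird random-effects pooling.

One routine shared by the two places the analysis pools estimates:
study-level log-RR coefficients for the health-based index, and
county-level log-RR-per-IQR associations within a region.

Given k estimates beta_i with standard errors se_i, the method-of-moments
between-unit variance is

    tau^2 = max(0, (Q - (k-1)) / (sum w_i - sum w_i^2 / sum w_i)),

with fixed-effect weights w_i = 1/se_i^2 and Cochran's
Q = sum w_i (beta_i - beta_FE)^2.  Random-effects weights are
w*_i = 1/(se_i^2 + tau^2); the pooled estimate is the w*-weighted mean with
standard error 1/sqrt(sum w*_i).  When Q <= k-1 the estimate reduces
exactly to fixed-effect inverse-variance pooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["DLResult", "dersimonian_laird"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DLResult:
    """Pooled estimate from a DerSimonian-Laird random-effects model."""

    beta: float
    se: float
    tau2: float
    Q: float
    k: int

    @property
    def i2(self) -> float:
        """Higgins' I^2 heterogeneity fraction, max(0, (Q-(k-1))/Q)."""
        if self.Q <= 0:
            return 0.0
        return max(0.0, (self.Q - (self.k - 1)) / self.Q)


def dersimonian_laird(betas, ses) -> DLResult:
    """Pool estimates with the DerSimonian-Laird random-effects model.

    Parameters
    ----------
    betas, ses : array-like
        Point estimates and their standard errors (same length, ses > 0).

    Returns
    -------
    DLResult
        Pooled estimate, its standard error, tau^2, Cochran's Q and k.
        For a single estimate the input is passed through with tau^2 = 0.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("cannot pool an empty set of estimates")
    if betas.shape != ses.shape:
        raise ValueError("betas and ses must have the same length")
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    k = betas.size
    if k == 1:
        log.info("pooling a single estimate: pass-through with tau^2 = 0")
        return DLResult(float(betas[0]), float(ses[0]), 0.0, 0.0, 1)

    w = 1.0 / ses**2
    beta_fe = float(np.sum(w * betas) / np.sum(w))
    Q = float(np.sum(w * (betas - beta_fe) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (ses**2 + tau2)
    beta_re = float(np.sum(w_re * betas) / np.sum(w_re))
    se_re = float(1.0 / np.sqrt(np.sum(w_re)))
    return DLResult(beta_re, se_re, float(tau2), Q, int(k))
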