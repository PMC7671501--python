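import numpy as np
import pytest

import aqindex as aq
from aqindex.health import load_example_coefficients


@pytest.fixture(scope="session")
def breakpoints():
    return aq.BreakpointTable.default()


@pytest.fixture(scope="session")
def sim_series():
    """One simulated county under study-like defaults (3 years daily)."""
    return aq.simulate_county(aq.default_config(n_counties=1, seed=42), 0)


@pytest.fixture(scope="session")
def pooled_coeffs():
    return aq.pool_study_table(load_example_coefficients())


@pytest.fixture(scope="session")
def fixed_spec():
    """Analysis model with fixed weather-spline dfs (no AIC search)."""
    return aq.ModelSpec(exposure="pm25", season="cool", lag=(0, 3),
                        temp_df=3, lagtemp_df=3, rh_df=3)


def dl_hand_oracle(betas, ses):
    """Step-by-step DerSimonian-Laird computation, written independently of
    the package implementation: plain loops over the textbook formulas."""
    k = len(betas)
    w = [1.0 / s**2 for s in ses]
    beta_fe = sum(wi * bi for wi, bi in zip(w, betas)) / sum(w)
    Q = sum(wi * (bi - beta_fe) ** 2 for wi, bi in zip(w, betas))
    denom = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / denom)
    w_star = [1.0 / (s**2 + tau2) for s in ses]
    beta_re = sum(wi * bi for wi, bi in zip(w_star, betas)) / sum(w_star)
    se_re = (1.0 / sum(w_star)) ** 0.5
    return beta_re, se_re, tau2, Q


def spearman_midrank_oracle(x, y):
    """Spearman rho as the Pearson correlation of mid-ranks (brute force)."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        out = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            out[i] = less + (equal + 1) / 2.0
        return out
    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])
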