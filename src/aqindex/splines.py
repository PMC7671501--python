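"""Natural cubic spline bases for confounder adjustment.

Natural cubic splines are the standard smooth-adjustment device in
short-term air-pollution time-series regression: they are piecewise cubic
between knots and constrained to be *linear* beyond the boundary knots,
which keeps extrapolation at the edges of the data tame.

The basis built here spans the same function space as R's ``splines::ns``:
``df`` columns (no intercept column), interior knots at equally spaced
quantiles of the data, boundary knots at the min and max.  ``df = 1``
degenerates to a single column affine in ``x``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["natural_spline_basis", "NaturalSpline"]


class NaturalSpline:
    """A natural cubic spline basis with frozen knots.

    Freezing the knots at construction lets the same basis be evaluated at
    new points (e.g. for extrapolation checks); the function space is linear
    outside ``[boundary_knots[0], boundary_knots[1]]`` by construction.

    Parameters
    ----------
    df : int
        Number of basis columns (>= 1). ``df - 1`` interior knots are used.
    knots : array-like
        Interior knots (may be empty).
    boundary_knots : (float, float)
        Lower and upper boundary knots.
    """

    def __init__(self, df: int, knots, boundary_knots):
        self.df = int(df)
        self.knots = np.asarray(knots, dtype=float)
        self.boundary_knots = (float(boundary_knots[0]), float(boundary_knots[1]))
        lo, hi = self.boundary_knots
        if not hi > lo:
            raise ValueError("boundary knots must be distinct and ordered")
        # all knots, boundaries included, ascending
        self._all = np.concatenate([[lo], np.sort(self.knots), [hi]])
        self._scale = hi - lo

    @classmethod
    def from_data(cls, x, df: int, name: str = "x") -> "NaturalSpline":
        x = np.asarray(x, dtype=float)
        x = x[~np.isnan(x)]
        if df < 1:
            raise ValueError("df must be >= 1")
        if np.unique(x).size < df + 1:
            raise ValueError(
                f"variable {name!r} has {np.unique(x).size} distinct values, "
                f"need at least {df + 1} for a df={df} natural spline"
            )
        probs = np.linspace(0.0, 1.0, df + 1)[1:-1]
        knots = np.quantile(x, probs) if probs.size else np.empty(0)
        return cls(df, knots, (x.min(), x.max()))

    def _d(self, x, k, km):
        """Truncated-power helper ((x-k)+^3 - (x-km)+^3) / (km - k)."""
        return (
            np.clip(x - k, 0.0, None) ** 3 - np.clip(x - km, 0.0, None) ** 3
        ) / (km - k)

    def design(self, x) -> np.ndarray:
        """Evaluate the basis at ``x``; returns an ``(n, df)`` array."""
        x = np.asarray(x, dtype=float)
        # work on the unit interval for numerical conditioning
        lo, _ = self.boundary_knots
        u = (x - lo) / self._scale
        ks = (self._all - lo) / self._scale
        cols = [u]
        km1, km = ks[-2], ks[-1]
        for k in ks[:-2]:
            cols.append(self._d(u, k, km) - self._d(u, km1, km))
        return np.column_stack(cols[: self.df])


def natural_spline_basis(x, df: int, name: str = "x") -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns.

    Interior knots sit at equally spaced quantiles of ``x``; boundary knots
    at its min and max. Raises ``ValueError`` naming the variable when ``x``
    has too few distinct values.
    """
    return NaturalSpline.from_data(x, df, name=name).design(np.asarray(x, dtype=float))
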