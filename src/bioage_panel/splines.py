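"""Natural cubic spline basis for age-trajectory fixed effects.

The trajectory models express the mean biological-age curve as
``intercept + ns(CA; df=3) + sex``, where ``ns`` is the natural cubic spline
basis: a cubic B-spline basis constrained to have zero second derivative at the
boundary knots, hence linear extrapolation outside the observed age range.

With ``df = 3`` the basis has two interior knots (placed at the 33.3/66.7
percentiles of observed age by default) and two boundary knots (observed
min/max age).  The construction mirrors the standard statistical-computing
recipe: build the unconstrained cubic B-spline design, drop the constant
column, and project onto the null space of the boundary second-derivative
constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = ["NaturalSplineBasis"]


@dataclass
class NaturalSplineBasis:
    """Frozen natural cubic spline basis with df columns.

    Parameters
    ----------
    interior_knots : array-like
        Interior knot locations (strictly inside the boundary).
    boundary : (low, high)
        Boundary knots; the basis is linear outside this interval.
    """

    interior_knots: np.ndarray
    boundary: tuple[float, float]
    _splines: list[BSpline] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        if not np.all((self.interior_knots > lo) & (self.interior_knots < hi)):
            raise ValueError("interior knots must lie strictly inside the boundary")
        self.interior_knots = np.asarray(self.interior_knots, dtype=float)
        t = np.r_[[lo] * 4, self.interior_knots, [hi] * 4]
        n_basis = len(t) - 4
        # second derivative of every B-spline basis element at the boundaries
        eye = np.eye(n_basis)
        const = np.empty((2, n_basis))
        for j in range(n_basis):
            d2 = BSpline(t, eye[j], 3).derivative(2)
            const[0, j] = d2(lo)
            const[1, j] = d2(hi)
        # drop the constant-direction column, then null space of the constraints
        keep = slice(1, None)
        ns_coef = null_space(const[:, keep])  # (n_basis-1, df)
        coefs = np.zeros((n_basis, ns_coef.shape[1]))
        coefs[keep] = ns_coef
        self._splines = [BSpline(t, coefs[:, j], 3) for j in range(coefs.shape[1])]

    @classmethod
    def from_data(cls, x, df: int = 3) -> "NaturalSplineBasis":
        """Quantile knot placement: df-1 interior knots at equal quantiles."""
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < df + 2:
            raise ValueError("not enough observations to place spline knots")
        lo, hi = float(x.min()), float(x.max())
        if lo == hi:
            raise ValueError("degenerate age range")
        probs = np.linspace(0, 1, df + 1)[1:-1]
        interior = np.quantile(x, probs)
        return cls(interior_knots=interior, boundary=(lo, hi))

    @property
    def df(self) -> int:
        return len(self._splines)

    def transform(self, x) -> np.ndarray:
        """Evaluate the basis; linear (first-order Taylor) outside the boundary."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.boundary
        xc = np.clip(x, lo, hi)
        out = np.column_stack([s(xc) for s in self._splines])
        below, above = x < lo, x > hi
        for mask, b in ((below, lo), (above, hi)):
            if np.any(mask):
                slopes = np.array([s.derivative(1)(b) for s in self._splines])
                out[mask] += (x[mask] - b)[:, None] * slopes[None, :]
        return out

    def is_extrapolating(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.boundary
        return (x < lo) | (x > hi)

    def to_dict(self) -> dict:
        return {
            "interior_knots": self.interior_knots.tolist(),
            "boundary": [float(self.boundary[0]), float(self.boundary[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalSplineBasis":
        return cls(
            interior_knots=np.asarray(d["interior_knots"], dtype=float),
            boundary=(d["boundary"][0], d["boundary"][1]),
        )
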