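"""Natural cubic spline basis for reaction-norm models.

The environmental smooth in the reaction-norm model is a natural cubic
spline of soil moisture with a small number of degrees of freedom
(``df=2`` by default: boundary knots at the observed extremes plus one
interior knot at the median).  Natural splines are piecewise cubics,
twice continuously differentiable, constrained to zero second and third
derivative beyond the boundary knots, so they extrapolate linearly --
the property that makes prediction on a 30--100% moisture grid that may
extend beyond a species' observed range well defined.

The basis is built from a cubic B-spline design matrix projected onto
the null space of the boundary-curvature constraints, with explicit
first-order Taylor extension outside the boundary knots.  Together with
the intercept the ``df`` returned columns span the full natural-spline
space for the given knots, which contains every linear function of x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SplineBasisDef:
    """Knot configuration of a natural cubic spline basis.

    boundary_knots are the (min, max) of the soil-moisture values the
    model was fitted on; interior_knots lie strictly between them.  The
    basis dimension (excluding the intercept) is
    ``df = len(interior_knots) + 1``.
    """

    boundary_knots: tuple[float, float]
    interior_knots: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("boundary knots must be finite and strictly ordered")
        for k in self.interior_knots:
            if not lo < k < hi:
                raise ValueError(
                    f"interior knot {k} not strictly inside boundaries ({lo}, {hi})"
                )
        if list(self.interior_knots) != sorted(self.interior_knots):
            raise ValueError("interior knots must be sorted")

    @property
    def df(self) -> int:
        return len(self.interior_knots) + 1


class NaturalSplineBasis:
    """Evaluate the natural cubic spline basis defined by a :class:`SplineBasisDef`.

    Construction mirrors the classical regression-spline recipe: take the
    order-4 B-spline design on the augmented knot sequence, drop the
    first column (absorbed by the model intercept), and rotate the rest
    onto the null space of the two second-derivative-at-boundary
    constraints.  Outside the boundary knots each basis function is
    continued linearly from its boundary value and slope.
    """

    def __init__(self, definition: SplineBasisDef):
        self.definition = definition
        lo, hi = definition.boundary_knots
        self._lo, self._hi = lo, hi
        # augmented knots for cubic B-splines
        self._knots = np.concatenate(
            [[lo] * 4, np.asarray(definition.interior_knots, float), [hi] * 4]
        )
        m = len(self._knots) - 4  # number of B-spline functions
        self._m = m
        # second derivatives of each B-spline at the two boundaries,
        # dropping the first function (intercept direction)
        const = np.column_stack(
            [self._bspline(j).derivative(2)([lo, hi]) for j in range(1, m)]
        )  # shape (2, m-1)
        q, _ = np.linalg.qr(const.T, mode="complete")
        self._null = q[:, 2:]  # (m-1, m-3) null-space rotation
        if self._null.shape[1] != definition.df:
            raise AssertionError("basis dimension mismatch")
        self._m = m

    @classmethod
    def from_data(cls, x: np.ndarray, df: int = 2) -> "NaturalSplineBasis":
        """Quantile knot placement: boundaries at min/max, ``df-1``
        interior knots at equally spaced quantiles (df=2 -> median)."""
        x = np.asarray(x, float)
        x = x[np.isfinite(x)]
        if np.unique(x).size < 3:
            raise ValueError("need at least 3 distinct x values to place knots")
        probs = np.linspace(0, 1, df + 1)[1:-1]
        interior = tuple(float(q) for q in np.quantile(x, probs))
        return cls(SplineBasisDef((float(x.min()), float(x.max())), interior))

    def _bspline(self, j: int) -> BSpline:
        c = np.zeros(self._m)
        c[j] = 1.0
        return BSpline(self._knots, c, 3, extrapolate=True)

    def _raw(self, x: np.ndarray, der: int = 0) -> np.ndarray:
        """B-spline design (columns 1..m-1) at points inside the boundaries."""
        cols = []
        for j in range(1, self._m):
            b = self._bspline(j)
            cols.append(b(x) if der == 0 else b.derivative(der)(x))
        return np.column_stack(cols)

    def __call__(self, x) -> np.ndarray:
        """Basis matrix (len(x) x df) with linear extrapolation outside
        the boundary knots."""
        x = np.atleast_1d(np.asarray(x, float))
        out = np.empty((x.size, self.definition.df))
        inside = (x >= self._lo) & (x <= self._hi)
        if inside.any():
            out[inside] = self._raw(x[inside]) @ self._null
        for boundary, mask in (
            (self._lo, x < self._lo),
            (self._hi, x > self._hi),
        ):
            if mask.any():
                b0 = np.asarray([boundary])
                val = (self._raw(b0) @ self._null)[0]
                slope = (self._raw(b0, der=1) @ self._null)[0]
                out[mask] = val + np.outer(x[mask] - boundary, slope)
        return out
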