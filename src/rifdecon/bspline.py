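"""Clamped B-spline basis for parameterizing the residue function.

The deconvolution unknown R(t) is expressed as R = B V where B is an
``n x (k + m)`` evaluation matrix of a clamped B-spline basis of order ``m``
(degree m-1) with ``k`` uniformly spaced interior knots over the measured
window, and V the coefficient vector.  Order 4 (cubic) gives continuous
first and second derivatives at the knots; ``k = floor(n/5)`` reduces the
number of unknowns five-fold relative to the time grid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .exceptions import OverparameterizedError

__all__ = ["SplineBasis", "bspline_basis", "first_derivative_operator"]


@dataclass(frozen=True)
class SplineBasis:
    """Evaluated clamped B-spline basis.

    Attributes
    ----------
    knots : ndarray
        Full clamped knot vector (m-fold end knots, k interior knots).
    m : int
        Spline order (degree + 1).
    k : int
        Number of interior knots.
    b : ndarray
        ``n x (k + m)`` evaluation matrix; rows sum to one (partition of
        unity) and all entries are non-negative.
    """

    knots: np.ndarray
    m: int
    k: int
    b: np.ndarray

    @property
    def n_coef(self) -> int:
        return self.k + self.m


def bspline_basis(tgrid: np.ndarray, k: int, m: int = 4) -> SplineBasis:
    """Evaluate a clamped uniform B-spline basis on ``tgrid``.

    Parameters
    ----------
    tgrid : array
        Strictly increasing sample times (n points).
    k : int
        Number of interior knots, uniformly spaced on (t0, tn).
    m : int
        Spline order; 4 = cubic.

    Returns a basis with ``k + m`` functions.  Raises
    :class:`OverparameterizedError` when ``k + m > n``.
    """
    t = np.asarray(tgrid, dtype=float)
    n = t.size
    if k < 1:
        raise ValueError("need at least one interior knot")
    if k + m > n:
        raise OverparameterizedError(
            f"{k + m} basis functions exceed {n} samples")
    interior = np.linspace(t[0], t[-1], k + 2)[1:-1]
    knots = np.concatenate([np.full(m, t[0]), interior, np.full(m, t[-1])])
    degree = m - 1
    b = BSpline.design_matrix(t, knots, degree, extrapolate=False).toarray()
    # design_matrix drops the final basis function's unit value at the right
    # endpoint for some scipy versions; clamp exact endpoint support
    b[-1, -1] = max(b[-1, -1], 1.0 - b[-1, :-1].sum())
    return SplineBasis(knots=knots, m=m, k=k, b=b)


def first_derivative_operator(n: int) -> np.ndarray:
    """(n-1) x n forward-difference stencil: rows (-1, 1) on adjacent columns.

    Discrete first-derivative seminorm operator used as the Tikhonov penalty
    on R; note it is the plain difference (no 1/dt), matching the stencil as
    conventionally printed.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    L = np.zeros((n - 1, n))
    idx = np.arange(n - 1)
    L[idx, idx] = -1.0
    L[idx, idx + 1] = 1.0
    return L
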