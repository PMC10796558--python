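"""Tikhonov-regularized deconvolution with L-curve selection.

Recovering R from C_tis = dt A R is a discretized Volterra/Fredholm problem
of the first kind: A is severely ill-conditioned and the naive inverse
amplifies noise.  The solution is stabilized in two steps:

1. R is written in a clamped cubic B-spline basis, R = B V, shrinking the
   unknowns from n to k + m (one coefficient per ~5 samples);
2. V minimizes the penalized least squares

       || dt A B V - y ||^2  +  lambda^2 || L B V ||^2,

   where L is the first-difference stencil acting on R (not on V: the
   physical prior — a smooth, minimally oscillating residue function —
   concerns R itself).

The weight lambda is chosen by the L-curve criterion: over a log-spaced
grid, plot log residual norm against log seminorm and take the point of
maximum curvature (the corner between the under- and over-regularized
branches), with curvature evaluated from local quadratic fits.

The per-lambda solves share one joint factorization of the (D, P) pair (a
generalized-singular-value style simultaneous diagonalization), so a full
50-point lambda sweep costs little more than a single solve.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.signal

from .bspline import SplineBasis, bspline_basis, first_derivative_operator
from .config import DEFAULT_CONFIG, DeconvolutionConfig
from .exceptions import (
    DegenerateLCurveWarning,
    NoInputSignalError,
    SingularSystemError,
)
from .kinetics import ResidueFunction
from .timecourse import TimeActivityCurve

__all__ = [
    "RegularizationResult",
    "TikhonovFactorization",
    "tikhonov_solve",
    "lcurve_corner",
    "deconvolve",
]


@dataclass(frozen=True)
class RegularizationResult:
    """Diagnostics of one L-curve sweep.

    ``residual_norms[i] = ||D v_i - y||`` and ``seminorms[i] = ||P v_i||``
    for each ``lambdas[i]``; ``curvature`` is the signed curvature of the
    (log residual, log seminorm) curve; ``lambda_star`` the selected weight,
    ``v_star`` its coefficient vector and ``r_star`` the residue samples
    ``B v_star``.
    """

    lambdas: np.ndarray
    residual_norms: np.ndarray
    seminorms: np.ndarray
    curvature: np.ndarray
    lambda_star: float
    v_star: np.ndarray
    r_star: np.ndarray

    @property
    def corner_index(self) -> int:
        return int(np.argmin(np.abs(self.lambdas - self.lambda_star)))


class TikhonovFactorization:
    """Joint diagonalization of a (design, penalty) pair.

    Computes once a basis X with  X^T D^T D X = diag(c2)  and
    X^T (D^T D + P^T P) X = I, after which the minimizer of
    ``||D v - y||^2 + lam^2 ||P v||^2`` for any ``lam`` is

        v(lam) = X diag(1 / (c2 + lam^2 s2)) X^T D^T y,

    with ``s2 = diag(X^T P^T P X)``.  Identical (to rounding) to solving the
    stacked augmented least-squares system per lambda, at a fraction of the
    cost across a lambda grid.
    """

    def __init__(self, D: np.ndarray, P: np.ndarray):
        D = np.asarray(D, dtype=float)
        P = np.asarray(P, dtype=float)
        if D.shape[1] != P.shape[1]:
            raise SingularSystemError("design and penalty column counts differ")
        M1 = D.T @ D
        M2 = P.T @ P
        M = M1 + M2
        try:
            L = scipy.linalg.cholesky(M, lower=True)
        except scipy.linalg.LinAlgError as exc:
            raise SingularSystemError(
                "stacked (design, penalty) system is rank deficient") from exc
        # S = L^-1 M1 L^-T is symmetric PSD with eigenvalues in [0, 1]
        W = scipy.linalg.solve_triangular(L, M1, lower=True)
        S = scipy.linalg.solve_triangular(L, W.T, lower=True)
        S = 0.5 * (S + S.T)
        c2, U = scipy.linalg.eigh(S)
        X = scipy.linalg.solve_triangular(L.T, U, lower=False)
        self.D = D
        self.P = P
        self.X = X
        self.c2 = np.clip(c2, 0.0, None)
        # recompute the penalty weights directly to avoid 1 - c2 cancellation
        PX = P @ X
        self.s2 = np.einsum("ij,ij->j", PX, PX)

    def solve(self, y: np.ndarray, lam: float) -> np.ndarray:
        b = self.X.T @ (self.D.T @ np.asarray(y, dtype=float))
        denom = self.c2 + lam * lam * self.s2
        if np.any(denom <= 0):
            raise SingularSystemError("degenerate regularized system")
        return self.X @ (b / denom)

    def sigma_max(self) -> float:
        """Largest singular value of D (sets the lambda-grid scale)."""
        return float(np.sqrt(scipy.linalg.eigh(
            self.D.T @ self.D, eigvals_only=True,
            subset_by_index=(self.D.shape[1] - 1, self.D.shape[1] - 1))[0]))


def tikhonov_solve(D: np.ndarray, y: np.ndarray, P: np.ndarray,
                   lam: float) -> np.ndarray:
    """Minimize ``||D v - y||^2 + lam^2 ||P v||^2`` for a single lambda."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    return TikhonovFactorization(D, P).solve(y, lam)


def _savgol_derivatives(y: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivatives w.r.t. sample index by local quadratic fits."""
    window = min(window, y.size if y.size % 2 == 1 else y.size - 1)
    d1 = scipy.signal.savgol_filter(y, window, 2, deriv=1)
    d2 = scipy.signal.savgol_filter(y, window, 2, deriv=2)
    return d1, d2


def lcurve_corner(lambdas: np.ndarray, residual_norms: np.ndarray,
                  seminorms: np.ndarray,
                  config: DeconvolutionConfig = DEFAULT_CONFIG,
                  ) -> tuple[float, np.ndarray]:
    """Select the regularization weight at the L-curve corner.

    The corner is the lambda maximizing the signed curvature of the
    parametric curve (log residual norm, log seminorm) traversed with
    increasing lambda; derivatives are taken by local quadratic fits over a
    5-point stencil of the (uniform) log-lambda grid.  Ties break toward the
    larger lambda (smoother solution).

    Residual norms should be non-decreasing and seminorms non-increasing in
    lambda; violations beyond a small slack trigger a
    :class:`DegenerateLCurveWarning` and the norms are smoothed before the
    curvature is evaluated.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size < 10:
        raise ValueError("need at least 10 lambda points for corner detection")
    rho = np.log(np.maximum(residual_norms, 1e-300))
    eta = np.log(np.maximum(seminorms, 1e-300))

    slack = 1e-8
    bad = (np.any(np.diff(residual_norms) < -slack * residual_norms[:-1].max())
           or np.any(np.diff(seminorms) > slack * np.abs(seminorms).max()))
    if bad:
        warnings.warn("L-curve norms non-monotone; smoothing before corner "
                      "detection", DegenerateLCurveWarning, stacklevel=2)
        w = min(7, rho.size if rho.size % 2 == 1 else rho.size - 1)
        rho = scipy.signal.savgol_filter(rho, w, 2)
        eta = scipy.signal.savgol_filter(eta, w, 2)

    d1r, d2r = _savgol_derivatives(rho, config.curvature_window)
    d1e, d2e = _savgol_derivatives(eta, config.curvature_window)
    speed = np.sqrt(d1r ** 2 + d1e ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (d1r * d2e - d1e * d2r) / speed ** 3
    # where the curve barely moves (the spline basis already fixes the
    # solution and lambda is inconsequential) curvature is numerical noise;
    # such points cannot be the corner
    moving = speed > 1e-4
    kappa = np.where(moving, kappa, -np.inf)
    if not np.any(moving):
        # whole curve is degenerate-flat: every lambda gives the same
        # solution, return the largest (smoothest by convention)
        return float(lambdas[-1]), kappa
    best = np.max(kappa)
    # ties (within float slop) break toward larger lambda
    candidates = np.flatnonzero(kappa >= best - 1e-12 * abs(best) - 1e-300)
    return float(lambdas[candidates[-1]]), kappa


def deconvolve(aif: TimeActivityCurve, tis: TimeActivityCurve,
               config: DeconvolutionConfig = DEFAULT_CONFIG,
               factorization: Optional["_PreparedSystem"] = None,
               ) -> tuple[ResidueFunction, RegularizationResult]:
    """End-to-end regularized deconvolution of one tissue curve.

    Builds the Toeplitz design on the (already aligned, uniformly sampled)
    grid, sweeps the lambda grid, picks the L-curve corner and returns the
    residue function at the corner together with full diagnostics.
    Deterministic given inputs and config.
    """
    aif.require_same_grid(tis)
    if not np.any(aif.c > 0):
        raise NoInputSignalError("AIF carries no signal")
    prep = factorization if factorization is not None else prepare_system(aif, config)
    y = tis.c

    lambdas = prep.lambda_grid(config)
    nl = lambdas.size
    p = prep.basis.n_coef
    vs = np.empty((nl, p))
    residual_norms = np.empty(nl)
    seminorms = np.empty(nl)
    for i, lam in enumerate(lambdas):
        v = prep.factorization.solve(y, lam)
        vs[i] = v
        residual_norms[i] = np.linalg.norm(prep.D @ v - y)
        seminorms[i] = np.linalg.norm(prep.P @ v)

    lambda_star, curvature = lcurve_corner(lambdas, residual_norms,
                                           seminorms, config)
    i_star = int(np.argmin(np.abs(lambdas - lambda_star)))
    v_star = vs[i_star]
    r_star = prep.basis.b @ v_star
    if config.nonneg_projection:
        r_star = np.maximum(r_star, 0.0)
    reg = RegularizationResult(lambdas=lambdas, residual_norms=residual_norms,
                               seminorms=seminorms, curvature=curvature,
                               lambda_star=lambda_star, v_star=v_star,
                               r_star=r_star)
    return ResidueFunction(aif.t, r_star), reg


@dataclass
class _PreparedSystem:
    """Design/penalty matrices and their factorization for one AIF.

    Reused across voxels that share the (shifted) AIF: the expensive pieces
    — building D and the joint factorization — depend only on the input
    function, not on the tissue curve.
    """

    basis: SplineBasis
    D: np.ndarray
    P: np.ndarray
    factorization: TikhonovFactorization
    _sigma_max: float = field(default=0.0)

    def lambda_grid(self, config: DeconvolutionConfig) -> np.ndarray:
        smax = self._sigma_max
        return np.geomspace(config.lambda_min_ratio * smax,
                            config.lambda_max_ratio * smax,
                            config.n_lambdas)


def prepare_system(aif: TimeActivityCurve,
                   config: DeconvolutionConfig = DEFAULT_CONFIG) -> _PreparedSystem:
    """Build D = dt A B and P = L B for an AIF and factorize once."""
    n = len(aif)
    k = max(1, n // config.k_divisor)
    basis = bspline_basis(aif.t, k, config.spline_order)
    # columns of A @ B are causal convolutions of the AIF with basis columns
    cols = [scipy.signal.fftconvolve(aif.c, basis.b[:, j])[:n]
            for j in range(basis.n_coef)]
    D = aif.dt * np.stack(cols, axis=1)
    P = first_derivative_operator(n) @ basis.b
    fact = TikhonovFactorization(D, P)
    return _PreparedSystem(basis=basis, D=D, P=P, factorization=fact,
                           _sigma_max=fact.sigma_max())
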