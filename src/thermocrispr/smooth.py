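"""Penalized cubic-spline smoothing of abundance against temperature.

The smoother plays the role of a one-dimensional GAM: abundance is
regressed on temperature through a cubic B-spline basis with knots at
temperature quantiles, penalized by the integrated squared second
derivative.  The smoothing parameter is chosen by generalized
cross-validation (GCV), and the fit's effective degrees of freedom (edf,
the trace of the influence matrix) measure how non-linear the fitted
relationship is.  A secondary shrinkage penalty on the slope component of
the penalty null space is selected on the same GCV grid, so that data with
no trend collapse to edf ~ 1 and exactly linear data to edf ~ 2.

The location of the most abrupt increase is read off the first-derivative
curve of the fit on a fine temperature grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = [
    "SmoothFit",
    "DerivativeCurve",
    "fit_smooth",
    "derivative",
    "build_design",
    "penalized_edf",
]

#: wiggliness-penalty grid (log-spaced) searched by GCV
RHO_GRID = np.logspace(-4, 4, 81)
#: null-space (slope) shrinkage grid; 0 = slope unpenalized
RHO0_GRID = np.concatenate([[0.0], np.logspace(-2, 8, 11)])


@dataclass
class SmoothFit:
    knots: np.ndarray
    coefficients: np.ndarray
    smoothing_parameter: float
    nullspace_shrinkage: float
    edf: float
    gcv_score: float
    grid_temperature: np.ndarray
    grid_fitted: np.ndarray
    basis_dim: int

    def predict(self, t) -> np.ndarray:
        spline = BSpline(self.knots, self.coefficients, 3, extrapolate=True)
        return spline(np.asarray(t, dtype=float))


@dataclass
class DerivativeCurve:
    grid_temperature: np.ndarray
    values: np.ndarray            # abundance units per °C
    argmax_temperature: int       # integer °C of the steepest increase


def _bspline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    return BSpline.design_matrix(x, knots, 3, extrapolate=True).toarray()


def _second_derivative_penalty(knots: np.ndarray, k: int) -> np.ndarray:
    """Gram matrix of second derivatives: S_ij = ∫ B_i'' B_j''.

    Second derivatives of cubic B-splines are piecewise linear, so 2-point
    Gauss-Legendre quadrature per knot interval is exact.
    """
    S = np.zeros((k, k))
    # second-derivative B-spline design via per-basis splines
    eye = np.eye(k)
    d2 = [BSpline(knots, eye[j], 3).derivative(2) for j in range(k)]
    xg, wg = np.polynomial.legendre.leggauss(2)
    breaks = np.unique(knots)
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        pts = mid + half * xg
        D = np.array([f(pts) for f in d2])          # k x 2
        S += half * (D * wg) @ D.T
    return S


def build_design(x: np.ndarray, basis_dim: int):
    """Spline design for the smoother.

    Returns ``(knots, B, S, S0, Z)``: B-spline knot vector, the design
    matrix, the wiggliness (second-derivative) penalty, the rank-1
    shrinkage of the slope direction in the penalty null space (the
    constant stays unpenalized), and the natural-boundary constraint map
    Z.  Columns of B/S/S0 live in the constrained coordinate system; full
    B-spline coefficients are recovered as ``Z @ theta``.  The natural
    constraints f''(min) = f''(max) = 0 restrict the fit to the classical
    smoothing-spline solution space and suppress boundary curl.
    """
    n_interior = basis_dim - 4
    if n_interior < 0:
        raise ValueError("basis_dim must be >= 4 for a cubic basis")
    lo, hi = x.min(), x.max()
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(np.unique(x), qs) if n_interior else np.array([])
    # strictly interior, deduplicated: heavy ties in x must not degenerate
    # the basis (effective dimension may drop below basis_dim)
    interior = np.unique(interior[(interior > lo) & (interior < hi)])
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])

    B = _bspline_design(x, knots)
    k = B.shape[1]
    S = _second_derivative_penalty(knots, k)

    eye = np.eye(k)
    d2_lo = np.array([BSpline(knots, eye[j], 3).derivative(2)(lo) for j in range(k)])
    d2_hi = np.array([BSpline(knots, eye[j], 3).derivative(2)(hi) for j in range(k)])
    Z = null_space(np.vstack([d2_lo, d2_hi]))
    B = B @ Z
    S = Z.T @ S @ Z
    kz = B.shape[1]

    # null space of S spans constant + linear trends in coefficient space;
    # shrink only the slope direction (orthogonal to the constant)
    evals, evecs = np.linalg.eigh(S)
    null = evecs[:, evals < 1e-9 * max(evals.max(), 1.0)]
    const_coef = np.linalg.lstsq(Z, np.ones(k), rcond=None)[0]
    const = const_coef / np.linalg.norm(const_coef)
    proj = null - np.outer(const, const @ null)
    u, sv, _ = np.linalg.svd(proj, full_matrices=False)
    slope_dir = u[:, 0] if sv[0] > 1e-9 else None
    S0 = np.outer(slope_dir, slope_dir) if slope_dir is not None else np.zeros((kz, kz))
    return knots, B, S, S0, Z


def penalized_edf(B: np.ndarray, S: np.ndarray, rho: float, S0=None, rho0: float = 0.0) -> float:
    """Effective degrees of freedom of the penalized fit at given penalties."""
    BtB = B.T @ B
    P = BtB + rho * S
    if S0 is not None and rho0:
        P = P + rho0 * S0
    return float(np.trace(np.linalg.solve(P, BtB)))


def fit_smooth(
    topt,
    abundance,
    basis_dim: int = 10,
    grid_step: float = 0.1,
    gamma: float = 1.4,
) -> SmoothFit:
    """Fit the penalized spline and evaluate it on a fine temperature grid.

    Knots sit at temperature quantiles; the fitted curve is evaluated every
    ``grid_step`` °C across the observed range.  ``gamma`` inflates the
    degrees-of-freedom cost in the GCV score (GCV tends to undersmooth;
    1.4 is the standard correction).  Raises if there are fewer than
    ``basis_dim + 2`` observations.
    """
    x = np.asarray(topt, dtype=float)
    y = np.asarray(abundance, dtype=float)
    n = len(x)
    if n < basis_dim + 2:
        raise ValueError(
            f"need at least basis_dim + 2 = {basis_dim + 2} observations "
            f"(got {n}); reduce basis_dim"
        )
    if np.ptp(x) == 0:
        raise ValueError("constant temperature axis")
    knots, B, S, S0, Z = build_design(x, basis_dim)

    BtB = B.T @ B
    Bty = B.T @ y
    yty = float(y @ y)
    scale = np.trace(BtB) / max(np.trace(S), np.finfo(float).tiny)

    # interpolating fits leave only round-off residuals; treat those as an
    # exact zero so GCV ties resolve toward the smallest edf
    rss_floor = 1e-12 * (yty + 1.0)
    best = None
    for rho0 in RHO0_GRID:
        for rho in RHO_GRID:
            P = BtB + rho * scale * S + rho0 * scale * S0
            try:
                Pinv = np.linalg.inv(P)
            except np.linalg.LinAlgError:
                continue
            coef = Pinv @ Bty
            edf = float(np.trace(Pinv @ BtB))
            rss = yty - 2 * float(coef @ Bty) + float(coef @ (BtB @ coef))
            rss = 0.0 if rss < rss_floor else rss
            denom = max(n - gamma * edf, 1e-8)
            gcv = n * rss / denom**2
            if (
                best is None
                or gcv < best[0] * (1 - 1e-10) - 1e-300
                or (gcv <= best[0] * (1 + 1e-10) + 1e-300 and edf < best[4] - 1e-9)
            ):
                best = (gcv, rho, rho0, coef, edf)
    gcv, rho, rho0, theta, edf = best
    coef = Z @ theta

    lo, hi = x.min(), x.max()
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    fitted = BSpline(knots, coef, 3, extrapolate=True)(grid)
    return SmoothFit(
        knots=knots,
        coefficients=coef,
        smoothing_parameter=float(rho),
        nullspace_shrinkage=float(rho0),
        edf=edf,
        gcv_score=float(gcv),
        grid_temperature=grid,
        grid_fitted=fitted,
        basis_dim=basis_dim,
    )


def derivative(fit: SmoothFit, step: float | None = None) -> DerivativeCurve:
    """First derivative of the fitted curve by finite differences.

    Central differences on the prediction grid, one-sided at the endpoints.
    The reported transition temperature is the integer °C nearest the grid
    argmax of the derivative (ties go to the smaller temperature).
    """
    t = fit.grid_temperature
    f = fit.grid_fitted
    d = np.gradient(f, t)
    k = int(np.argmax(d))
    return DerivativeCurve(t, d, int(round(float(t[k]))))
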