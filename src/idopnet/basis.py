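"""Shared numerical machinery for trajectory modelling.

Three building blocks used everywhere else in the package:

* Legendre orthogonal polynomial (LOP) bases on a rescaled time grid,
  together with their antiderivatives, used to smooth ODE rate terms
  nonparametrically;
* the logistic growth curve ``a / (1 + b e^{-rt})``, the parametric form
  for independent (self-driven) growth components;
* the first-order structured antedependence covariance, SAD(1), whose
  inverse and determinant have closed forms, which keeps longitudinal
  likelihood evaluations cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "LOPBasis",
    "LogisticParams",
    "SAD1Params",
    "SAD1Cov",
    "lop_basis",
    "lop_antiderivative",
    "logistic_curve",
    "sad1_cov",
    "sad1_whiten",
    "sad1_bivariate_logdet",
    "smooth_series",
]


# ---------------------------------------------------------------------------
# Legendre orthogonal polynomials
# ---------------------------------------------------------------------------

@dataclass
class LOPBasis:
    """Legendre polynomial basis evaluated on a time grid.

    Attributes
    ----------
    order : int
        Highest polynomial degree R; the basis has R+1 columns.
    times : ndarray
        Original (unscaled) observation times.
    scaled_times : ndarray
        Times affinely mapped onto [-1, 1].
    P : ndarray of shape (T, R+1)
        ``P[j, r] = p_r(scaled_times[j])``.
    Q : ndarray of shape (T, R+1) or None
        Cumulative-trapezoid antiderivatives of the columns of P in scaled
        time, anchored so the first row is zero.  Filled by
        :func:`lop_antiderivative`.
    """

    order: int
    times: np.ndarray
    scaled_times: np.ndarray
    P: np.ndarray
    Q: Optional[np.ndarray] = None


def _scale_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    tmin, tmax = t[0], t[-1]
    if tmax == tmin:
        raise ValueError("time grid is constant; cannot rescale to [-1, 1]")
    return 2.0 * (t - tmin) / (tmax - tmin) - 1.0


def lop_basis(times: np.ndarray, order: int) -> LOPBasis:
    """Evaluate Legendre polynomials p_0..p_order on a rescaled grid.

    Times are mapped affinely so the first and last grid points hit -1 and
    1 exactly, then the polynomials are generated by the stable three-term
    recurrence ``(r+1) p_{r+1} = (2r+1) x p_r - r p_{r-1}``.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2 or np.unique(t).size < 2:
        raise ValueError("need at least two distinct time points")
    if order < 0:
        raise ValueError("order must be >= 0")
    x = _scale_times(t)
    P = np.empty((t.size, order + 1))
    P[:, 0] = 1.0
    if order >= 1:
        P[:, 1] = x
    for r in range(1, order):
        P[:, r + 1] = ((2 * r + 1) * x * P[:, r] - r * P[:, r - 1]) / (r + 1)
    return LOPBasis(order=order, times=t, scaled_times=x, P=P)


def lop_antiderivative(basis: LOPBasis) -> LOPBasis:
    """Fill ``Q`` with cumulative-trapezoid antiderivatives of ``P``.

    Integration is carried out in scaled time with the constant anchored so
    that every antiderivative is zero at the first grid point.
    """
    Q = cumulative_trapezoid(basis.P, basis.scaled_times, axis=0, initial=0.0)
    return LOPBasis(
        order=basis.order,
        times=basis.times,
        scaled_times=basis.scaled_times,
        P=basis.P,
        Q=Q,
    )


# ---------------------------------------------------------------------------
# Logistic growth
# ---------------------------------------------------------------------------

@dataclass
class LogisticParams:
    """Parameters of the logistic growth curve a / (1 + b e^{-rt}).

    ``a`` is the asymptote in trait units, ``b`` sets the starting point
    through y(0) = a/(1+b), and ``r`` is the intrinsic growth rate (1/time).
    """

    a: float
    b: float
    r: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.r <= 0:
            raise ValueError(
                f"logistic parameters must be positive, got a={self.a}, "
                f"b={self.b}, r={self.r}"
            )


def logistic_curve(params: LogisticParams, times: np.ndarray) -> np.ndarray:
    """Evaluate the logistic growth curve on a grid."""
    t = np.asarray(times, dtype=float)
    return params.a / (1.0 + params.b * np.exp(-params.r * t))


def _logistic_values(a: float, b: float, r: float, times: np.ndarray) -> np.ndarray:
    # unchecked fast path for optimizers
    return a / (1.0 + b * np.exp(-r * times))


# ---------------------------------------------------------------------------
# SAD(1) covariance
# ---------------------------------------------------------------------------

@dataclass
class SAD1Params:
    """First-order structured antedependence parameters.

    The latent residual process is z(t_j) = phi * z(t_{j-1}) + eps_j with
    eps_j ~ N(0, nu2) and z zero before the first observation, giving a
    nonstationary variance profile.  ``rho`` is the optional innovation
    correlation between two traits measured at the same times.
    """

    phi: float
    nu2: float
    rho: Optional[float] = None

    def __post_init__(self) -> None:
        if self.nu2 <= 0:
            raise ValueError(f"innovation variance nu2 must be > 0, got {self.nu2}")
        if self.rho is not None and not -1.0 < self.rho < 1.0:
            raise ValueError(f"cross-trait rho must lie in (-1, 1), got {self.rho}")


@dataclass
class SAD1Cov:
    """Covariance bundle: matrix, closed-form inverse and log-determinant."""

    cov: np.ndarray
    inv: np.ndarray
    logdet: float


def sad1_cov(params: SAD1Params, T: int) -> SAD1Cov:
    """Closed-form SAD(1) covariance of a length-T series.

    With L the lower-bidiagonal innovation operator (ones on the diagonal,
    -phi on the first subdiagonal), the series is z = L^{-1} eps, so

        cov    = nu2 * L^{-1} L^{-T},      L^{-1}[i, j] = phi^{i-j} (i >= j)
        inv    = L^T L / nu2               (tridiagonal)
        logdet = T * log(nu2)              (L is unit triangular)
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    phi, nu2 = params.phi, params.nu2
    i = np.arange(T)
    diff = i[:, None] - i[None, :]
    C = np.where(diff >= 0, np.power(phi, np.clip(diff, 0, None)), 0.0)
    cov = nu2 * C @ C.T
    L = np.eye(T)
    if T > 1:
        L[np.arange(1, T), np.arange(T - 1)] = -phi
    inv = L.T @ L / nu2
    logdet = T * np.log(nu2)
    return SAD1Cov(cov=cov, inv=inv, logdet=logdet)


def sad1_whiten(resid: np.ndarray, phi: float) -> np.ndarray:
    """Map residual series to their SAD(1) innovations along the last axis.

    eps_j = z_j - phi z_{j-1} with z_0 = 0; the quadratic form
    r^T Sigma^{-1} r equals ||eps||^2 / nu2.
    """
    r = np.asarray(resid, dtype=float)
    eps = r.copy()
    eps[..., 1:] -= phi * r[..., :-1]
    return eps


def sad1_bivariate_logdet(nu2_1: float, nu2_2: float, rho: float, T: int) -> float:
    """Log-determinant of the joint SAD(1) covariance of two traits.

    Each trait follows its own SAD(1) recursion; innovations at the same
    time are correlated with coefficient rho.  The joint covariance of the
    concatenated 2T-vector is B K B^T with B unit triangular, so the
    determinant is that of the stacked innovation covariance.
    """
    return T * float(np.log(nu2_1 * nu2_2 * (1.0 - rho**2)))


# ---------------------------------------------------------------------------
# LOP least-squares smoothing
# ---------------------------------------------------------------------------

def smooth_series(
    values: np.ndarray,
    times: np.ndarray,
    max_order: Optional[int] = None,
    return_noise: bool = False,
):
    """Denoise one series by Legendre least squares with BIC order choice.

    Fits LOP expansions of degree 2..max_order (default min(8, T-3)) and
    returns the fitted values of the degree minimizing
    ``T log(RSS/T) + (R+1) log T``.  With ``return_noise=True`` also
    returns the residual-based noise variance estimate RSS/(T-R-1).  Used
    to stabilize trajectory curves before building ODE regressions from
    noisy observations.
    """
    y = np.asarray(values, dtype=float)
    T = y.size
    if max_order is None:
        max_order = min(8, T - 3)
    max_order = max(2, max_order)
    best = None
    best_bic = np.inf
    best_sigma2 = 0.0
    basis = lop_basis(times, max_order)
    for R in range(2, max_order + 1):
        X = basis.P[:, : R + 1]
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ coef
        rss = float(np.sum((y - fitted) ** 2))
        bic = T * np.log(max(rss, 1e-12) / T) + (R + 1) * np.log(T)
        if bic < best_bic:
            best_bic = bic
            best = fitted
            best_sigma2 = rss / max(T - R - 1, 1)
    if return_noise:
        return best, best_sigma2
    return best
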