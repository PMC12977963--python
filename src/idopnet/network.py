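"""Mixed-ODE decomposition and sparse network reconstruction.

Every node (a genotype's trajectory at one SNP for one trait, or a module
mean curve) obeys a mixed ODE: its rate of change is the sum of a
self-driven (independent) term and regulator-driven (dependent) terms,
each expressed as a Legendre-polynomial expansion multiplying the relevant
curve.  Integrating once turns the ODE into a linear regression of the
anchored trajectory on cumulative integrals of basis-times-curve products.
Regulators are selected with a group LASSO that penalizes each candidate's
whole coefficient block (the self block is never penalized); the penalty
level is chosen by BIC along a warm-started path.  Active blocks become
signed, weighted, directed edges: epistatic within a trait layer,
pleiotropic between the two trajectories of the same SNP across layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from sklearn.base import BaseEstimator

from .basis import lop_antiderivative, lop_basis, smooth_series
from .io import AnalysisConfig, IdopNetwork, NetworkEdge, NetworkNode

logger = logging.getLogger("idopnet")

SELF = "_self"

__all__ = [
    "RegressorSet",
    "GroupLassoFit",
    "ODEDecomposition",
    "build_regressors",
    "group_lasso_fit",
    "kkt_violation",
    "select_lambda",
    "decompose",
    "extract_edges",
    "build_entanglement",
    "build_multilayer",
    "decompose_trait_pair",
    "MixedODENetwork",
]


# ---------------------------------------------------------------------------
# Regression design
# ---------------------------------------------------------------------------

@dataclass
class RegressorSet:
    """Design matrix bundle for one focal node's integrated mixed ODE.

    ``response`` is the focal trajectory anchored at the first observation
    (value at t_1 subtracted, stored in ``anchor``).  The unpenalized self
    block holds a linear-in-time column plus the integrals of each basis
    polynomial times the focal curve; every candidate regulator contributes
    one penalized block of integrals of basis polynomials times its curve.
    """

    node: Tuple[str, str]  # (id, layer)
    times: np.ndarray
    response: np.ndarray
    anchor: float
    self_block: np.ndarray  # (T, R_s + 2)
    groups: Dict[Tuple[str, str], np.ndarray]  # regulator -> (T, R_dep + 1)

    @property
    def group_names(self) -> List[Tuple[str, str]]:
        return list(self.groups)


_QUAD_REFINE = 20  # spline-refinement factor for design-column quadrature


def _refine_grid(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform fine grid containing the scaled observation grid."""
    xf = np.linspace(x[0], x[-1], (x.size - 1) * _QUAD_REFINE + 1)
    idx = np.arange(0, xf.size, _QUAD_REFINE)
    return xf, idx


def _integrated_products(P_fine: np.ndarray, curve_fine: np.ndarray,
                         xf: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Columns: cumulative integral of p_r(s) * curve(s), anchored at 0.

    Integration runs on a spline-refined grid so that quadrature error sits
    far below the signal the regulator selection must resolve; the columns
    are then subsampled back onto the observation grid.
    """
    prod = P_fine * curve_fine[:, None]
    full = cumulative_trapezoid(prod, xf, axis=0, initial=0.0)
    return full[idx]


def build_regressors(
    focal: np.ndarray,
    candidates: Dict[Tuple[str, str], np.ndarray],
    times: np.ndarray,
    config: Optional[AnalysisConfig] = None,
    node: Tuple[str, str] = ("focal", ""),
    response: Optional[np.ndarray] = None,
) -> RegressorSet:
    """Assemble the integrated mixed-ODE regression for one focal node.

    ``focal`` and each candidate curve must share ``times``.  ``response``
    defaults to the focal curve itself; passing the raw observed series
    while using smoothed curves in the design keeps observation noise in
    the residual rather than in the regressors.

    The self block depends on ``config.independent_form``: the parametric
    ``"logistic"`` form yields the two columns [int y, int y^2] (the
    logistic rate r y - (r/a) y^2 integrated, linear in (r, r/a)); the
    nonparametric ``"lop"`` form yields a linear-in-time column plus the
    integrals of each basis polynomial times the focal curve.
    """
    from scipy.interpolate import CubicSpline

    config = config or AnalysisConfig()
    focal = np.asarray(focal, dtype=float)
    times = np.asarray(times, dtype=float)
    if focal.shape != times.shape:
        raise ValueError("focal curve and time grid have mismatched lengths")
    for name, c in candidates.items():
        if np.asarray(c).shape != times.shape:
            raise ValueError(f"candidate {name} is not on the shared grid")
    if node in candidates:
        raise ValueError("focal node may not appear among its own candidates")

    basis_self = lop_basis(times, config.lop_order_independent)
    x = basis_self.scaled_times
    xf, idx = _refine_grid(x)
    from numpy.polynomial.legendre import legvander

    focal_fine = CubicSpline(x, focal)(xf)
    if config.independent_form == "logistic":
        self_block = np.stack(
            [
                cumulative_trapezoid(focal_fine, xf, initial=0.0)[idx],
                cumulative_trapezoid(focal_fine**2, xf, initial=0.0)[idx],
            ],
            axis=1,
        )
    else:  # "lop": Eq-style nonparametric self expansion
        P_self_fine = legvander(xf, config.lop_order_independent)
        lin = (x - x[0])[:, None]
        self_block = np.hstack(
            [lin, _integrated_products(P_self_fine, focal_fine, xf, idx)]
        )
    P_dep_fine = legvander(xf, config.lop_order_dependent)
    groups = {
        name: _integrated_products(
            P_dep_fine, CubicSpline(x, np.asarray(c, dtype=float))(xf), xf, idx
        )
        for name, c in candidates.items()
    }
    obs = np.asarray(response, dtype=float) if response is not None else focal
    # anchor at the (smoothed) focal curve's start: anchoring at a noisy
    # observation would inject a constant offset into the response that the
    # intercept-free design cannot absorb
    anchor = float(focal[0])
    return RegressorSet(
        node=node,
        times=times,
        response=obs - anchor,
        anchor=anchor,
        self_block=self_block,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# Group LASSO (FISTA proximal gradient)
# ---------------------------------------------------------------------------

@dataclass
class GroupLassoFit:
    lam: float  # absolute penalty level
    coef_self: np.ndarray  # on the original column scale
    coefs: Dict[Tuple[str, str], np.ndarray]
    active: List[Tuple[str, str]]
    fitted: np.ndarray  # fitted anchored response
    rss: float
    df: int
    # standardized internals retained for KKT verification
    _X: np.ndarray = field(repr=False, default=None)
    _z: np.ndarray = field(repr=False, default=None)
    _b: np.ndarray = field(repr=False, default=None)
    _slices: dict = field(repr=False, default=None)
    _weights: dict = field(repr=False, default=None)


def _assemble(reg: RegressorSet):
    blocks = [reg.self_block] + [reg.groups[g] for g in reg.group_names]
    X = np.hstack(blocks)
    slices = {}
    start = 0
    for name, blk in zip([SELF] + reg.group_names,
                         blocks):
        slices[name] = slice(start, start + blk.shape[1])
        start += blk.shape[1]
    scales = np.linalg.norm(X, axis=0)
    scales[scales == 0] = 1.0
    Xs = X / scales
    weights = {g: np.sqrt(reg.groups[g].shape[1]) for g in reg.group_names}
    return Xs, scales, slices, weights


def _kkt_max_violation(XtX, Xtz, b, slices, weights, lam) -> float:
    from math import sqrt

    grad = XtX @ b - Xtz
    viol = np.max(np.abs(grad[slices[SELF]])) if slices[SELF].stop > 0 else 0.0
    for g, w in weights.items():
        sl = slices[g]
        bg = b[sl]
        nrm = sqrt(bg @ bg)
        if nrm == 0:
            gs = grad[sl]
            viol = max(viol, max(0.0, sqrt(gs @ gs) - lam * w))
        else:
            v = grad[sl] + lam * w * bg / nrm
            viol = max(viol, sqrt(v @ v))
    return float(viol)


def _group_update(U, s, Vt, r, lam_w, b_old):
    """Exact minimizer of 0.5||r - Xg b||^2 + lam_w ||b|| for one block.

    Via the SVD Xg = U diag(s) Vt: the solution is b = Vt^T diag(s/(s^2+mu)) c
    with c = U^T r scaled by s, where mu = lam_w / ||b|| solves the scalar
    secular equation mu ||b(mu)|| = lam_w (monotone; safeguarded Newton).
    The block is zero iff ||Xg^T r|| <= lam_w.
    """
    c = s * (U.T @ r)  # len = rank
    if lam_w <= 0:
        coef = np.zeros_like(s)
        nz = s > 1e-12 * (s[0] if s.size else 1.0)
        coef[nz] = c[nz] / (s[nz] ** 2)
        return Vt.T @ coef
    cnorm = np.linalg.norm(c)
    if cnorm <= lam_w:
        return np.zeros(Vt.shape[1])
    if c.size == 1:  # scalar block: plain soft threshold, no root-find
        return Vt.T @ ((c - np.sign(c) * lam_w) / (s**2))
    c2 = c * c
    # bracket: h(mu) = mu ||b(mu)|| - lam_w, increasing; h(hi) > 0 for
    # hi = cnorm - lam_w scaled by smallest active s^2 bound below
    lo, hi = 0.0, lam_w
    while True:
        d = s**2 + hi
        if hi * np.sqrt(np.sum(c2 / d**2)) >= lam_w:
            break
        hi *= 4.0
    mu = 0.5 * (lo + hi)
    for _ in range(60):
        d = s**2 + mu
        q = np.sum(c2 / d**2)
        nb = np.sqrt(q)
        h = mu * nb - lam_w
        if h > 0:
            hi = mu
        else:
            lo = mu
        dh = nb - mu * np.sum(c2 / d**3) / nb
        mu_new = mu - h / dh if dh > 0 else 0.5 * (lo + hi)
        if not (lo < mu_new < hi):
            mu_new = 0.5 * (lo + hi)
        if abs(mu_new - mu) <= 1e-14 * max(mu, 1e-300):
            mu = mu_new
            break
        mu = mu_new
    return Vt.T @ (c / (s**2 + mu))


def _fista(state, lam, b0, tol, max_iter=200000):
    """Accelerated proximal gradient fallback (slow but dependable)."""
    XtX, Xtz, slices, weights = state.XtX, state.Xtz, state.slices, state.weights
    L = state.L
    b = b0.copy()
    v = b.copy()
    t_k = 1.0
    pen = [(slices[g], lam * weights[g] / L) for g in weights]
    for it in range(max_iter):
        grad = XtX @ v - Xtz
        b_new = v - grad / L
        for sl, thr in pen:
            nrm = np.linalg.norm(b_new[sl])
            b_new[sl] *= 0.0 if nrm <= thr else (1.0 - thr / nrm)
        if np.dot(v - b_new, b_new - b) > 0:
            t_k = 1.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
        v = b_new + ((t_k - 1.0) / t_new) * (b_new - b)
        b, t_k = b_new, t_new
        if it % 100 == 99:
            if _kkt_max_violation(XtX, Xtz, b, slices, weights, lam) <= tol:
                break
    return b


def _newton_on_support(H, c, sub_slices, pen_groups, b, max_iter=60):
    """Damped Newton for the smooth restricted problem on a fixed support.

    Objective 0.5 b'Hb - c'b + sum lam_w ||b_g||; away from zero the
    penalty is twice differentiable, with block Hessian
    lam_w (I/||b|| - b b^T/||b||^3).
    """
    from math import sqrt

    def value(bv):
        val = 0.5 * bv @ (H @ bv) - c @ bv
        for sl, lw in pen_groups:
            bg = bv[sl]
            val += lw * sqrt(bg @ bg)
        return val

    def grad_of(bv):
        gr = H @ bv - c
        for sl, lw in pen_groups:
            bg = bv[sl]
            nrm = sqrt(bg @ bg)
            if nrm > 0:
                gr[sl] += lw * bg / nrm
        return gr

    val = value(b)
    gr = grad_of(b)
    gtol = 1e-12 * (sqrt(c @ c) + 1.0)
    for _ in range(max_iter):
        Hp = H.copy()
        for sl, lw in pen_groups:
            bg = b[sl]
            nrm = sqrt(bg @ bg)
            if nrm > 0:
                k = sl.stop - sl.start
                outer = np.outer(bg, bg) / (nrm * nrm)
                Hp[sl, sl] += (lw / nrm) * (np.eye(k) - outer)
        try:
            step = np.linalg.solve(Hp + 1e-12 * np.eye(Hp.shape[0]), gr)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Hp, gr, rcond=None)[0]
        gs = gr @ step
        t = 1.0
        for _ls in range(40):
            b_new = b - t * step
            val_new = value(b_new)
            if val_new <= val - 1e-4 * t * gs:
                break
            t *= 0.5
        if val - val_new <= 1e-15 * (abs(val) + 1.0) and t < 1e-6:
            break
        b, val = b_new, val_new
        gr = grad_of(b)
        if sqrt(gr @ gr) <= gtol:
            break
    return b


def _active_set_polish(state, lam, b, tol):
    """Finish a group-LASSO solve by Newton steps on the active support.

    Block coordinate descent stalls when candidate blocks are nearly
    collinear; away from zero the objective is smooth, so the restricted
    problem over the currently-active blocks is solved by damped Newton,
    after which the zero blocks' KKT conditions are re-checked and
    violating blocks admitted.  Convex problem, so the loop terminates at
    the optimum.
    """
    XtX, Xtz = state.XtX, state.Xtz
    slices, weights = state.slices, state.weights
    names = list(slices)
    b = b.copy()
    for _ in range(25):
        grad = XtX @ b - Xtz
        active = [g for g in names
                  if g == SELF or np.linalg.norm(b[slices[g]]) > 0]
        worst, worst_excess = None, tol
        for g in names:
            if g in active:
                continue
            excess = np.linalg.norm(grad[slices[g]]) - lam * weights[g]
            if excess > worst_excess:
                worst, worst_excess = g, excess
        if worst is not None:
            active.append(worst)
            b[slices[worst]] = 1e-8  # nudge off the nonsmooth point
        idx = np.concatenate([np.arange(slices[g].start, slices[g].stop)
                              for g in active])
        sub_slices = {}
        start = 0
        pen_groups = []
        for g in active:
            width = slices[g].stop - slices[g].start
            sub_slices[g] = slice(start, start + width)
            if g != SELF:
                pen_groups.append((sub_slices[g], lam * weights[g]))
            start += width
        H = XtX[np.ix_(idx, idx)]
        c = Xtz[idx]
        ba = _newton_on_support(H, c, sub_slices, pen_groups, b[idx])
        b[:] = 0.0
        b[idx] = ba
        for g in active:
            if g != SELF and np.linalg.norm(b[slices[g]]) < 1e-7:
                b[slices[g]] = 0.0
        if _kkt_max_violation(XtX, Xtz, b, slices, weights, lam) <= tol:
            break
    return b


class _SolverState:
    """Per-design quantities shared across a lambda path."""

    def __init__(self, reg: RegressorSet):
        Xs, scales, slices, weights = _assemble(reg)
        self.Xs, self.scales = Xs, scales
        self.slices, self.weights = slices, weights
        self.names = [SELF] + list(weights)
        self.XtX = Xs.T @ Xs
        self.Xtz = Xs.T @ reg.response
        self.L = float(np.linalg.eigvalsh(self.XtX)[-1])
        self.scale = max(np.max(np.abs(self.Xtz)), 1.0)
        self.svds = {g: np.linalg.svd(Xs[:, slices[g]], full_matrices=False)
                     for g in self.names}


def group_lasso_fit(
    reg: RegressorSet,
    lam: float,
    b0: Optional[np.ndarray] = None,
    max_iter: int = 2000,
    rtol: float = 1e-9,
    state: Optional[_SolverState] = None,
) -> GroupLassoFit:
    """Solve the integrated-ODE group LASSO at one penalty level.

    Minimizes ``0.5 ||z - Xb||^2 + lam * sum_g sqrt(p_g) ||b_g||_2`` with
    the self block unpenalized, by block coordinate descent with exact
    per-block updates (SVD plus a scalar root-find) on a
    column-standardized design, finished by Newton steps on the active
    support when blocks are strongly correlated.  At ``lam=0`` the
    minimum-norm least squares solution is returned directly.  Iterates
    until the maximum KKT violation falls below ``rtol`` times the
    gradient scale.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if state is None:
        state = _SolverState(reg)
    Xs, scales = state.Xs, state.scales
    slices, weights = state.slices, state.weights
    z = reg.response
    XtX, Xtz, scale = state.XtX, state.Xtz, state.scale
    p = Xs.shape[1]
    names = state.names
    if lam == 0.0:
        b, *_ = np.linalg.lstsq(Xs, z, rcond=None)
    else:
        b = np.zeros(p) if b0 is None else b0.copy()
        fitted = Xs @ b
        for sweep in range(30):
            for g in names:
                sl = slices[g]
                bg = b[sl]
                if np.any(bg):
                    fitted -= Xs[:, sl] @ bg
                r = z - fitted
                U, sv, Vt = state.svds[g]
                lam_w = 0.0 if g == SELF else lam * weights[g]
                bg_new = _group_update(U, sv, Vt, r, lam_w, bg)
                b[sl] = bg_new
                if np.any(bg_new):
                    fitted += Xs[:, sl] @ bg_new
            if _kkt_max_violation(XtX, Xtz, b, slices, weights,
                                  lam) <= rtol * scale:
                break
        if _kkt_max_violation(XtX, Xtz, b, slices, weights, lam) > rtol * scale:
            b = _active_set_polish(state, lam, b, rtol * scale)
        if _kkt_max_violation(XtX, Xtz, b, slices, weights, lam) > 1e-6 * scale:
            b = _fista(state, lam, b, 1e-7 * scale)
    if _kkt_max_violation(XtX, Xtz, b, slices, weights, lam) > 1e-5 * scale:
        raise RuntimeError(
            f"group LASSO did not converge at lam={lam:g} "
            f"(KKT violation above tolerance)"
        )
    fitted = Xs @ b
    coefs_scaled = b / scales
    coef_self = coefs_scaled[slices[SELF]]
    coefs = {g: coefs_scaled[slices[g]] for g in reg.group_names}
    active = [g for g in reg.group_names
              if np.linalg.norm(b[slices[g]]) > 0]
    rss = float(np.sum((z - fitted) ** 2))
    df = int(np.sum(b != 0.0))
    return GroupLassoFit(
        lam=lam, coef_self=coef_self, coefs=coefs, active=active,
        fitted=fitted, rss=rss, df=df,
        _X=Xs, _z=z, _b=b, _slices=slices, _weights=weights,
    )


def kkt_violation(fit: GroupLassoFit) -> float:
    """Maximum violation of the group-LASSO stationarity conditions."""
    XtX = fit._X.T @ fit._X
    Xtz = fit._X.T @ fit._z
    return _kkt_max_violation(XtX, Xtz, fit._b, fit._slices, fit._weights,
                              fit.lam)


def lambda_max(reg: RegressorSet) -> float:
    """Smallest absolute penalty zeroing every regulator block."""
    Xs, _, slices, weights = _assemble(reg)
    X0 = Xs[:, slices[SELF]]
    b0, *_ = np.linalg.lstsq(X0, reg.response, rcond=None)
    r0 = reg.response - X0 @ b0
    lmax = 0.0
    for g, w in weights.items():
        lmax = max(lmax, np.linalg.norm(Xs[:, slices[g]].T @ r0) / w)
    return lmax if lmax > 0 else 1.0


def select_lambda(
    reg: RegressorSet,
    lambda_grid: Optional[np.ndarray] = None,
    criterion: str = "BIC",
    floor_rel: float = 1e-5,
    sigma2_hat: float = 0.0,
    noise_floor_mult: float = 2.0,
) -> Tuple[float, GroupLassoFit]:
    """BIC-guided penalty selection along a warm-started path.

    ``lambda_grid`` holds fractions of the data-dependent lambda_max,
    ascending.  The path is traversed from the sparsest end downward with
    warm starts; the fit minimizing ``T log((RSS + delta)/T) + df log T``
    (or the AIC analogue) wins, with ties resolved toward the larger
    (sparser) penalty.  ``delta = floor_rel * ||z||^2`` is the squared
    relative error scale of reconstructing a smooth trajectory from T
    samples (spline interpolation plus quadrature): fit improvements below
    that floor carry no evidence and must not buy extra regulators, which
    is what keeps selection consistent on noise-free data.  Returns the
    winning absolute lambda and its fit; per-grid-point active-set sizes
    are attached as ``fit.path_active_counts``.
    """
    if lambda_grid is None:
        lambda_grid = AnalysisConfig().lambda_grid
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    T = reg.response.size
    lmax = lambda_max(reg)
    z = reg.response
    delta = max(floor_rel * (float(z @ z) + 1e-12),
                noise_floor_mult * T * sigma2_hat)
    best_fit, best_lam, best_score = None, None, np.inf
    b_warm = None
    counts = []
    seen = {}
    state = _SolverState(reg)
    stale = 0
    prev_support = None
    for frac in lambda_grid[::-1]:  # sparse -> dense
        lam = frac * lmax
        fit = group_lasso_fit(reg, lam, b0=b_warm, state=state)
        b_warm = fit._b
        counts.append(len(fit.active))
        support = frozenset(fit.active)
        if support == prev_support:
            continue  # plateau: same model, nothing new to score
        prev_support = support
        # evaluate each support by its unpenalized refit (relaxed group
        # LASSO): shrinkage would otherwise bias selection toward denser
        # models that compensate the penalty
        if support not in seen:
            X = np.hstack([reg.self_block]
                          + [reg.groups[g] for g in fit.active])
            coef, *_ = np.linalg.lstsq(X, z, rcond=None)
            rss = float(np.sum((z - X @ coef) ** 2))
            seen[support] = (rss, X.shape[1])
        rss, df = seen[support]
        pen = df * np.log(T) if criterion == "BIC" else 2.0 * df
        score = T * np.log((rss + delta) / T) + pen
        if score < best_score:
            best_score, best_lam, best_fit = score, lam, fit
            stale = 0
        else:
            stale += 1
            if stale >= 4:  # path truncation: criterion stopped improving
                break

    def score_of(support):
        key = frozenset(support)
        if key not in seen:
            X = np.hstack([reg.self_block] + [reg.groups[g] for g in support])
            coef, *_ = np.linalg.lstsq(X, z, rcond=None)
            rss = float(np.sum((z - X @ coef) ** 2))
            seen[key] = (rss, X.shape[1])
        rss, df = seen[key]
        pen = df * np.log(T) if criterion == "BIC" else 2.0 * df
        return T * np.log((rss + delta) / T) + pen

    # stepwise refinement: the penalized path can visit supersets (a weak
    # group entering before a strong one) or skip a regulator entirely, so
    # greedily drop or admit single groups while the criterion improves
    support = list(best_fit.active)
    for _ in range(2 * len(reg.group_names) + 1):
        moves = [(score_of([h for h in support if h != g]), "drop", g)
                 for g in support]
        moves += [(score_of(support + [g]), "add", g)
                  for g in reg.group_names if g not in support]
        if not moves:
            break
        sc, op, g = min(moves, key=lambda m: m[0])
        if sc >= best_score - 1e-12:
            break
        best_score = sc
        if op == "drop":
            support.remove(g)
        else:
            support.append(g)
    best_fit.support_ = support
    best_fit.path_active_counts = counts  # ascending along the traversal
    return best_lam, best_fit


# ---------------------------------------------------------------------------
# Decomposition and edge extraction
# ---------------------------------------------------------------------------

@dataclass
class ODEDecomposition:
    """One node's trajectory split into independent and dependent parts.

    At every grid point ``overall == independent + sum(dependent.values())``
    exactly; the residual (observed minus overall) is excluded from that
    sum.
    """

    node: Tuple[str, str]
    times: np.ndarray
    overall: np.ndarray
    independent: np.ndarray
    dependent: Dict[Tuple[str, str], np.ndarray]
    residual: np.ndarray


def decompose(reg: RegressorSet, fit: GroupLassoFit) -> ODEDecomposition:
    """Split the fitted response into per-group component curves."""
    independent = reg.anchor + reg.self_block @ fit.coef_self
    dependent = {
        g: reg.groups[g] @ fit.coefs[g] for g in fit.active
    }
    overall = independent + (
        np.sum(list(dependent.values()), axis=0) if dependent else 0.0
    )
    residual = (reg.anchor + reg.response) - overall
    return ODEDecomposition(
        node=reg.node,
        times=reg.times,
        overall=overall,
        independent=independent,
        dependent=dependent,
        residual=residual,
    )


def _edge_sign(dep: np.ndarray, times: np.ndarray) -> int:
    integral = float(np.trapezoid(dep, times))
    tiny = 1e-12 * float(np.max(np.abs(dep)) + 1e-300) * (times[-1] - times[0])
    if integral > tiny:
        return 1
    if integral < -tiny:
        return -1
    # zero net integral: take the sign of the larger-magnitude half,
    # positive on an exact tie
    pos = float(np.trapezoid(np.clip(dep, 0.0, None), times))
    neg = float(np.trapezoid(np.clip(-dep, 0.0, None), times))
    return 1 if pos >= neg - tiny else -1


def extract_edges(
    decomps: Sequence[ODEDecomposition],
    modules: Optional[Dict[Tuple[str, str], str]] = None,
) -> IdopNetwork:
    """Turn active dependent components into a signed, weighted digraph.

    Edge regulator -> focal exists iff the regulator's block is active in
    the focal fit; the sign is that of the time integral of the dependent
    component and the weight its time-averaged absolute value.
    """
    modules = modules or {}
    nodes = [
        NetworkNode(id=d.node[0], layer=d.node[1],
                    module=modules.get(d.node, ""))
        for d in decomps
    ]
    known = {d.node for d in decomps}
    edges: List[NetworkEdge] = []
    for d in decomps:
        span = d.times[-1] - d.times[0]
        for reg_node, dep in d.dependent.items():
            etype = "epistatic" if reg_node[1] == d.node[1] else "pleiotropic"
            edges.append(
                NetworkEdge(
                    source=reg_node[0],
                    target=d.node[0],
                    layer_source=reg_node[1],
                    layer_target=d.node[1],
                    edge_type=etype,
                    sign=_edge_sign(dep, d.times),
                    weight=float(np.trapezoid(np.abs(dep), d.times)) / span,
                )
            )
            if reg_node not in known:
                known.add(reg_node)
                nodes.append(NetworkNode(id=reg_node[0], layer=reg_node[1],
                                         module=modules.get(reg_node, "")))
    net = IdopNetwork(nodes=nodes, edges=edges)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Whole-system inference
# ---------------------------------------------------------------------------

def _infer_nodes(
    curves: Dict[Tuple[str, str], np.ndarray],
    candidate_map: Dict[Tuple[str, str], List[Tuple[str, str]]],
    times: np.ndarray,
    config: AnalysisConfig,
    responses: Optional[Dict[Tuple[str, str], np.ndarray]] = None,
    sparse: bool = True,
    sigma2_hat: Optional[Dict[Tuple[str, str], float]] = None,
):
    decomps = []
    fits = {}
    for node, cand_names in candidate_map.items():
        reg = build_regressors(
            curves[node],
            {c: curves[c] for c in cand_names},
            times,
            config=config,
            node=node,
            response=None if responses is None else responses[node],
        )
        if sparse and cand_names:
            s2 = sigma2_hat.get(node, 0.0) if sigma2_hat else 0.0
            _, sel = select_lambda(reg, config.lambda_grid, config.criterion,
                                   floor_rel=config.rss_floor_rel,
                                   sigma2_hat=s2,
                                   noise_floor_mult=config.noise_floor_mult)
            # debiased component estimates: OLS refit on the selected
            # (backward-pruned) support
            support = getattr(sel, "support_", sel.active)
            reg_red = replace(reg, groups={g: reg.groups[g]
                                           for g in support})
            fit = group_lasso_fit(reg_red, 0.0)
            fits[node] = (reg_red, fit)
            decomps.append(decompose(reg_red, fit))
            continue
        fit = group_lasso_fit(reg, 0.0)
        fits[node] = (reg, fit)
        decomps.append(decompose(reg, fit))
    return decomps, fits


def build_entanglement(
    trait_curves: Dict[str, Dict[str, np.ndarray]],
    times: np.ndarray,
    config: Optional[AnalysisConfig] = None,
    observed: Optional[Dict[str, Dict[str, np.ndarray]]] = None,
    sigma2_hat: Optional[Dict[Tuple[str, str], float]] = None,
) -> Tuple[IdopNetwork, List[ODEDecomposition]]:
    """Two-trait entanglement network over a shared SNP set.

    ``trait_curves[layer][snp_id]`` are genotypic-value curves on a shared
    grid.  For a focal node the candidate regulators are every other SNP in
    its own trait layer (epistatic blocks) plus the same SNP's curve in the
    other layer (one pleiotropic block).  ``observed`` optionally supplies
    raw series used as regression responses while ``trait_curves`` holds
    the (smoothed) regressor curves.
    """
    config = config or AnalysisConfig()
    layers = list(trait_curves)
    snp_sets = [set(trait_curves[l]) for l in layers]
    if len(layers) == 2 and snp_sets[0] != snp_sets[1]:
        raise ValueError("both trait layers must cover the same SNPs")
    curves = {
        (snp, layer): np.asarray(v, dtype=float)
        for layer in layers
        for snp, v in trait_curves[layer].items()
    }
    for v in curves.values():
        if v.shape != np.asarray(times).shape:
            raise ValueError("grid mismatch across traits")
    responses = None
    if observed is not None:
        responses = {
            (snp, layer): np.asarray(observed[layer][snp], dtype=float)
            for layer in layers
            for snp in observed[layer]
        }
    candidate_map = {}
    for snp, layer in curves:
        cands = [(s, layer) for s in trait_curves[layer] if s != snp]
        for other in layers:
            if other != layer and snp in trait_curves[other]:
                cands.append((snp, other))
        candidate_map[(snp, layer)] = cands
    decomps, _ = _infer_nodes(curves, candidate_map, times, config,
                              responses=responses, sigma2_hat=sigma2_hat)
    return extract_edges(decomps), decomps


def decompose_trait_pair(
    trait_a: np.ndarray,
    trait_b: np.ndarray,
    times: np.ndarray,
    config: Optional[AnalysisConfig] = None,
    names: Tuple[str, str] = ("A", "B"),
) -> Tuple[ODEDecomposition, ODEDecomposition]:
    """Two-node systems-mapping special case: each trait's curve is split
    into an independent part and a part dependent on the other trait.  No
    sparsity is needed; both blocks are kept (ordinary least squares)."""
    config = config or AnalysisConfig()
    curves = {
        ("trait", names[0]): np.asarray(trait_a, dtype=float),
        ("trait", names[1]): np.asarray(trait_b, dtype=float),
    }
    candidate_map = {
        ("trait", names[0]): [("trait", names[1])],
        ("trait", names[1]): [("trait", names[0])],
    }
    decomps, _ = _infer_nodes(curves, candidate_map, times, config,
                              sparse=False)
    return decomps[0], decomps[1]


@dataclass
class MultilayerNetwork:
    """Module-level (upper) and SNP-level (lower) network stack."""

    module_network: IdopNetwork
    unit_networks: Dict[str, IdopNetwork]
    membership: Dict[str, str]  # snp id -> module path


def build_multilayer(
    curves: Dict[str, np.ndarray],
    hierarchy,
    times: np.ndarray,
    config: Optional[AnalysisConfig] = None,
    layer: str = "trait",
) -> MultilayerNetwork:
    """Assemble a two-level network from a module hierarchy.

    The upper layer runs the same regressor / group-LASSO machinery on the
    module mean curves (one node per leaf module); the lower layer is one
    network per leaf with candidate regulators restricted to that unit.
    """
    config = config or AnalysisConfig()
    membership = hierarchy.leaf_paths()
    leaves = hierarchy.leaves()
    module_curves = {}
    for node in leaves:
        path = membership[node.ids[0]]
        module_curves[f"module:{path}"] = np.mean(
            [curves[i] for i in node.ids], axis=0
        )
    mod_nodes = {(m, layer): v for m, v in module_curves.items()}
    cand_map = {
        n: [o for o in mod_nodes if o != n] for n in mod_nodes
    }
    decomps, _ = _infer_nodes(mod_nodes, cand_map, times, config)
    module_net = extract_edges(decomps)

    unit_networks = {}
    for node in leaves:
        path = membership[node.ids[0]]
        unit_curves = {(i, layer): np.asarray(curves[i], dtype=float)
                       for i in node.ids}
        cmap = {n: [o for o in unit_curves if o != n] for n in unit_curves}
        d, _ = _infer_nodes(unit_curves, cmap, times, config)
        unit_networks[path] = extract_edges(
            d, modules={n: path for n in unit_curves}
        )
    return MultilayerNetwork(
        module_network=module_net,
        unit_networks=unit_networks,
        membership=membership,
    )


class MixedODENetwork(BaseEstimator):
    """Entanglement-network inference as a fit-shaped estimator.

    ``fit(X, nodes=..., times=...)`` takes an (n_nodes, T) array of
    trajectories and a list of (snp_id, layer) node labels; candidates are
    all other nodes in the same layer plus the same SNP in the other
    layer.  With ``smooth=True`` each series is denoised by BIC-selected
    Legendre least squares before entering the design (the raw series
    remains the regression response).
    """

    def __init__(
        self,
        lop_order_independent: int = 2,
        lop_order_dependent: int = 1,
        independent_form: str = "logistic",
        lambda_grid: Optional[np.ndarray] = None,
        criterion: str = "BIC",
        smooth: bool = True,
    ):
        self.lop_order_independent = lop_order_independent
        self.lop_order_dependent = lop_order_dependent
        self.independent_form = independent_form
        self.lambda_grid = lambda_grid
        self.criterion = criterion
        self.smooth = smooth

    def fit(self, X: np.ndarray, nodes: Sequence[Tuple[str, str]],
            times: Optional[np.ndarray] = None):
        X = np.asarray(X, dtype=float)
        times = (np.asarray(times, dtype=float) if times is not None
                 else np.arange(X.shape[1], dtype=float))
        config = AnalysisConfig(
            lop_order_independent=self.lop_order_independent,
            lop_order_dependent=self.lop_order_dependent,
            independent_form=self.independent_form,
            lambda_grid=(self.lambda_grid if self.lambda_grid is not None
                         else AnalysisConfig().lambda_grid),
            criterion=self.criterion,
        )
        layers = list(dict.fromkeys(l for _, l in nodes))
        trait_curves: Dict[str, Dict[str, np.ndarray]] = {l: {} for l in layers}
        observed: Dict[str, Dict[str, np.ndarray]] = {l: {} for l in layers}
        sigma2_hat: Dict[Tuple[str, str], float] = {}
        for (snp, layer), row in zip(nodes, X):
            observed[layer][snp] = row
            if self.smooth:
                fitted, s2 = smooth_series(row, times, return_noise=True)
                trait_curves[layer][snp] = fitted
                sigma2_hat[(snp, layer)] = s2
            else:
                trait_curves[layer][snp] = row
        net, decomps = build_entanglement(
            trait_curves, times, config,
            observed=observed if self.smooth else None,
            sigma2_hat=sigma2_hat if self.smooth else None,
        )
        self.network_ = net
        self.decompositions_ = decomps
        self.times_ = times
        return self
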