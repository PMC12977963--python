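"""Functional clustering of genotypic-value curves into modules.

A finite mixture over curves: each cluster k has prior pi_k and a
longitudinal normal density whose mean is a logistic growth curve (per
trait) and whose covariance is a shared SAD(1) structure (plus an
innovation cross-correlation when two traits are clustered jointly, by
concatenating the trait curves).  Estimation is a hybrid EM: posteriors
and priors in closed form, mean/covariance parameters by Nelder--Mead on
the expected complete-data log-likelihood with the innovation covariance
profiled out, which makes every EM sweep a generalized (monotone) M-step.

Model size is chosen by AIC/BIC; a bottom-up recursion re-clusters every
module larger than ``unit_size`` into submodules until units are small or
a single cluster is preferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .basis import LogisticParams, SAD1Params, _logistic_values, sad1_whiten
from .io import AnalysisConfig

logger = logging.getLogger("idopnet")

__all__ = [
    "CurveClusterer",
    "ModuleNode",
    "ModuleHierarchy",
    "fit_mixture",
    "select_k",
    "assign_modules",
    "recursive_partition",
]

_LOG2PI = np.log(2.0 * np.pi)


def _split_traits(X: np.ndarray, n_traits: int) -> List[np.ndarray]:
    T = X.shape[1] // n_traits
    return [X[:, i * T : (i + 1) * T] for i in range(n_traits)]


class CurveClusterer(BaseEstimator):
    """Mixture-model clustering of growth curves with SAD(1) covariance.

    Parameters
    ----------
    n_clusters : int
        Number of mixture components K.
    n_traits : int
        1 for single-trait curves, 2 for concatenated two-trait curves.
    max_iter, tol : EM stopping rule (relative log-likelihood change).
    init : 'kmeans' or 'random' hard-label initialization.
    random_state : seed for initialization and restart perturbations.

    Attributes (after fit)
    ----------------------
    weights_ : mixture priors pi_k.
    posterior_ : (n_curves, K) responsibility matrix.
    labels_ : hard assignments (argmax posterior, ties -> lowest index).
    cluster_curves_ : (K, n_features) fitted mean curves.
    log_likelihood_, loglik_path_, aic_, bic_, n_params_.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        n_traits: int = 1,
        max_iter: int = 50,
        tol: float = 1e-6,
        init: str = "kmeans",
        random_state: int = 0,
        nm_maxiter: int = 200,
    ):
        self.n_clusters = n_clusters
        self.n_traits = n_traits
        self.max_iter = max_iter
        self.tol = tol
        self.init = init
        self.random_state = random_state
        self.nm_maxiter = nm_maxiter

    # -- internal likelihood machinery ------------------------------------

    def _unpack(self, theta: np.ndarray):
        K, d = self.n_clusters, self.n_traits
        curves = theta[: K * d * 3].reshape(d, K, 3)
        phis = theta[K * d * 3 :]
        return curves, phis

    def _mean_curves(self, theta: np.ndarray) -> List[np.ndarray]:
        curves, _ = self._unpack(theta)
        mus = []
        for tr in range(self.n_traits):
            mu = np.empty((self.n_clusters, self._T))
            for k in range(self.n_clusters):
                la, lb, lr = curves[tr, k]
                mu[k] = _logistic_values(
                    np.exp(la), np.exp(lb), np.exp(lr), self._times
                )
            mus.append(mu)
        return mus

    def _innovations(self, theta: np.ndarray, Ys: List[np.ndarray]):
        """Per-trait innovation arrays of shape (K, n, T)."""
        mus = self._mean_curves(theta)
        _, phis = self._unpack(theta)
        out = []
        for tr in range(self.n_traits):
            resid = Ys[tr][None, :, :] - mus[tr][:, None, :]
            out.append(sad1_whiten(resid, phis[tr]))
        return out

    def _profiled_q(self, theta: np.ndarray, Ys: List[np.ndarray],
                    resp: np.ndarray) -> float:
        """Expected complete-data log-likelihood, innovation cov profiled."""
        innov = self._innovations(theta, Ys)
        N = resp.sum()
        T, d = self._T, self.n_traits
        w = resp.T  # (K, n)
        if d == 1:
            e = innov[0]
            nu2 = float(np.sum(w[:, :, None] * e * e)) / (N * T)
            if not np.isfinite(nu2) or nu2 <= 0:
                return -np.inf
            return -0.5 * N * T * (_LOG2PI + np.log(nu2) + 1.0)
        ea, eb = innov
        k11 = float(np.sum(w[:, :, None] * ea * ea)) / (N * T)
        k22 = float(np.sum(w[:, :, None] * eb * eb)) / (N * T)
        k12 = float(np.sum(w[:, :, None] * ea * eb)) / (N * T)
        det = k11 * k22 - k12 * k12
        if not np.isfinite(det) or det <= 0:
            return -np.inf
        return -N * T * (_LOG2PI + 1.0) - 0.5 * N * T * np.log(det)

    def _profiled_cov(self, theta: np.ndarray, Ys: List[np.ndarray],
                      resp: np.ndarray):
        innov = self._innovations(theta, Ys)
        N = resp.sum()
        T = self._T
        w = resp.T
        if self.n_traits == 1:
            nu2 = float(np.sum(w[:, :, None] * innov[0] ** 2)) / (N * T)
            return np.array([[nu2]])
        ea, eb = innov
        k11 = float(np.sum(w[:, :, None] * ea * ea)) / (N * T)
        k22 = float(np.sum(w[:, :, None] * eb * eb)) / (N * T)
        k12 = float(np.sum(w[:, :, None] * ea * eb)) / (N * T)
        return np.array([[k11, k12], [k12, k22]])

    def _log_densities(self, theta: np.ndarray, Kmat: np.ndarray,
                       Ys: List[np.ndarray]) -> np.ndarray:
        """(n, K) matrix of per-cluster log densities."""
        innov = self._innovations(theta, Ys)
        T, d = self._T, self.n_traits
        if d == 1:
            nu2 = Kmat[0, 0]
            quad = np.sum(innov[0] ** 2, axis=2) / nu2  # (K, n)
            logdet = T * np.log(nu2)
        else:
            Kinv = np.linalg.inv(Kmat)
            ea, eb = innov
            quad = (
                Kinv[0, 0] * np.sum(ea * ea, axis=2)
                + Kinv[1, 1] * np.sum(eb * eb, axis=2)
                + 2 * Kinv[0, 1] * np.sum(ea * eb, axis=2)
            )
            logdet = T * float(np.log(np.linalg.det(Kmat)))
        return (-0.5 * (T * d * _LOG2PI + logdet + quad)).T  # (n, K)

    # -- EM ----------------------------------------------------------------

    def _init_theta(self, Ys: List[np.ndarray], labels: np.ndarray) -> np.ndarray:
        from .funmap import _moment_start

        theta = []
        for tr in range(self.n_traits):
            for k in range(self.n_clusters):
                mask = labels == k
                ybar = (Ys[tr][mask].mean(axis=0) if mask.any()
                        else Ys[tr].mean(axis=0))
                p = _moment_start(ybar, self._times)
                theta.extend([np.log(p.a), np.log(p.b), np.log(p.r)])
        theta.extend([0.3] * self.n_traits)
        return np.array(theta)

    def fit(self, X: np.ndarray, times: Optional[np.ndarray] = None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        K = self.n_clusters
        if K > n:
            raise ValueError(f"n_clusters={K} exceeds number of curves {n}")
        self._T = X.shape[1] // self.n_traits
        self._times = (np.asarray(times, dtype=float) if times is not None
                       else np.arange(self._T, dtype=float))
        Ys = _split_traits(X, self.n_traits)
        rng = np.random.default_rng(self.random_state)

        if K == 1:
            labels = np.zeros(n, dtype=int)
        elif self.init == "kmeans":
            labels = KMeans(
                n_clusters=K, n_init=10, random_state=self.random_state
            ).fit_predict(X)
        else:
            labels = rng.integers(0, K, size=n)
            for k in range(K):  # guarantee non-empty init clusters
                if not np.any(labels == k):
                    labels[rng.integers(0, n)] = k

        theta = self._init_theta(Ys, labels)
        resp = np.zeros((n, K))
        resp[np.arange(n), labels] = 1.0
        weights = resp.mean(axis=0)

        # initial M-step from hard labels
        theta = self._m_step(theta, Ys, resp)
        Kmat = self._profiled_cov(theta, Ys, resp)

        path: List[float] = []
        prev = -np.inf
        for it in range(self.max_iter):
            # E-step
            logdens = self._log_densities(theta, Kmat, Ys)
            logw = np.log(np.clip(weights, 1e-300, None))
            joint = logdens + logw[None, :]
            ll = float(np.sum(logsumexp(joint, axis=1)))
            resp = np.exp(joint - logsumexp(joint, axis=1)[:, None])
            path.append(ll)
            if it > 0 and abs(ll - prev) <= self.tol * (abs(prev) + 1.0):
                prev = ll
                break
            prev = ll
            # empty-cluster rescue: reseed from the farthest curve
            col = resp.sum(axis=0)
            for k in np.where(col < 1e-8 * n)[0]:
                logger.warning("cluster %d emptied; reseeding", k)
                far = int(np.argmax(np.min(
                    ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1), axis=1)))
                resp[:, k] = 0.0
                resp[far] = 0.0
                resp[far, k] = 1.0
                resp /= resp.sum(axis=1, keepdims=True)
            # M-step
            weights = resp.mean(axis=0)
            theta = self._m_step(theta, Ys, resp)
            Kmat = self._profiled_cov(theta, Ys, resp)

        self.loglik_path_ = np.array(path)
        self.log_likelihood_ = prev
        self.weights_ = weights
        self.posterior_ = resp
        self.labels_ = assign_modules(self)
        self._theta = theta
        self._Kmat = Kmat
        curves, phis = self._unpack(theta)
        self.cluster_params_ = {
            tr: {
                k: LogisticParams(*np.exp(curves[tr, k]))
                for k in range(K)
            }
            for tr in range(self.n_traits)
        }
        rho = None
        if self.n_traits == 2:
            rho = float(Kmat[0, 1] / np.sqrt(Kmat[0, 0] * Kmat[1, 1]))
        self.sad_params_ = [
            SAD1Params(phi=float(phis[tr]), nu2=float(Kmat[tr, tr]), rho=rho)
            for tr in range(self.n_traits)
        ]
        mus = self._mean_curves(theta)
        self.cluster_curves_ = np.hstack(mus) if self.n_traits > 1 else mus[0]
        d = self.n_traits
        self.n_params_ = (K - 1) + K * 3 * d + 2 * d + (1 if d == 2 else 0)
        self.aic_ = -2.0 * prev + 2.0 * self.n_params_
        self.bic_ = -2.0 * prev + self.n_params_ * np.log(n)
        return self

    def _m_step(self, theta: np.ndarray, Ys, resp: np.ndarray) -> np.ndarray:
        # Nelder-Mead started at the current parameters: the returned point
        # is at least as good as the start, so EM never decreases.
        res = minimize(
            lambda t: -self._profiled_q(t, Ys, resp),
            theta,
            method="Nelder-Mead",
            options={"maxiter": self.nm_maxiter, "fatol": 1e-9, "xatol": 1e-6},
        )
        return res.x if -res.fun >= self._profiled_q(theta, Ys, resp) else theta

    def predict(self, X: np.ndarray) -> np.ndarray:
        Ys = _split_traits(np.asarray(X, dtype=float), self.n_traits)
        logdens = self._log_densities(self._theta, self._Kmat, Ys)
        joint = logdens + np.log(np.clip(self.weights_, 1e-300, None))
        return np.argmax(joint, axis=1)


def fit_mixture(
    X: np.ndarray,
    K: int,
    config: AnalysisConfig,
    times: Optional[np.ndarray] = None,
    n_traits: int = 1,
    init: str = "kmeans",
) -> CurveClusterer:
    """Fit a K-component curve mixture (thin wrapper over CurveClusterer)."""
    model = CurveClusterer(
        n_clusters=K,
        n_traits=n_traits,
        max_iter=config.em_max_iter,
        tol=config.em_tol,
        init=init,
        random_state=config.seed,
    )
    return model.fit(X, times=times)


def assign_modules(model: CurveClusterer) -> np.ndarray:
    """Hard assignments: argmax posterior per row, ties to the lowest index."""
    return np.argmax(model.posterior_, axis=1)


def select_k(
    X: np.ndarray,
    k_range: Sequence[int],
    config: AnalysisConfig,
    times: Optional[np.ndarray] = None,
    n_traits: int = 1,
) -> CurveClusterer:
    """Fit each K in k_range, return the AIC/BIC minimizer (ties: smallest K)."""
    if len(k_range) == 0:
        raise ValueError("k_range must be nonempty")
    best = None
    best_score = np.inf
    for K in sorted(k_range):
        if K > X.shape[0]:
            continue
        model = fit_mixture(X, K, config, times=times, n_traits=n_traits)
        score = model.bic_ if config.criterion == "BIC" else model.aic_
        if score < best_score:
            best_score = score
            best = model
    return best


@dataclass
class ModuleNode:
    ids: List[str]
    children: List["ModuleNode"] = field(default_factory=list)
    model: Optional[CurveClusterer] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ModuleHierarchy:
    """Tree of recursive module partitions; leaves partition the SNP set."""

    root: ModuleNode

    def leaves(self) -> List[ModuleNode]:
        out: List[ModuleNode] = []

        def walk(node: ModuleNode):
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_paths(self) -> Dict[str, str]:
        """Map each id to its dotted path through the tree, e.g. '0.2'."""
        paths: Dict[str, str] = {}

        def walk(node: ModuleNode, prefix: str):
            if node.is_leaf:
                for i in node.ids:
                    paths[i] = prefix or "0"
                return
            for j, c in enumerate(node.children):
                walk(c, f"{prefix}.{j}" if prefix else str(j))

        walk(self.root, "")
        return paths


def recursive_partition(
    X: np.ndarray,
    ids: Sequence[str],
    config: AnalysisConfig,
    times: Optional[np.ndarray] = None,
    n_traits: int = 1,
) -> ModuleHierarchy:
    """Bottom-up module detection: re-cluster units until each is small.

    A unit is accepted as a leaf when it has at most ``unit_size`` members,
    when model selection prefers a single cluster, or when a proposed split
    fails to strictly reduce the unit (termination guard).
    """
    if config.unit_size < 2:
        raise ValueError("unit_size must be >= 2")
    ids = list(ids)

    def build(sub_idx: np.ndarray) -> ModuleNode:
        node = ModuleNode(ids=[ids[i] for i in sub_idx])
        if sub_idx.size <= config.unit_size:
            return node
        k_range = [k for k in config.k_range if k <= sub_idx.size]
        model = select_k(X[sub_idx], k_range, config, times=times,
                         n_traits=n_traits)
        if model is None or model.n_clusters == 1:
            return node
        labels = model.labels_
        groups = [sub_idx[labels == k] for k in range(model.n_clusters)]
        groups = [g for g in groups if g.size > 0]
        if len(groups) < 2:
            return node  # degenerate split: accept as leaf
        node.model = model
        node.children = [build(g) for g in groups]
        return node

    return ModuleHierarchy(root=build(np.arange(len(ids))))
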