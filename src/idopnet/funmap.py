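"""Functional mapping (FunMap) of growth trajectories.

Each SNP partitions the mapping population into genotype classes; every
class gets its own logistic mean curve per trait while all classes share a
SAD(1) longitudinal covariance (with an innovation cross-correlation when
two traits are fitted jointly).  The likelihood-ratio statistic against a
pooled single-curve null, thresholded by permutation, flags QTLs, and each
individual then inherits the fitted curve of the genotype class it carries
-- its time-varying genotypic values, the raw material for network
inference.

The innovation covariance is profiled out analytically, so Nelder--Mead
only searches the logistic parameters (on log scale) and the
antedependence coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .basis import LogisticParams, SAD1Params, _logistic_values, sad1_whiten
from .io import MISSING, AnalysisConfig, GenotypeMatrix, PhenotypePanel

logger = logging.getLogger("idopnet")

__all__ = [
    "SnpFit",
    "QtlScan",
    "GenotypicCurve",
    "fit_snp",
    "lr_scan",
    "permutation_threshold",
    "assign_genotypic_values",
    "FunMapScanner",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class SnpFit:
    """Converged genotype-partitioned growth-curve fit at one SNP."""

    snp_id: str
    class_codes: List[int]
    curve_params: Dict[str, Dict[int, LogisticParams]]  # trait -> code -> params
    sad_params: Dict[str, SAD1Params]  # trait -> (phi, nu2)
    rho: Optional[float]
    log_likelihood: float
    n_per_class: Dict[int, int]
    individuals_used: np.ndarray  # indices into the panel


@dataclass
class QtlScan:
    snp_ids: List[str]
    lr: np.ndarray
    threshold: Optional[float] = None
    significant: Optional[np.ndarray] = None


@dataclass
class GenotypicCurve:
    """Time-indexed genotypic values of one genotype at one SNP, one trait."""

    snp_id: str
    genotype: str
    trait: str
    times: np.ndarray
    values: np.ndarray
    individual_id: Optional[str] = None


# ---------------------------------------------------------------------------
# Profiled likelihood
# ---------------------------------------------------------------------------

def _pack_theta(curve0: Dict[str, List[LogisticParams]], phi0: Dict[str, float]):
    theta = []
    for trait, plist in curve0.items():
        for p in plist:
            theta.extend([np.log(p.a), np.log(p.b), np.log(p.r)])
    for trait in curve0:
        theta.append(phi0[trait])
    return np.array(theta)


def _profiled_loglik(
    theta: np.ndarray,
    Y: Dict[str, np.ndarray],
    class_masks: List[np.ndarray],
    times: np.ndarray,
) -> float:
    """Log-likelihood with the innovation covariance profiled out.

    Each genotype class has its own logistic mean curve per trait; the
    SAD(1) innovation variance (and, for two traits, the 2x2 innovation
    covariance including the cross-correlation) is replaced by its
    conditional MLE in closed form.
    """
    traits = list(Y)
    n_classes = len(class_masks)
    n = next(iter(Y.values())).shape[0]
    T = times.size
    k = 0
    innov = {}
    for trait in traits:
        mu = np.empty((n_classes, T))
        for c in range(n_classes):
            la, lb, lr = theta[k : k + 3]
            k += 3
            mu[c] = _logistic_values(np.exp(la), np.exp(lb), np.exp(lr), times)
        resid = np.empty_like(Y[trait])
        for c, mask in enumerate(class_masks):
            resid[mask] = Y[trait][mask] - mu[c]
        innov[trait] = resid  # whitened below once phi is known
    phis = theta[k : k + len(traits)]
    for trait, phi in zip(traits, phis):
        innov[trait] = sad1_whiten(innov[trait], phi)

    if len(traits) == 1:
        e = innov[traits[0]]
        nu2 = float(np.mean(e * e))
        if not np.isfinite(nu2) or nu2 <= 0:
            return -np.inf
        return -0.5 * n * T * (_LOG2PI + np.log(nu2) + 1.0)
    # bivariate: MLE of the stacked 2x2 innovation covariance
    ea = innov[traits[0]].ravel()
    eb = innov[traits[1]].ravel()
    m = ea.size
    k11 = float(ea @ ea) / m
    k22 = float(eb @ eb) / m
    k12 = float(ea @ eb) / m
    det = k11 * k22 - k12 * k12
    if not np.isfinite(det) or det <= 0:
        return -np.inf
    return -n * T * (_LOG2PI + 1.0) - 0.5 * n * T * np.log(det)


def _innovation_mles(theta, Y, class_masks, times):
    """Recover the profiled (nu2 per trait, rho) at the optimum."""
    traits = list(Y)
    n_classes = len(class_masks)
    T = times.size
    k = 0
    innov = {}
    for trait in traits:
        mu = np.empty((n_classes, T))
        for c in range(n_classes):
            la, lb, lr = theta[k : k + 3]
            k += 3
            mu[c] = _logistic_values(np.exp(la), np.exp(lb), np.exp(lr), times)
        resid = np.empty_like(Y[trait])
        for c, mask in enumerate(class_masks):
            resid[mask] = Y[trait][mask] - mu[c]
        innov[trait] = resid
    phis = theta[k : k + len(traits)]
    for trait, phi in zip(traits, phis):
        innov[trait] = sad1_whiten(innov[trait], phi)
    nu2 = {t: float(np.mean(innov[t] ** 2)) for t in traits}
    rho = None
    if len(traits) == 2:
        ea, eb = innov[traits[0]].ravel(), innov[traits[1]].ravel()
        rho = float(np.mean(ea * eb) / np.sqrt(nu2[traits[0]] * nu2[traits[1]]))
    return nu2, dict(zip(traits, phis)), rho


def _moment_start(ybar: np.ndarray, times: np.ndarray) -> LogisticParams:
    """Crude logistic start from a class-mean curve."""
    a0 = 1.05 * float(np.nanmax(ybar))
    a0 = max(a0, 1e-6)
    y0 = float(np.clip(ybar[0], 1e-3 * a0, 0.95 * a0))
    b0 = float(np.clip(a0 / y0 - 1.0, 0.05, 500.0))
    # slope of log(a0/y - 1) vs t gives -r
    w = np.log(np.clip(a0 / np.clip(ybar, 1e-3 * a0, 0.999 * a0) - 1.0, 1e-8, None))
    slope = np.polyfit(times, w, 1)[0]
    r0 = float(np.clip(-slope, 1e-3, 5.0))
    return LogisticParams(a=a0, b=b0, r=r0)


def _fit_partition(
    Y: Dict[str, np.ndarray],
    class_masks: List[np.ndarray],
    times: np.ndarray,
    seed: int,
    restarts: int = 3,
    maxiter: int = 2000,
):
    """Maximize the profiled likelihood for a fixed class partition."""
    traits = list(Y)
    starts = {
        trait: [
            _moment_start(np.nanmean(Y[trait][mask], axis=0), times)
            for mask in class_masks
        ]
        for trait in traits
    }
    phi0 = {trait: 0.5 for trait in traits}
    theta0 = _pack_theta(starts, phi0)
    rng = np.random.default_rng(seed)
    best_theta, best_ll = None, -np.inf
    for s in range(restarts):
        th = theta0 if s == 0 else theta0 + rng.normal(0.0, 0.1, theta0.size)
        res = minimize(
            lambda t: -_profiled_loglik(t, Y, class_masks, times),
            th,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "fatol": 1e-7, "xatol": 1e-5},
        )
        if -res.fun > best_ll:
            best_ll, best_theta = -res.fun, res.x
    return best_theta, best_ll


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _complete_rows(panel: PhenotypePanel, traits: Sequence[str]) -> np.ndarray:
    ok = np.ones(len(panel.individuals), dtype=bool)
    for t in traits:
        ok &= ~np.isnan(panel.values[t]).any(axis=1)
    return ok


def fit_snp(
    geno_row: np.ndarray,
    panel: PhenotypePanel,
    config: AnalysisConfig,
    snp_id: str = "",
    min_class_size: int = 3,
    on_small_class: str = "skip",
    seed: Optional[int] = None,
) -> Optional[SnpFit]:
    """Fit the genotype-partitioned growth model at one SNP.

    Individuals with a missing genotype, or missing phenotype time points,
    are excluded from this SNP's likelihood.  A genotype class smaller than
    ``min_class_size`` either causes the SNP to be skipped (default) or is
    merged into the nearest class (``on_small_class='merge'``).
    """
    traits = panel.traits
    times = panel.times[traits[0]]
    usable = _complete_rows(panel, traits) & (np.asarray(geno_row) != MISSING)
    codes = np.asarray(geno_row)[usable]
    observed = list(np.unique(codes))
    counts = {c: int(np.sum(codes == c)) for c in observed}
    small = [c for c in observed if counts[c] < min_class_size]
    if small:
        if on_small_class == "merge" and len(observed) - len(small) >= 1:
            logger.warning("%s: merging small class(es) %s", snp_id, small)
            keep = [c for c in observed if counts[c] >= min_class_size]
            remap = {c: min(keep, key=lambda k: abs(k - c)) for c in small}
            codes = np.array([remap.get(c, c) for c in codes])
            observed = list(np.unique(codes))
        else:
            logger.warning("%s: class(es) %s below %d individuals; skipped",
                           snp_id, small, min_class_size)
            return None
    if len(observed) < 2:
        logger.warning("%s: fewer than two usable genotype classes; skipped", snp_id)
        return None

    Y = {t: panel.values[t][usable] for t in traits}
    masks = [codes == c for c in observed]
    if seed is None:
        seed = config.seed
    theta, ll = _fit_partition(Y, masks, times, seed=seed)
    nu2, phis, rho = _innovation_mles(theta, Y, masks, times)
    curve_params: Dict[str, Dict[int, LogisticParams]] = {}
    k = 0
    for trait in traits:
        curve_params[trait] = {}
        for c in observed:
            la, lb, lr = theta[k : k + 3]
            k += 3
            curve_params[trait][c] = LogisticParams(
                a=float(np.exp(la)), b=float(np.exp(lb)), r=float(np.exp(lr))
            )
    sad = {t: SAD1Params(phi=float(phis[t]), nu2=nu2[t], rho=rho) for t in traits}
    return SnpFit(
        snp_id=snp_id,
        class_codes=[int(c) for c in observed],
        curve_params=curve_params,
        sad_params=sad,
        rho=rho,
        log_likelihood=float(ll),
        n_per_class={int(c): counts.get(c, int(np.sum(codes == c))) for c in observed},
        individuals_used=np.where(usable)[0],
    )


def fit_null(
    panel: PhenotypePanel,
    config: AnalysisConfig,
    subset: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
):
    """Pooled single-curve-per-trait null model; returns its log-likelihood."""
    traits = panel.traits
    times = panel.times[traits[0]]
    usable = _complete_rows(panel, traits)
    if subset is not None:
        mask = np.zeros_like(usable)
        mask[subset] = True
        usable &= mask
    Y = {t: panel.values[t][usable] for t in traits}
    masks = [np.ones(next(iter(Y.values())).shape[0], dtype=bool)]
    if seed is None:
        seed = config.seed
    _, ll = _fit_partition(Y, masks, times, seed=seed)
    return float(ll)


def lr_scan(
    genotypes: GenotypeMatrix,
    panel: PhenotypePanel,
    config: AnalysisConfig,
    _null_ll: Optional[float] = None,
) -> QtlScan:
    """Likelihood-ratio scan LR_s = 2(l_full,s - l_null) across all SNPs.

    The pooled null is fitted once per dataset; for SNPs with missing
    genotypes it is refitted on that SNP's usable individuals so the
    nested-model inequality holds exactly.
    """
    if _null_ll is None:
        _null_ll = fit_null(panel, config)
    usable_all = _complete_rows(panel, panel.traits)
    lrs = np.full(len(genotypes.snps), np.nan)
    fits: List[Optional[SnpFit]] = []
    for i, snp in enumerate(genotypes.snps):
        row = genotypes.codes[i]
        f = fit_snp(row, panel, config, snp_id=snp.snp_id,
                    seed=config.seed + 17 * i)
        fits.append(f)
        if f is None:
            continue
        if np.array_equal(f.individuals_used, np.where(usable_all)[0]):
            null_ll = _null_ll
        else:
            null_ll = fit_null(panel, config, subset=f.individuals_used)
        lrs[i] = 2.0 * (f.log_likelihood - null_ll)
    scan = QtlScan(snp_ids=genotypes.snp_ids, lr=lrs)
    scan.fits = fits  # type: ignore[attr-defined]
    return scan


def permutation_threshold(
    genotypes: GenotypeMatrix,
    panel: PhenotypePanel,
    config: AnalysisConfig,
) -> float:
    """Genome-wide max-LR permutation threshold at level alpha.

    Whole phenotype vectors are permuted against genotypes (preserving
    within-individual longitudinal structure); the (1 - alpha) empirical
    quantile of the per-permutation maximum LR is returned.  Individuals
    are ordered canonically by id first, so the result does not depend on
    input row order.
    """
    if not 0 < config.alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    order = np.argsort(np.asarray(panel.individuals, dtype=object))
    canon = PhenotypePanel(
        individuals=[panel.individuals[i] for i in order],
        times=panel.times,
        values={t: v[order] for t, v in panel.values.items()},
    )
    geno_canon = GenotypeMatrix(
        snps=genotypes.snps,
        individuals=[genotypes.individuals[i] for i in order],
        codes=genotypes.codes[:, order],
    )
    null_ll = fit_null(canon, config)
    rng = np.random.default_rng(config.seed)
    n = len(canon.individuals)
    max_lrs = np.empty(config.n_permutations)
    for b in range(config.n_permutations):
        perm = rng.permutation(n)
        permuted = PhenotypePanel(
            individuals=canon.individuals,
            times=canon.times,
            values={t: v[perm] for t, v in canon.values.items()},
        )
        scan = lr_scan(geno_canon, permuted, config, _null_ll=null_ll)
        max_lrs[b] = np.nanmax(scan.lr)
    return float(np.quantile(max_lrs, 1.0 - config.alpha))


def assign_genotypic_values(
    fit: SnpFit,
    genotypes: GenotypeMatrix,
    panel: PhenotypePanel,
) -> List[GenotypicCurve]:
    """Assign each individual the fitted curve of the genotype it carries."""
    i = genotypes.snp_ids.index(fit.snp_id)
    row = genotypes.codes[i]
    out: List[GenotypicCurve] = []
    for trait in fit.curve_params:
        times = panel.times[trait]
        class_curves = {
            c: _logistic_values(p.a, p.b, p.r, times)
            for c, p in fit.curve_params[trait].items()
        }
        for j, ind in enumerate(genotypes.individuals):
            code = row[j]
            if code == MISSING or code not in class_curves:
                continue
            out.append(
                GenotypicCurve(
                    snp_id=fit.snp_id,
                    genotype=str(code),
                    trait=trait,
                    times=times,
                    values=class_curves[code].copy(),
                    individual_id=ind,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class FunMapScanner(BaseEstimator):
    """Genome-wide functional-mapping scan as a fit-shaped estimator.

    Parameters mirror :class:`AnalysisConfig`; after ``fit`` the object
    exposes ``scan_`` (per-SNP LR), ``threshold_``, ``significant_`` and
    the per-SNP fits in ``fits_``.
    """

    def __init__(self, n_permutations: int = 100, alpha: float = 0.05,
                 seed: int = 0, compute_threshold: bool = True):
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.seed = seed
        self.compute_threshold = compute_threshold

    def fit(self, genotypes: GenotypeMatrix, panel: PhenotypePanel):
        config = AnalysisConfig(
            n_permutations=self.n_permutations, alpha=self.alpha, seed=self.seed
        )
        scan = lr_scan(genotypes, panel, config)
        if self.compute_threshold:
            scan.threshold = permutation_threshold(genotypes, panel, config)
            scan.significant = scan.lr > scan.threshold
        self.scan_ = scan
        self.fits_ = scan.fits  # type: ignore[attr-defined]
        self.genotypes_ = genotypes
        self.panel_ = panel
        return self

    def genotypic_curves(self, snp_id: str) -> List[GenotypicCurve]:
        i = self.genotypes_.snp_ids.index(snp_id)
        f = self.fits_[i]
        if f is None:
            raise ValueError(f"SNP {snp_id} was not fitted")
        return assign_genotypic_values(f, self.genotypes_, self.panel_)
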