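"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from idopnet.basis import LogisticParams, _logistic_values, sad1_whiten
from idopnet.io import GenotypeMatrix, PhenotypePanel, SnpRecord


def sad1_noise(rng, n, T, phi, nu2):
    """Draw SAD(1) residual series: z_j = phi z_{j-1} + eps_j."""
    eps = rng.normal(0.0, np.sqrt(nu2), (n, T))
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    for j in range(1, T):
        z[:, j] = phi * z[:, j - 1] + eps[:, j]
    return z


def make_mapping_data(
    n=40,
    T=11,
    sigma2=0.25,
    phi=0.4,
    n_null_snps=0,
    effect=(LogisticParams(10.0, 9.0, 0.5), LogisticParams(14.0, 9.0, 0.5)),
    seed=0,
    trait="HT",
):
    """One QTL (testcross, codes 0/1) plus optional null SNPs.

    Phenotypes follow the genotype-specific logistic curve of the QTL with
    SAD(1) residuals; null SNP codes are independent of phenotype.
    """
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, 20.0, T)
    codes_qtl = rng.permutation(np.repeat([0, 1], n // 2))
    curves = {c: _logistic_values(p.a, p.b, p.r, times)
              for c, p in enumerate(effect)}
    Y = np.vstack([curves[c] for c in codes_qtl])
    Y = Y + sad1_noise(rng, n, T, phi, sigma2)
    individuals = [f"i{k}" for k in range(n)]
    snps = [SnpRecord("qtl", "1", 1000, "testcross")]
    rows = [codes_qtl]
    for j in range(n_null_snps):
        snps.append(SnpRecord(f"null{j}", "1", 2000 + j, "testcross"))
        rows.append(rng.permutation(np.repeat([0, 1], n // 2)))
    genotypes = GenotypeMatrix(
        snps=snps, individuals=individuals, codes=np.vstack(rows)
    )
    panel = PhenotypePanel(
        individuals=individuals, times={trait: times}, values={trait: Y}
    )
    return genotypes, panel


def make_curve_groups(n_per_group, asymptotes, T=11, sigma2=0.25, phi=0.3,
                      seed=0, b=9.0, r=0.5):
    """Curve sets drawn around logistic group means with SAD(1) noise."""
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, 20.0, T)
    X, labels = [], []
    for g, a in enumerate(asymptotes):
        mean = _logistic_values(a, b, r, times)
        X.append(mean + sad1_noise(rng, n_per_group, T, phi, sigma2))
        labels += [g] * n_per_group
    return np.vstack(X), np.array(labels), times


@pytest.fixture
def mapping_data():
    return make_mapping_data(seed=1)


@pytest.fixture
def curve_groups():
    return make_curve_groups(15, (5.0, 15.0), seed=2)
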