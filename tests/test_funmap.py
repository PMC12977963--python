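"""Functional-mapping likelihoods, LR scan and genotypic-value assignment."""

import numpy as np
import pytest

from conftest import make_mapping_data
from idopnet.basis import LogisticParams
from idopnet.funmap import (
    assign_genotypic_values,
    fit_null,
    fit_snp,
    lr_scan,
    permutation_threshold,
)
from idopnet.io import AnalysisConfig, GenotypeMatrix, PhenotypePanel


CFG = AnalysisConfig(n_permutations=30, seed=0)


class TestFitSnp:
    def test_recovers_genotype_asymptotes(self):
        truth = (LogisticParams(10.0, 9.0, 0.5), LogisticParams(14.0, 9.0, 0.5))
        genotypes, panel = make_mapping_data(
            n=40, T=11, sigma2=0.25, effect=truth, seed=7
        )
        fit = fit_snp(genotypes.codes[0], panel, CFG, snp_id="qtl")
        a_hat = sorted(p.a for p in fit.curve_params["HT"].values())
        assert abs(a_hat[0] - 10.0) / 10.0 < 0.05
        assert abs(a_hat[1] - 14.0) / 14.0 < 0.05

    def test_null_case_gives_near_zero_lr(self):
        same = (LogisticParams(12.0, 9.0, 0.5), LogisticParams(12.0, 9.0, 0.5))
        genotypes, panel = make_mapping_data(
            n=40, T=11, sigma2=0.25, effect=same, seed=8
        )
        fit = fit_snp(genotypes.codes[0], panel, CFG, snp_id="qtl")
        null_ll = fit_null(panel, CFG)
        lr = 2.0 * (fit.log_likelihood - null_ll)
        # fitted class curves differ by less than the noise scale
        curves = list(fit.curve_params["HT"].values())
        assert abs(curves[0].a - curves[1].a) < np.sqrt(0.25) * 3
        assert lr < 15.0  # chi-square-scale fluctuation, not a real signal

    def test_small_class_skipped_with_warning(self, caplog):
        genotypes, panel = make_mapping_data(n=20, seed=9)
        codes = genotypes.codes[0].copy()
        codes[:] = 0
        codes[:2] = 1  # class of size 2 < 3
        with caplog.at_level("WARNING", logger="idopnet"):
            fit = fit_snp(codes, panel, CFG, snp_id="s")
        assert fit is None

    def test_single_trait_panel_runs_univariate(self, mapping_data):
        genotypes, panel = mapping_data
        assert len(panel.traits) == 1
        fit = fit_snp(genotypes.codes[0], panel, CFG, snp_id="qtl")
        assert fit.rho is None
        assert np.isfinite(fit.log_likelihood)

    def test_bivariate_panel_estimates_cross_correlation(self):
        g1, p1 = make_mapping_data(n=30, T=9, seed=10, trait="HT")
        _, p2 = make_mapping_data(n=30, T=9, seed=11, trait="DIA")
        panel = PhenotypePanel(
            individuals=p1.individuals,
            times={"HT": p1.times["HT"], "DIA": p2.times["DIA"]},
            values={"HT": p1.values["HT"], "DIA": p2.values["DIA"]},
        )
        fit = fit_snp(g1.codes[0], panel, CFG, snp_id="qtl")
        assert fit.rho is not None and -1 < fit.rho < 1
        assert set(fit.curve_params) == {"HT", "DIA"}


class TestScan:
    def test_true_qtl_attains_max_lr(self):
        genotypes, panel = make_mapping_data(
            n=40, T=11, sigma2=0.25, n_null_snps=9, seed=12
        )
        scan = lr_scan(genotypes, panel, CFG)
        assert scan.snp_ids[int(np.nanargmax(scan.lr))] == "qtl"

    def test_lr_nonnegative_up_to_tolerance(self):
        genotypes, panel = make_mapping_data(
            n=30, T=9, sigma2=0.5, n_null_snps=4, seed=13
        )
        scan = lr_scan(genotypes, panel, CFG)
        assert np.all(scan.lr[~np.isnan(scan.lr)] >= -1e-6)


class TestPermutationThreshold:
    @pytest.fixture(scope="class")
    def data(self):
        return make_mapping_data(n=30, T=9, sigma2=0.25, n_null_snps=3,
                                 seed=14)

    def test_deterministic_given_seed(self, data):
        genotypes, panel = data
        cfg = AnalysisConfig(n_permutations=20, seed=5)
        t1 = permutation_threshold(genotypes, panel, cfg)
        t2 = permutation_threshold(genotypes, panel, cfg)
        assert t1 == t2
        assert t1 > 0

    def test_invariant_to_individual_ordering(self, data):
        genotypes, panel = data
        cfg = AnalysisConfig(n_permutations=20, seed=5)
        t1 = permutation_threshold(genotypes, panel, cfg)
        perm = np.random.default_rng(0).permutation(len(panel.individuals))
        panel2 = PhenotypePanel(
            individuals=[panel.individuals[i] for i in perm],
            times=panel.times,
            values={t: v[perm] for t, v in panel.values.items()},
        )
        geno2 = GenotypeMatrix(
            snps=genotypes.snps,
            individuals=[genotypes.individuals[i] for i in perm],
            codes=genotypes.codes[:, perm],
        )
        t2 = permutation_threshold(geno2, panel2, cfg)
        assert np.isclose(t1, t2)

    def test_alpha_validated(self, data):
        genotypes, panel = data
        with pytest.raises(ValueError):
            AnalysisConfig(alpha=0.0)


class TestAssignment:
    def test_class_level_assignment(self, mapping_data):
        genotypes, panel = mapping_data
        fit = fit_snp(genotypes.codes[0], panel, CFG, snp_id="qtl")
        curves = assign_genotypic_values(fit, genotypes, panel)
        by_ind = {c.individual_id: c for c in curves}
        codes = genotypes.codes[0]
        inds = genotypes.individuals
        same = [i for i in range(len(inds)) if codes[i] == codes[0]]
        assert np.array_equal(
            by_ind[inds[same[0]]].values, by_ind[inds[same[1]]].values
        )
        assert all(c.values.size == panel.times["HT"].size for c in curves)

    def test_missing_genotype_omitted(self, mapping_data):
        genotypes, panel = mapping_data
        from idopnet.io import MISSING

        codes = genotypes.codes.copy()
        codes[0, 0] = MISSING
        geno2 = GenotypeMatrix(
            snps=genotypes.snps, individuals=genotypes.individuals, codes=codes
        )
        fit = fit_snp(codes[0], panel, CFG, snp_id="qtl")
        curves = assign_genotypic_values(fit, geno2, panel)
        assert genotypes.individuals[0] not in {c.individual_id for c in curves}
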