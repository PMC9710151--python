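"""Simulator: drift, LD, liability phenotype, determinism, fresh cohorts."""

import numpy as np
import pytest

from genotransfer.popsim import (PhenotypeSpec, PopulationModel,
                                 SimulationError, generate_fresh_cohort,
                                 shared_rsids, simulate_phenotype,
                                 simulate_population_pair)


def model(n_snps=200, seed=0, **kw):
    return PopulationModel.default(n_snps=n_snps, seed=seed, **kw)


class TestPopulationPair:
    def test_determinism(self):
        m = model()
        a1, b1 = simulate_population_pair(m, 50, 20, seed=7)
        a2, b2 = simulate_population_pair(m, 50, 20, seed=7)
        assert a1.equals(a2) and b1.equals(b2)

    def test_no_drift_means_equal_frequencies(self):
        m = model(n_snps=300, divergence_F=(0.0, 0.0), ld_rho=0.0,
                  private_snp_fraction=0.0)
        a, b = simulate_population_pair(m, 2000, 2000, seed=1)
        diff = np.abs(a.allele_b_freq() - b.allele_b_freq())
        assert diff.mean() < 0.03

    def test_drift_variance_matches_balding_nichols(self):
        # Var(pop freq) = F * p * (1 - p): compare the mean squared deviation
        # of realized population frequencies from the ancestral ones.
        F = 0.2
        m = model(n_snps=1000, divergence_F=(F, F), ld_rho=0.0,
                  private_snp_fraction=0.0, seed=3)
        a, b = simulate_population_pair(m, 5000, 5000, seed=4)
        p = m.ancestral_freqs
        expected = (F * p * (1 - p)).mean()
        for ds in (a, b):
            msd = ((ds.allele_b_freq() - p) ** 2).mean()
            assert abs(msd - expected) < 0.2 * expected

    def test_allele_frequency_recovery(self):
        # estimated frequencies within 3 binomial SEs of the model frequency
        # for >= 99% of SNPs (exact marginals hold at ld_rho = 0)
        m = model(n_snps=500, ld_rho=0.0, seed=5)
        n = 2000
        a, _ = simulate_population_pair(m, n, 100, seed=6)
        f = a.pop_freqs
        se = np.sqrt(f * (1 - f) / (2 * n))
        within = np.abs(a.allele_b_freq() - f) <= 3 * se
        assert within.mean() >= 0.99

    @pytest.mark.parametrize("rho,bound,above", [(0.0, 0.05, False),
                                                 (0.8, 0.4, True)])
    def test_adjacent_snp_correlation(self, rho, bound, above):
        m = model(n_snps=100, ld_rho=rho, private_snp_fraction=0.0,
                  divergence_F=(0.0, 0.0), seed=8)
        a, _ = simulate_population_pair(m, 2000, 100, seed=9)
        g = a.calls.astype(float)
        cors = [abs(np.corrcoef(g[:, j], g[:, j + 1])[0, 1])
                for j in range(0, 99, 2)]
        med = float(np.median(cors))
        assert med > bound if above else med < bound

    def test_panel_overlap_fraction(self):
        m = model(n_snps=1000, private_snp_fraction=0.4, seed=10)
        a, b = simulate_population_pair(m, 10, 10, seed=11)
        common = set(a.rsids) & set(b.rsids)
        assert len(common) == pytest.approx(600, abs=2)
        assert set(shared_rsids(m)) == common

    def test_degenerate_frequencies_rejected(self):
        with pytest.raises(SimulationError):
            PopulationModel(n_snps=2, ancestral_freqs=np.array([0.0, 0.5]))


class TestPhenotype:
    def setup_method(self):
        self.m = model(n_snps=100, seed=20, private_snp_fraction=0.0)
        self.geno, _ = simulate_population_pair(self.m, 2000, 100, seed=21)

    def spec(self, h2, seed=22):
        return PhenotypeSpec.draw(shared_rsids(self.m), 5, seed=seed,
                                  heritability=h2, phenotype_code="YRI_5_1")

    def test_zero_heritability_uncouples_genotype(self):
        cohort = simulate_phenotype(self.geno, self.spec(0.0), seed=23)
        idx = [cohort.genotypes.rsids.index(r) for r in cohort.spec.risk_snp_ids]
        score = cohort.genotypes.calls[:, idx].astype(float) @ np.array(
            cohort.spec.effect_sizes)
        r = np.corrcoef(score, cohort.continuous_phenotype)[0, 1]
        assert abs(r) < 0.05

    def test_case_fraction_near_half(self):
        cohort = simulate_phenotype(self.geno, self.spec(0.5), seed=24)
        assert abs(cohort.case_fraction - 0.5) < 0.03

    def test_determinism(self):
        c1 = simulate_phenotype(self.geno, self.spec(0.5), seed=25)
        c2 = simulate_phenotype(self.geno, self.spec(0.5), seed=25)
        np.testing.assert_array_equal(c1.continuous_phenotype,
                                      c2.continuous_phenotype)

    def test_binary_is_threshold_indicator(self):
        cohort = simulate_phenotype(self.geno, self.spec(0.5), seed=26)
        np.testing.assert_array_equal(
            cohort.binary_phenotype,
            (cohort.continuous_phenotype > 0).astype(int))
        assert 0 < cohort.binary_phenotype.mean() < 1

    def test_heritability_controls_genetic_variance(self):
        h2 = 0.8
        cohort = simulate_phenotype(self.geno, self.spec(h2), seed=27)
        idx = [cohort.genotypes.rsids.index(r) for r in cohort.spec.risk_snp_ids]
        g = cohort.genotypes.calls[:, idx].astype(float)
        z = (g - g.mean(0)) / g.std(0)
        score = z @ np.array(cohort.spec.effect_sizes)
        r2 = np.corrcoef(score, cohort.continuous_phenotype)[0, 1] ** 2
        assert abs(r2 - h2) < 0.05

    def test_missing_risk_snp_named_in_error(self):
        spec = PhenotypeSpec(n_risk_snps=1, risk_snp_ids=("rs_nope",),
                             effect_sizes=(1.0,), phenotype_code="YRI_1_1")
        with pytest.raises(SimulationError, match="rs_nope"):
            simulate_phenotype(self.geno, spec, seed=0)


class TestFreshCohort:
    def test_same_panel_disjoint_ids(self):
        m = model(n_snps=100, seed=30)
        _, small = simulate_population_pair(m, 50, 30, seed=31)
        spec = PhenotypeSpec.draw(shared_rsids(m), 5, seed=32,
                                  phenotype_code="YRI_5_1")
        fd = generate_fresh_cohort(m, spec, 50, seed=33)
        assert fd.genotypes.n_samples == 50
        assert fd.genotypes.rsids == small.rsids
        assert not set(fd.genotypes.sample_ids) & set(small.sample_ids)

    def test_deterministic_per_seed(self):
        m = model(n_snps=50, seed=40)
        spec = PhenotypeSpec.draw(shared_rsids(m), 5, seed=41,
                                  phenotype_code="YRI_5_1")
        f1 = generate_fresh_cohort(m, spec, 20, seed=42)
        f2 = generate_fresh_cohort(m, spec, 20, seed=42)
        assert f1.genotypes.equals(f2.genotypes)
        np.testing.assert_array_equal(f1.binary_phenotype, f2.binary_phenotype)

    def test_same_population_frequencies(self):
        m = model(n_snps=300, seed=50, ld_rho=0.0)
        _, small = simulate_population_pair(m, 2000, 2000, seed=51)
        spec = PhenotypeSpec.draw(shared_rsids(m), 5, seed=52,
                                  phenotype_code="YRI_5_1")
        fd = generate_fresh_cohort(m, spec, 2000, seed=53)
        np.testing.assert_allclose(fd.genotypes.pop_freqs, small.pop_freqs)

    def test_n_below_one_rejected(self):
        m = model(n_snps=20, seed=60)
        spec = PhenotypeSpec.draw(shared_rsids(m), 2, seed=61,
                                  phenotype_code="YRI_2_1")
        with pytest.raises(SimulationError):
            generate_fresh_cohort(m, spec, 0, seed=62)
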