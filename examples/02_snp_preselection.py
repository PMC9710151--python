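"""Score SNPs on training data and build the nested sub-dataset ladder.

Each SNP gets a case/control allele-frequency difference and an allelic
chi-square computed on the training split only; descending thresholds then
carve out nested SNP subsets ("sub-datasets") used as feature sets.
"""

from genotransfer import (PhenotypeSpec, PopulationModel, SplitSpec,
                          build_subdataset_ladder, geometric_thresholds,
                          make_splits, score_snps, shared_rsids,
                          simulate_phenotype, simulate_population_pair)

model = PopulationModel.default(n_snps=500, seed=1)
_, small = simulate_population_pair(model, 1000, 100, seed=2)
spec = PhenotypeSpec.draw(shared_rsids(model), 5, seed=3, heritability=0.6,
                          phenotype_code="YRI_5_1")
cohort = simulate_phenotype(small, spec, seed=5)

splits = make_splits(cohort, SplitSpec(70, 10, 20, seed=6))
scores = score_snps(splits["TD"].genotypes, splits["TD"].labels)

print("top 5 SNPs by case/control frequency difference:")
print(scores.sort_values("abs_diff", ascending=False).head().round(3))

ladder = build_subdataset_ladder(scores, geometric_thresholds(scores, 6))
print("\nladder rung sizes:", [sub.n_snps for sub in ladder])
hits = [sum(r in spec.risk_snp_ids for r in sub.snp_ids) for sub in ladder]
print("true risk SNPs captured per rung:", hits)
# Stricter rungs keep only the strongest case/control differences; with
# heritable signal the causal SNPs climb toward the top of the ranking.
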