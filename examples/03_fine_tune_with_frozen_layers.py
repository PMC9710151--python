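"""Train a source network on the large population, then fine-tune it on the
small one under every freeze plan.

The frozen bottom layers keep the representation learned from the large
cohort; only the trainable top layers adapt to the target population.
"""

import dataclasses

import numpy as np

from genotransfer import (ArchitectureSpec, FreezePlan, PhenotypeSpec,
                          PopulationModel, SplitSpec, SubDataset,
                          TrainingConfig, accuracy, fine_tune,
                          intersect_common_snps, make_splits, materialize,
                          qc_filter, score_snps, shared_rsids,
                          simulate_phenotype, simulate_population_pair,
                          train_source)
from genotransfer.preselect import build_subdataset_ladder, geometric_thresholds

model = PopulationModel.default(n_snps=500, seed=1)
large_g, small_g = simulate_population_pair(model, 1000, 100, seed=2)
spec = PhenotypeSpec.draw(shared_rsids(model), 5, seed=3, heritability=0.6,
                          phenotype_code="YRI_5_1")
large = simulate_phenotype(large_g, spec.with_population("CEU"), seed=4)
small = simulate_phenotype(small_g, spec, seed=5)

lg, sg, _ = intersect_common_snps(qc_filter(large.genotypes)[0],
                                  qc_filter(small.genotypes)[0])
large = dataclasses.replace(large, genotypes=lg)
small = dataclasses.replace(small, genotypes=sg)
large_splits = make_splits(large, SplitSpec(700, 100, 200, seed=6))
small_splits = make_splits(small, SplitSpec(70, 10, 20, seed=7))

scores = score_snps(large_splits["TD"].genotypes, large_splits["TD"].labels)
sub = build_subdataset_ladder(scores, geometric_thresholds(scores, 3))[1]
print(f"sub-dataset {sub.name}: {sub.n_snps} SNPs selected on CEU training data")

mats_large = materialize(sub, large_splits)
mats_small = materialize(sub, small_splits)

cfg = TrainingConfig(epochs=20, seed=0)
src = train_source(ArchitectureSpec(model_id=1, input_dim=sub.n_snps),
                   mats_large["TD"], mats_large["VD"], cfg, subdataset=sub)
src_acc = accuracy(src.net.predict(mats_large["ED"][0]), mats_large["ED"][1])
print(f"source model accuracy on CEU test data: {src_acc:.1f}%")

for t in range(src.net.n_layers):
    plan = FreezePlan.top_k(src.net.n_layers, t)
    tuned = fine_tune(src, plan, mats_small["TD"], mats_small["VD"], cfg)
    acc = accuracy(tuned.net.predict(mats_small["ED"][0]), mats_small["ED"][1])
    print(f"trainable top layers t={t}: YRI test accuracy {acc:.1f}%")
# t=0 is pure transfer (no adaptation); larger t lets more of the network
# adjust to the small population while the frozen prefix keeps the
# large-population representation.
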