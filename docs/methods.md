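# Methods

## Simulation model

**Population structure.** A shared universe of `n_snps` biallelic SNPs is
given ancestral allele-B frequencies (default drawn Uniform(0.05, 0.95) so
every SNP is comfortably polymorphic). Each population's frequencies are
drawn from a Balding–Nichols distribution: Beta with mean `p` and variance
`F·p(1−p)`, where `F` is the per-population drift parameter. The default
`F = (0.075, 0.075)` puts roughly 0.15 of combined differentiation between
the two populations, the magnitude typical of a European/West-African pair.
Each population's panel omits a private fraction of the universe
(default 0.3 split evenly), so the harmonization step has real work to do;
risk SNPs are always drawn from the shared panel.

**Linkage disequilibrium.** Haplotypes are generated by a first-order
Markov copy process: allele *j* copies allele *j−1* with probability
`ld_rho` (default 0.2), else is drawn fresh from the population frequency;
a genotype is the sum of two independent haplotypes. This gives tunable
adjacent-SNP correlation (≈ `ld_rho` when neighbouring frequencies are
similar) at trivial cost. One deliberate consequence: when `ld_rho > 0`,
the marginal frequency of SNP *j* is a geometric smoothing of its
neighbours' frequencies, so exact per-SNP frequency recovery is defined —
and tested — at `ld_rho = 0`. The process has no block structure, no
long-range LD and no relationship to a recombination map; it is a
correlation knob, not a coalescent.

**Phenotype.** The continuous phenotype is an additive liability: risk-SNP
genotypes are standardized within the cohort, weighted by signed effect
sizes (magnitudes Uniform(0.2, 1.0), signs ±1, drawn once per phenotype),
and the resulting score is rescaled so the genetic variance equals the
heritability `h²`; independent Gaussian noise supplies the remaining
`1 − h²`. After mean-centering, the binary label is `liability > 0`
(case = 1), which yields an approximately balanced cohort by construction.
There are no covariates, no shared environmental components and no kinship:
the noise-variance knob subsumes everything non-genetic. Both populations
use the same risk SNPs and the same effect sizes — the assumption that
makes transfer possible at all — while their allele frequencies differ by
drift, which is the domain shift the transfer methods must absorb.

**What passing tests do and do not show.** The simulator produces exactly
the regime the transfer design assumes: shared causal architecture,
moderate drift, clean genotypes, balanced classes. Real cross-population
transfer additionally faces differing LD between causal and tagging
variants, effect-size heterogeneity, missingness, and ascertainment
differences, none of which are emulated. A passing headline check therefore
shows the machinery works under its stated assumptions, not that transfer
will help for any particular real phenotype pair.

## Pipeline

**Splits.** The large cohort (default 1000) is split 700/100/200 into
training (TD), validation (VD) and test (ED); the small cohort (default
100) 70/10/20; a fresh 50-sample cohort from the same population model is
the final hold-out (FD). Splits are label-stratified (a 10-sample
validation set is useless single-class) and deterministic per seed. FD is
wrapped in an access counter and read exactly once per arm, after model
selection on ED — accuracy on FD is therefore selection-free.

**QC and harmonization.** Duplicate rsids (first kept), undefined alleles
and monomorphic SNPs are dropped. Panels are intersected on rsid in the
large population's order; swapped A/B labels are recoded `g → 2 − g` on the
small side so allele-B frequency refers to the same allele everywhere.
Mismatched allele sets are dropped, never guessed; strand complementing is
out of scope because the simulator is strand-consistent.

**SNP pre-selection.** On training data only, each SNP gets case/control
allele-B frequencies (2 alleles per sample), their absolute difference, and
an allelic 2×2 chi-square without continuity correction (upper-tail
p-value, 1 df; degenerate tables score 0/1). A descending threshold ladder
on the frequency difference yields nested sub-datasets (`snps_<n>`); empty
rungs are dropped. The default ladder is geometric from just under the
maximum score down to the 95th percentile of the score distribution — the
published sub-dataset ladders reach at most a few percent of the common
panel, and a floor much lower than that floods the features with null SNPs.
The p-value here is a ranking device: no multiple-testing correction, no LD
pruning, no genomic control.

**Classical arm.** Five model families with library defaults and fixed
seeds: SVM (RBF), decision tree, random-undersampling tree bagging (each of
10 trees sees a class-balanced undersample; majority vote), random forest,
bagging. Selection is arg-max ED accuracy with deterministic tie-breaks
(fewer SNPs, then the fixed model order). SNP transfer trains these models
on the large population's TD restricted to each large-population rung and
evaluates them directly on the small population's ED/FD; a refit-on-target
variant (same SNPs, model refit on the small TD) is exposed as an option
but is not the default reading.

**Deep arm.** Nine architectures: dense stacks 30-10-2, 80-70-40-10-2,
80-70-50-20-10-2 (models 1–3) and GRU/LSTM/BiLSTM 50→20 followed by a dense
head of 2 or 10-5-2 (models 4–9). Recurrent models read the SNP vector as a
length-*n* sequence, one SNP per step in genomic-position order — the only
canonical ordering for tabular SNP input. Hidden dense activations are
ReLU; the 2-unit output feeds a softmax cross-entropy loss; the optimizer
is Adam (lr 1e-3, batch 32), default 50 epochs, no early stopping. The
backend is pure NumPy with full backpropagation-through-time, validated
against numerical gradients in the test suite; training is exactly
deterministic given the seed.

**Freeze plans.** A plan is a boolean trainable mask over weight-bearing
layers constrained to frozen-prefix/trainable-suffix form, enumerated as
t = 0..L−1 trainable top layers. Frozen layers are skipped by the optimizer
entirely, so their weights stay bit-identical — an exact invariant, not a
tolerance. The all-trainable plan is excluded from transfer selection
(unfreezing everything discards what was transferred) but available as a
diagnostic. The selection grid is rungs × architectures × plans, selected
on ED with ties broken by fewer SNPs, smaller model id, more frozen layers.

**Comparison.** Per risk-SNP group (four phenotypes each), the report has
seven rows: the three arms' FD accuracies, the two improvements over
baseline (negative values preserved — negative transfer is a legitimate
outcome the report must be able to show), the maximum achieved, and the
final improvement. The group t-test is Student's pooled-variance two-sample
test between the no-transfer and deep-transfer FD accuracy vectors; pooled
rather than Welch because the reference results report df = n₁+n₂−2 with
the pooled standard error.

## Problem sizes and defaults

| Parameter | Default | Note |
| --- | --- | --- |
| panel size `n_snps` | 1000 | scaled stand-in for the ~62k common SNPs of a real chromosome-21 pair |
| cohorts | 1000 / 100 + 50 FD | splits 700/100/200 and 70/10/20 |
| heritability `h²` | 0.5 (0.6 in the scaled study) | liability-scale variance explained |
| drift `F` | (0.075, 0.075) | CEU–YRI-like differentiation |
| LD `ld_rho` | 0.2 | adjacent-SNP haplotype copy probability |
| private SNP fraction | 0.3 | of the SNP universe |
| effect sizes | ±Uniform(0.2, 1.0) | drawn once per phenotype |
| ladder | 13 rungs (small) / 10 (large), floor at the 95th score percentile | |
| training | Adam, lr 1e-3, batch 32, E = 50 | scaled study uses E = 20 |

The scaled study configuration (`pipeline.scaled_study_config`) reduces the
grid to 3 rungs × 3 architectures (models 1, 2 and the GRU model 4) × 3
freeze plans (t = 0, 1, 2) at 20 epochs so that a full 4-phenotype arm
comparison runs in seconds-to-minutes on one CPU; cohort sizes and splits
stay at their full values.

## Numerical choices and degenerate inputs

- GEN probability triples are hard-called by arg-max; an exact tie (for
  example the uniform triple that encodes a missing call on write) reads
  back as missing.
- Missing genotype calls are mean-filled from the training split at
  materialization; missing SNPs (a real-data situation) are dropped from
  both domains by default ("ignore") or mean-imputed on request, with an
  error above 50% missing.
- Zero heritability or a zero-variance genetic score yields a pure-noise
  phenotype rather than an error; monomorphic risk SNPs contribute zero
  after standardization guarding.
- The t-test with zero pooled variance returns t = 0, p = 1 for equal
  means and refuses unequal means (the statistic is undefined).
- Beta-drawn population frequencies are clipped to [1e-4, 1−1e-4] so no
  panel SNP is exactly fixed.
- All derived seeds come from `numpy.random.SeedSequence` spawns of the
  master seed and stay below 2³¹.

## Known limitations

- The LD model distorts marginal frequencies when `ld_rho` is large and
  neighbouring frequencies differ; calibration statements about frequency
  recovery are made at `ld_rho = 0`.
- The simulator has no covariates, relatedness or population mixture; the
  small population is a drifted sibling of the large one, which is the
  friendliest realistic case for transfer.
- The recurrent architectures are sequential in the panel size, so very
  loose pre-selection rungs (thousands of SNPs) make them expensive; the
  ladder floor keeps default rungs well below that.
- Classical hyperparameters are library defaults throughout; no tuning is
  attempted anywhere, so all arms are compared under equally plain
  settings.
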