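"""Quality control, cross-population SNP harmonization, and data splits.

Transfer requires both populations to carry the same features: the SNP
panels are intersected on rsid, and A/B allele labels that are swapped
between the two datasets are recoded (g -> 2 - g in the small population) so
that allele-B frequency refers to the same allele on both sides.  Allele
sets that do not match at all are dropped, never guessed; strand
complementing is out of scope (simulated data is strand-consistent).

Splits follow the study design: training (TD), validation (VD), test/model
selection (ED) and a final generalization hold-out (FD) that is touched
exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .io_formats import MISSING, GenotypeDataset
from .popsim import SimulatedCohort

logger = logging.getLogger(__name__)


class HarmonizeError(ValueError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    """Sizes of the TD/VD/ED splits (FD comes from a fresh cohort)."""

    n_train: int
    n_val: int
    n_test: int
    n_final: int = 0
    seed: int = 0

    @property
    def n_used(self) -> int:
        return self.n_train + self.n_val + self.n_test


@dataclass
class QCReport:
    duplicates: int = 0
    undefined_alleles: int = 0
    monomorphic: int = 0

    @property
    def total_dropped(self) -> int:
        return self.duplicates + self.undefined_alleles + self.monomorphic


@dataclass
class IntersectReport:
    n_common: int
    n_swapped: int
    n_allele_mismatch: int
    n_large_only: int
    n_small_only: int


def qc_filter(dataset: GenotypeDataset) -> tuple[GenotypeDataset, QCReport]:
    """Drop duplicate rsids (first kept), undefined-allele SNPs, monomorphic SNPs."""
    report = QCReport()
    snps = dataset.snps
    keep = np.ones(len(snps), dtype=bool)

    dup = snps["rsid"].duplicated(keep="first").to_numpy()
    report.duplicates = int(dup.sum())
    keep &= ~dup

    valid_base = snps["allele_a"].isin(list("ACGT")) & snps["allele_b"].isin(list("ACGT"))
    defined = (valid_base & (snps["allele_a"] != snps["allele_b"])).to_numpy()
    report.undefined_alleles = int((keep & ~defined).sum())
    keep &= defined

    calls = dataset.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    first = np.where(obs.any(axis=0), calls[obs.argmax(axis=0), np.arange(calls.shape[1])], 0)
    mono = np.array([
        n_obs[j] == 0 or (calls[obs[:, j], j] == first[j]).all()
        for j in range(calls.shape[1])
    ])
    report.monomorphic = int((keep & mono).sum())
    keep &= ~mono

    if not keep.any():
        logger.warning("qc_filter removed every SNP")
    for category, count in (("duplicate", report.duplicates),
                            ("undefined-allele", report.undefined_alleles),
                            ("monomorphic", report.monomorphic)):
        if count:
            logger.info("qc_filter dropped %d %s SNPs", count, category)
    # positional selection: rsids may be duplicated before QC
    filtered = GenotypeDataset(
        sample_ids=list(dataset.sample_ids),
        snps=snps.loc[keep].reset_index(drop=True),
        calls=dataset.calls[:, keep],
    )
    return filtered, report


def intersect_common_snps(
    large: GenotypeDataset,
    small: GenotypeDataset,
) -> tuple[GenotypeDataset, GenotypeDataset, IntersectReport]:
    """Restrict both datasets to shared rsids with aligned alleles.

    Output SNP order follows the large population's panel.  A shared rsid
    whose alleles are swapped (A/B vs B/A) has the small population's calls
    recoded g -> 2 - g (missing stays missing) and its allele labels swapped,
    so allele-B frequency means the same thing in both outputs.
    """
    small_meta = {r: (a, b) for r, a, b in zip(
        small.snps["rsid"], small.snps["allele_a"], small.snps["allele_b"])}
    common, swapped, mismatched = [], set(), 0
    for rsid, a, b in zip(large.snps["rsid"], large.snps["allele_a"],
                          large.snps["allele_b"]):
        alleles = small_meta.get(rsid)
        if alleles is None:
            continue
        if alleles == (a, b):
            common.append(rsid)
        elif alleles == (b, a):
            common.append(rsid)
            swapped.add(rsid)
        else:
            mismatched += 1
            logger.info("intersect: dropping %s, allele sets %s vs %s", rsid,
                        (a, b), alleles)
    if not common:
        raise HarmonizeError("no common SNPs between the two populations: "
                             "nothing to transfer")

    large_out = large.subset_snps(common)
    small_out = small.subset_snps(common)
    if swapped:
        cols = [j for j, r in enumerate(common) if r in swapped]
        calls = small_out.calls.copy()
        block = calls[:, cols]
        calls[:, cols] = np.where(block == MISSING, MISSING, 2 - block)
        snps = small_out.snps.copy()
        snps.loc[cols, ["allele_a", "allele_b"]] = \
            snps.loc[cols, ["allele_b", "allele_a"]].to_numpy()
        small_out = GenotypeDataset(small_out.sample_ids, snps, calls)

    report = IntersectReport(
        n_common=len(common),
        n_swapped=len(swapped),
        n_allele_mismatch=mismatched,
        n_large_only=large.n_snps - len(common) - mismatched,
        n_small_only=small.n_snps - len(common) - mismatched,
    )
    return large_out, small_out, report


@dataclass
class LabeledSplit:
    """One split: genotypes plus the binary labels of its samples."""

    genotypes: GenotypeDataset
    labels: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)


def make_splits(cohort: SimulatedCohort, spec: SplitSpec) -> dict[str, LabeledSplit]:
    """Partition a cohort into TD/VD/ED, label-stratified where possible.

    Deterministic per ``spec.seed``; the three splits are disjoint and their
    sizes are exactly (n_train, n_val, n_test).
    """
    n = cohort.genotypes.n_samples
    if spec.n_used > n:
        raise HarmonizeError(
            f"split sizes {spec.n_train}+{spec.n_val}+{spec.n_test} exceed cohort size {n}"
        )
    y = cohort.binary_phenotype
    idx = np.arange(n)

    def _split(pool, pool_y, size, rand):
        stratify = pool_y if min(np.bincount(pool_y, minlength=2)) >= 2 else None
        if stratify is None:
            logger.warning("make_splits: class too small, falling back to unstratified")
        taken, rest = train_test_split(pool, train_size=size, random_state=rand,
                                       stratify=stratify)
        return np.sort(taken), rest

    rng = np.random.default_rng(spec.seed)
    rand = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    pool = idx
    td_idx, pool = _split(pool, y[pool], spec.n_train, rand())
    vd_idx, pool = _split(pool, y[pool], spec.n_val, rand())
    if spec.n_test == len(pool):
        ed_idx = np.sort(pool)
    else:
        ed_idx, _ = _split(pool, y[pool], spec.n_test, rand())

    def _make(index):
        return LabeledSplit(cohort.genotypes.subset_samples(index), y[index])

    return {"TD": _make(td_idx), "VD": _make(vd_idx), "ED": _make(ed_idx)}


class FinalHoldout:
    """Wrapper around the FD split that counts every access.

    The generalization estimate is only honest if FD is touched exactly once,
    after model selection; pipelines assert ``access_count == 1``.
    """

    def __init__(self, split: LabeledSplit):
        self._split = split
        self.access_count = 0

    @property
    def n(self) -> int:  # size does not count as an access
        return self._split.n

    def access(self) -> LabeledSplit:
        self.access_count += 1
        return self._split
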