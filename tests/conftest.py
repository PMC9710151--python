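import numpy as np
import pytest

from genotransfer.io_formats import GenotypeDataset, snp_table

_BASES = "ACGT"


def make_dataset(calls, rsids=None, alleles=None, sample_ids=None,
                 chromosome="21", positions=None):
    """Build a small GenotypeDataset from a call matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    rsids = rsids or [f"rs{j + 1}" for j in range(m)]
    alleles = alleles or [("A", "G")] * m
    positions = positions or [1000 * (j + 1) for j in range(m)]
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    snps = snp_table(
        (rsids[j], chromosome, positions[j], alleles[j][0], alleles[j][1])
        for j in range(m)
    )
    return GenotypeDataset(sample_ids=sample_ids, snps=snps, calls=calls)


def random_dataset(rng, n_samples=None, n_snps=None, missing_rate=0.0):
    """A random small dataset for round-trip property tests."""
    n = n_samples or int(rng.integers(1, 6))
    m = n_snps or int(rng.integers(1, 8))
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate:
        calls[rng.random((n, m)) < missing_rate] = -1
    alleles = []
    for _ in range(m):
        i, j = rng.choice(4, size=2, replace=False)
        alleles.append((_BASES[i], _BASES[j]))
    return make_dataset(calls, alleles=alleles)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    return make_dataset([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]])
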