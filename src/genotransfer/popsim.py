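"""Two-population genotype and case/control phenotype simulation.

Replaces a haplotype-resampling + phenotype-simulation toolchain with a
self-contained parametric model:

* Population structure follows a Balding–Nichols drift model: each
  population's allele-B frequency at a SNP is drawn from a Beta distribution
  with mean equal to the ancestral frequency ``p`` and variance
  ``F * p * (1 - p)``, where ``F`` is the per-population drift parameter.
* Linkage disequilibrium is generated at the haplotype level by a first-order
  Markov copy process: each allele copies its left neighbour with probability
  ``ld_rho``, otherwise it is drawn fresh from the population frequency.
  A genotype is the sum of two independent haplotypes.
* The phenotype is an additive liability: a standardized genetic score over
  the risk SNPs scaled to variance ``heritability``, plus independent
  Gaussian noise of variance ``1 - heritability``, mean-centered; the binary
  case/control label is the indicator ``continuous > threshold`` (cases are
  coded 1, controls 0).

Both populations share the SNP universe minus per-population private panels,
and — crucially for transfer — the same risk SNPs and effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeDataset, snp_table

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class PopulationModel:
    """Parametric structure of a pair of diverged populations.

    Parameters
    ----------
    n_snps:
        Size of the shared SNP universe (each population's panel is a subset).
    ancestral_freqs:
        Per-SNP allele-B frequency in the ancestral population, strictly
        inside (0, 1).
    divergence_F:
        Balding–Nichols drift parameter per population (large, small), each
        in [0, 1).  F=0 means the population frequencies equal the ancestral
        ones exactly.
    ld_rho:
        Adjacent-SNP haplotype copy probability in [0, 1); 0 gives
        independent SNPs.
    private_snp_fraction:
        Fraction of the SNP universe present in only one population's panel
        (split evenly between the two populations); in [0, 1).
    chromosome:
        Chromosome label stamped on all SNPs.
    seed:
        Seed fixing the population structure (frequencies, panels, alleles).
        Genotype draws take their own seed.
    """

    n_snps: int
    ancestral_freqs: np.ndarray
    divergence_F: tuple[float, float] = (0.075, 0.075)
    ld_rho: float = 0.2
    private_snp_fraction: float = 0.3
    chromosome: str = "21"
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.ancestral_freqs, dtype=float)
        object.__setattr__(self, "ancestral_freqs", freqs)
        if len(freqs) != self.n_snps:
            raise SimulationError("ancestral_freqs length must equal n_snps")
        if not ((freqs > 0) & (freqs < 1)).all():
            raise SimulationError("ancestral frequencies must be strictly inside (0, 1)")
        for F in self.divergence_F:
            if not (0 <= F < 1):
                raise SimulationError("divergence_F must be in [0, 1)")
        if not (0 <= self.ld_rho < 1):
            raise SimulationError("ld_rho must be in [0, 1)")
        if not (0 <= self.private_snp_fraction < 1):
            raise SimulationError("private_snp_fraction must be in [0, 1)")

    @classmethod
    def default(cls, n_snps: int = 1000, seed: int = 0, **kwargs) -> "PopulationModel":
        """A model with ancestral frequencies drawn Uniform(0.05, 0.95)."""
        rng = np.random.default_rng(seed)
        freqs = rng.uniform(0.05, 0.95, size=n_snps)
        return cls(n_snps=n_snps, ancestral_freqs=freqs, seed=seed, **kwargs)


@dataclass(frozen=True)
class PhenotypeSpec:
    """Risk-SNP set, effect sizes and liability parameters for one phenotype.

    ``phenotype_code`` follows the ``X_Y_Z`` convention: population label,
    number of risk SNPs, iteration number (e.g. ``YRI_5_1``).
    """

    n_risk_snps: int
    risk_snp_ids: tuple[str, ...]
    effect_sizes: tuple[float, ...]
    heritability: float = 0.5
    threshold: float = 0.0
    phenotype_code: str = "POP_0_0"

    def __post_init__(self) -> None:
        if not (len(self.risk_snp_ids) == self.n_risk_snps == len(self.effect_sizes)):
            raise SimulationError(
                "n_risk_snps, risk_snp_ids and effect_sizes must agree in length"
            )
        if not (0.0 <= self.heritability <= 1.0):
            raise SimulationError("heritability must be in [0, 1]")
        parts = self.phenotype_code.split("_")
        if len(parts) != 3:
            raise SimulationError("phenotype_code must follow the 'X_Y_Z' convention")

    def with_population(self, pop_label: str) -> "PhenotypeSpec":
        _, y, z = self.phenotype_code.split("_")
        return replace(self, phenotype_code=f"{pop_label}_{y}_{z}")

    @classmethod
    def draw(
        cls,
        shared_rsids: Sequence[str],
        n_risk_snps: int,
        seed: int,
        heritability: float = 0.5,
        phenotype_code: str | None = None,
    ) -> "PhenotypeSpec":
        """Draw risk SNPs and effects the way the study's phenotypes are made.

        Risk SNPs are sampled without replacement from the SNPs shared by both
        populations; effects are signed, magnitude Uniform(0.2, 1.0).
        """
        rng = np.random.default_rng(seed)
        if len(shared_rsids) < n_risk_snps:
            raise SimulationError("not enough shared SNPs to place risk SNPs")
        ids = rng.choice(np.asarray(shared_rsids, dtype=object), size=n_risk_snps,
                         replace=False)
        effects = rng.choice([-1.0, 1.0], size=n_risk_snps) * rng.uniform(
            0.2, 1.0, size=n_risk_snps)
        return cls(
            n_risk_snps=n_risk_snps,
            risk_snp_ids=tuple(str(r) for r in ids),
            effect_sizes=tuple(float(e) for e in effects),
            heritability=heritability,
            phenotype_code=phenotype_code or f"POP_{n_risk_snps}_1",
        )


@dataclass
class SimulatedCohort:
    """Genotypes plus the continuous and binarized phenotype of one cohort."""

    genotypes: GenotypeDataset
    continuous_phenotype: np.ndarray
    binary_phenotype: np.ndarray
    spec: PhenotypeSpec

    def __post_init__(self) -> None:
        expected = (self.continuous_phenotype > self.spec.threshold).astype(np.int64)
        if not np.array_equal(self.binary_phenotype, expected):
            raise SimulationError("binary phenotype must equal (continuous > threshold)")

    @property
    def case_fraction(self) -> float:
        return float(self.binary_phenotype.mean())

    def phenotype_table(self) -> dict[str, int]:
        return {s: int(v) for s, v in zip(self.genotypes.sample_ids,
                                          self.binary_phenotype)}


# ---------------------------------------------------------------------------
# Population structure (deterministic given model.seed)
# ---------------------------------------------------------------------------

def _population_structure(model: PopulationModel):
    """Derive SNP metadata, per-population frequencies and panel masks.

    Deterministic in ``model.seed`` so that fresh cohorts can be drawn from
    the same population later.
    """
    rng = np.random.default_rng(model.seed)
    n = model.n_snps
    positions = np.cumsum(rng.integers(200, 2000, size=n)) + 9_000_000
    allele_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(n)])
    snps = snp_table(
        (f"rs{i + 1}", model.chromosome, int(positions[i]),
         _BASES[allele_idx[i, 0]], _BASES[allele_idx[i, 1]])
        for i in range(n)
    )

    pop_freqs = []
    for F in model.divergence_F:
        p = model.ancestral_freqs
        if F == 0:
            pop_freqs.append(p.copy())
        else:
            a = p * (1 - F) / F
            b = (1 - p) * (1 - F) / F
            f = rng.beta(a, b)
            # keep frequencies non-degenerate so every panel SNP is polymorphic
            pop_freqs.append(np.clip(f, 1e-4, 1 - 1e-4))

    n_private = int(round(model.private_snp_fraction * n))
    private = rng.choice(n, size=n_private, replace=False)
    half = n_private // 2
    panel_a = np.ones(n, dtype=bool)
    panel_b = np.ones(n, dtype=bool)
    panel_a[private[half:]] = False   # these SNPs are private to population B
    panel_b[private[:half]] = False   # these are private to population A
    if not (panel_a & panel_b).any():
        raise SimulationError("population panels do not overlap")
    return snps, pop_freqs, (panel_a, panel_b)


def _draw_genotypes(freqs: np.ndarray, ld_rho: float, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Genotypes as the sum of two Markov-copy haplotypes."""
    m = len(freqs)
    geno = np.zeros((n, m), dtype=np.int8)
    for _ in range(2):
        hap = np.empty((n, m), dtype=np.int8)
        fresh = rng.random((n, m)) < freqs
        if ld_rho == 0:
            hap = fresh.astype(np.int8)
        else:
            copy = rng.random((n, m)) < ld_rho
            copy[:, 0] = False
            hap[:, 0] = fresh[:, 0]
            for j in range(1, m):
                hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])
        geno += hap
    return geno


def _make_dataset(model: PopulationModel, pop_index: int, n: int, seed: int,
                  id_prefix: str) -> GenotypeDataset:
    snps, pop_freqs, panels = _population_structure(model)
    mask = panels[pop_index]
    freqs = pop_freqs[pop_index][mask]
    rng = np.random.default_rng(seed)
    calls = _draw_genotypes(freqs, model.ld_rho, n, rng)
    return GenotypeDataset(
        sample_ids=[f"{id_prefix}{i + 1}" for i in range(n)],
        snps=snps[mask].reset_index(drop=True),
        calls=calls,
        pop_freqs=freqs,
    )


def simulate_population_pair(
    model: PopulationModel,
    n_large: int,
    n_small: int,
    seed: int,
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Simulate genotype panels for the large and the small population.

    The two panels overlap according to ``model.private_snp_fraction``; the
    per-population allele frequencies diverge from the ancestral ones by the
    Balding–Nichols drift ``model.divergence_F``.  Deterministic given
    ``seed`` (and ``model.seed`` for the population structure).
    """
    if not (n_large >= n_small >= 2):
        raise SimulationError("need n_large >= n_small >= 2")
    ss = np.random.SeedSequence([seed, model.seed])
    s_large, s_small = ss.spawn(2)
    large = _make_dataset(model, 0, n_large, s_large.generate_state(1)[0], "L")
    small = _make_dataset(model, 1, n_small, s_small.generate_state(1)[0], "S")
    return large, small


def shared_rsids(model: PopulationModel) -> list[str]:
    """rsids present in both populations' panels (risk SNPs must come from here)."""
    snps, _, (panel_a, panel_b) = _population_structure(model)
    return snps.loc[panel_a & panel_b, "rsid"].tolist()


def simulate_phenotype(
    genotypes: GenotypeDataset,
    spec: PhenotypeSpec,
    seed: int,
) -> SimulatedCohort:
    """Draw a liability phenotype on an existing cohort and binarize it.

    The continuous phenotype is the additive genetic score over the risk
    SNPs (standardized genotypes weighted by the effect sizes), rescaled to
    variance = heritability, plus independent Gaussian noise of variance
    1 - heritability; the result is mean-centered.  The binary label is
    ``continuous > spec.threshold``.
    """
    idx = pd.Index(genotypes.snps["rsid"])
    for rsid in spec.risk_snp_ids:
        if rsid not in idx:
            raise SimulationError(f"risk SNP {rsid} not present in the genotype panel")
    locs = idx.get_indexer(list(spec.risk_snp_ids))
    g = genotypes.calls[:, locs].astype(float)
    g[g == MISSING] = np.nan
    mu = np.nanmean(g, axis=0)
    sd = np.nanstd(g, axis=0)
    sd[sd == 0] = 1.0
    z = (np.where(np.isnan(g), mu[None, :], g) - mu) / sd
    score = z @ np.asarray(spec.effect_sizes)

    h2 = spec.heritability
    s = score.std()
    genetic = np.zeros_like(score) if (h2 == 0 or s == 0) else score * np.sqrt(h2) / s

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(genotypes.n_samples) * np.sqrt(1.0 - h2)
    continuous = genetic + noise
    continuous = continuous - continuous.mean()
    binary = (continuous > spec.threshold).astype(np.int64)
    return SimulatedCohort(
        genotypes=genotypes,
        continuous_phenotype=continuous,
        binary_phenotype=binary,
        spec=spec,
    )


def generate_fresh_cohort(
    model: PopulationModel,
    spec: PhenotypeSpec,
    n: int,
    seed: int,
    population: str = "small",
    id_prefix: str = "F",
) -> SimulatedCohort:
    """Draw a brand-new cohort from the same population and phenotype model.

    Used for the final hold-out: same population frequencies (the structure
    is deterministic in ``model.seed``), same risk SNPs and effect sizes,
    fresh samples with ids disjoint from earlier cohorts (``id_prefix``).
    """
    if n < 1:
        raise SimulationError("need n >= 1")
    pop_index = {"large": 0, "small": 1}[population]
    ss = np.random.SeedSequence([seed, model.seed, 7 + pop_index])
    geno_seed, pheno_seed = (s.generate_state(1)[0] for s in ss.spawn(2))
    genotypes = _make_dataset(model, pop_index, n, geno_seed, id_prefix)
    return simulate_phenotype(genotypes, spec, pheno_seed)
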