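"""Genotype and phenotype file dialects.

Two text formats are supported: the Oxford GEN/SAMPLE pair (genotype
probability triples, as emitted by haplotype-resampling simulators) and a
23andme-style per-sample raw genotype file (tab-separated rsid, chromosome,
position, two-letter genotype).  Probability triples are hard-called by
arg-max; an exact tie is treated as a missing call.  Positions are 1-based
throughout, and allele orientation is owned by :mod:`genotransfer.harmonize`,
not by the readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

SNP_COLUMNS = ["rsid", "chromosome", "position", "allele_a", "allele_b"]


class FormatError(ValueError):
    """Raised when a genotype/phenotype file cannot be parsed."""


def snp_table(records: Iterable[tuple]) -> pd.DataFrame:
    """Build the SNP metadata table from (rsid, chrom, pos, A, B) tuples."""
    df = pd.DataFrame(list(records), columns=SNP_COLUMNS)
    df["position"] = df["position"].astype(np.int64)
    return df.reset_index(drop=True)


@dataclass
class GenotypeDataset:
    """A sample x SNP matrix of hard calls plus SNP metadata.

    calls[i, j] is the count (0/1/2) of ``allele_b`` for sample i at SNP j,
    or MISSING (-1).
    """

    sample_ids: list[str]
    snps: pd.DataFrame  # columns: rsid, chromosome, position, allele_a, allele_b
    calls: np.ndarray   # int8, shape (n_samples, n_snps)
    #: optional per-SNP population allele-B frequency (attached by popsim)
    pop_freqs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"genotype calls outside {{-1,0,1,2}}: {bad}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids are not unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def rsids(self) -> list[str]:
        return self.snps["rsid"].tolist()

    def allele_b_freq(self) -> np.ndarray:
        """Empirical allele-B frequency per SNP, ignoring missing calls."""
        calls = self.calls.astype(float)
        obs = calls != MISSING
        b = np.where(obs, calls, 0.0).sum(axis=0)
        n = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, b / n, np.nan)

    def subset_snps(self, rsids: Sequence[str]) -> "GenotypeDataset":
        """Restrict to the given rsids, in the given order."""
        idx = pd.Index(self.snps["rsid"])
        missing = [r for r in rsids if r not in idx]
        if missing:
            raise KeyError(f"rsids not in dataset: {missing[:5]}")
        locs = idx.get_indexer(list(rsids))
        return GenotypeDataset(
            sample_ids=list(self.sample_ids),
            snps=self.snps.iloc[locs].reset_index(drop=True),
            calls=self.calls[:, locs],
            pop_freqs=None if self.pop_freqs is None else self.pop_freqs[locs],
        )

    def subset_samples(self, index: Sequence[int]) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            sample_ids=[self.sample_ids[i] for i in index],
            snps=self.snps.copy().reset_index(drop=True),
            calls=self.calls[index],
            pop_freqs=self.pop_freqs,
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.snps[SNP_COLUMNS].equals(other.snps[SNP_COLUMNS])
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PhenotypeTable:
    """sample_id -> binary phenotype (0=control, 1=case)."""

    values: dict[str, int]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.values.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"phenotype values must be 0/1, got {bad}")

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.values[s] for s in sample_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"sample id missing from phenotype table: {exc}") from exc


# ---------------------------------------------------------------------------
# Oxford GEN / SAMPLE
# ---------------------------------------------------------------------------

def _hard_call(triple: np.ndarray) -> int:
    """Arg-max hard call; an exact tie for the maximum is MISSING."""
    m = triple.max()
    if (triple == m).sum() > 1:
        return MISSING
    return int(triple.argmax())


def read_sample(path: str | Path) -> tuple[list[str], np.ndarray | None]:
    """Read an Oxford SAMPLE file; returns (sample_ids, phenotype or None).

    Layout: header ``ID_1 ID_2 pheno``, type line ``0 0 B``, then one row per
    sample.  The phenotype column may be absent.
    """
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: sample file needs header + type lines")
    header = lines[0]
    body = lines[2:]
    ids = [row[0] for row in body]
    pheno = None
    if "pheno" in header:
        col = header.index("pheno")
        vals = []
        for row in body:
            if len(row) <= col or row[col] in ("NA", "-9"):
                vals.append(MISSING)
            else:
                vals.append(int(float(row[col])))
        pheno = np.array(vals, dtype=np.int64)
    return ids, pheno


def read_gen(path: str | Path, sample_path: str | Path) -> GenotypeDataset:
    """Read an Oxford GEN file plus its SAMPLE file into hard calls.

    Each GEN row carries SNP metadata followed by one probability triple per
    sample.  Rows may start with 5 fields (snpid rsid pos A B) or 6 (with a
    leading chromosome); the layout is inferred from the sample count.
    """
    sample_ids, _ = read_sample(sample_path)
    n = len(sample_ids)
    records, calls = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        lead = len(fields) - 3 * n
        if lead not in (5, 6):
            raise FormatError(
                f"{path}:{lineno}: row has {len(fields)} fields, expected "
                f"5 or 6 + 3*{n} probabilities"
            )
        if lead == 6:
            chrom, snpid, rsid, pos, a, b = fields[:6]
        else:
            snpid, rsid, pos, a, b = fields[:5]
            chrom = "0"
        try:
            probs = np.array(fields[lead:], dtype=float).reshape(n, 3)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed probability "
                              f"fields ({exc})") from exc
        records.append((rsid, chrom, int(pos), a, b))
        calls.append([_hard_call(t) for t in probs])
    if not records:
        raise FormatError(f"{path}: no genotype rows")
    return GenotypeDataset(
        sample_ids=sample_ids,
        snps=snp_table(records),
        calls=np.array(calls, dtype=np.int8).T,
    )


_TRIPLES = {0: "1 0 0", 1: "0 1 0", 2: "0 0 1",
            MISSING: "0.3333333333 0.3333333333 0.3333333333"}


def write_gen(
    dataset: GenotypeDataset,
    path: str | Path,
    sample_path: str | Path,
    phenotype: Mapping[str, int] | None = None,
) -> None:
    """Write GEN + SAMPLE files (inverse of :func:`read_gen` on hard calls).

    Missing calls are written as the uniform probability triple, which
    arg-max-with-tie reads back as missing.
    """
    if dataset.n_samples == 0 or dataset.n_snps == 0:
        raise ValueError("refusing to write an empty dataset")
    with open(path, "w") as fh:
        for j, snp in dataset.snps.iterrows():
            lead = (f"{snp.chromosome} snp{j + 1} {snp.rsid} "
                    f"{snp.position} {snp.allele_a} {snp.allele_b}")
            trips = " ".join(_TRIPLES[int(c)] for c in dataset.calls[:, j])
            fh.write(f"{lead} {trips}\n")
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 pheno\n0 0 B\n")
        for sid in dataset.sample_ids:
            p = "NA" if phenotype is None else str(int(phenotype[sid]))
            fh.write(f"{sid} {sid} {p}\n")


# ---------------------------------------------------------------------------
# 23andme dialect
# ---------------------------------------------------------------------------

_GENO_STRINGS = {0: lambda a, b: a + a, 1: lambda a, b: a + b, 2: lambda a, b: b + b}


def write_23andme(dataset: GenotypeDataset, sample_id: str, path: str | Path) -> None:
    """Write one sample as a 23andme-style raw genotype file."""
    i = dataset.sample_ids.index(sample_id)
    with open(path, "w") as fh:
        fh.write(f"# sample {sample_id}\n# rsid\tchromosome\tposition\tgenotype\n")
        for j, snp in dataset.snps.iterrows():
            c = int(dataset.calls[i, j])
            geno = "--" if c == MISSING else _GENO_STRINGS[c](snp.allele_a, snp.allele_b)
            fh.write(f"{snp.rsid}\t{snp.chromosome}\t{snp.position}\t{geno}\n")


def read_23andme(
    paths: Mapping[str, str | Path],
    snp_reference: pd.DataFrame,
) -> GenotypeDataset:
    """Read per-sample 23andme files into a dataset.

    ``paths`` maps sample_id -> file.  ``snp_reference`` (a SNP metadata table
    as in :class:`GenotypeDataset`) fixes the SNP panel, order and the A/B
    allele orientation; the raw genotype letters alone cannot.  Genotype
    letters outside {allele_a, allele_b} become missing calls, with a warning.
    """
    ref = snp_reference.reset_index(drop=True)
    rsid_to_col = {r: j for j, r in enumerate(ref["rsid"])}
    sample_ids = list(paths)
    calls = np.full((len(sample_ids), len(ref)), MISSING, dtype=np.int8)
    for i, sid in enumerate(sample_ids):
        for lineno, line in enumerate(Path(paths[sid]).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise FormatError(f"{paths[sid]}:{lineno}: expected 4 tab-separated fields")
            rsid, _chrom, _pos, geno = parts
            j = rsid_to_col.get(rsid)
            if j is None:
                logger.warning("%s:%d: rsid %s not in reference, skipped", paths[sid], lineno, rsid)
                continue
            a, b = ref.at[j, "allele_a"], ref.at[j, "allele_b"]
            if geno == "--" or any(ch not in (a, b) for ch in geno):
                if geno != "--":
                    logger.warning(
                        "%s:%d: genotype %r not composed of alleles %s/%s, set missing",
                        paths[sid], lineno, geno, a, b,
                    )
                calls[i, j] = MISSING
            else:
                calls[i, j] = sum(ch == b for ch in geno)
    return GenotypeDataset(sample_ids=sample_ids, snps=ref.copy(), calls=calls)


# ---------------------------------------------------------------------------
# Phenotype and rsid-list files
# ---------------------------------------------------------------------------

def write_phenotype(table: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, v in table.values.items():
            fh.write(f"{sid} {v}\n")


def read_phenotype(path: str | Path) -> PhenotypeTable:
    values: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'sample_id value'")
        sid, raw = parts
        if raw not in ("0", "1"):
            raise FormatError(f"{path}:{lineno}: phenotype must be 0 or 1, got {raw!r}")
        values[sid] = int(raw)
    return PhenotypeTable(values)


def write_rsid_list(rsids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{r}\n" for r in rsids))


def read_rsid_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
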