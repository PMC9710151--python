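"""Per-SNP case/control statistics and the nested sub-dataset ladder.

Dimensionality reduction before model fitting: each SNP is scored on the
TRAINING samples only (leakage guard) by the case/control allele-frequency
difference and an allelic 2x2 chi-square; a descending ladder of thresholds
then yields nested SNP subsets ("sub-datasets", named ``snps_<n>``).  The
p-value here is a ranking device, not an inference: no multiple-testing
correction, no LD pruning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeDataset
from .harmonize import LabeledSplit

logger = logging.getLogger(__name__)


class PreselectError(ValueError):
    pass


@dataclass(frozen=True)
class SubDataset:
    """A named SNP subset selected on training data.

    ``snp_ids`` are ordered by descending score (ties by rsid) and are
    materialized identically across all splits of a population.
    """

    name: str
    snp_ids: tuple[str, ...]
    threshold_used: float
    source_population: str = ""

    def __post_init__(self) -> None:
        if len(self.snp_ids) == 0:
            raise PreselectError("a sub-dataset must contain at least one SNP")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def score_snps(train_genotypes: GenotypeDataset, train_labels: np.ndarray) -> pd.DataFrame:
    """Case/control allele statistics per SNP, from training samples only.

    Returns a DataFrame indexed by rsid with columns ``freq_case``,
    ``freq_control``, ``abs_diff``, ``chi2`` and ``pvalue``.  Frequencies are
    allele-B counts over 2 alleles per non-missing sample; the chi-square is
    the allelic 2x2 test without continuity correction, with upper-tail
    p-value (1 df).  Degenerate tables (a zero margin) score chi2=0, p=1.
    """
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise PreselectError("score_snps needs both cases and controls in the labels")
    calls = train_genotypes.calls
    obs = calls != MISSING

    def allele_counts(mask):
        c = calls[mask].astype(np.int64)
        o = obs[mask]
        b = np.where(o, c, 0).sum(axis=0).astype(float)
        total = 2.0 * o.sum(axis=0)
        return b, total - b, total

    case_b, case_a, case_n = allele_counts(y == 1)
    ctrl_b, ctrl_a, ctrl_n = allele_counts(y == 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        freq_case = np.where(case_n > 0, case_b / case_n, np.nan)
        freq_ctrl = np.where(ctrl_n > 0, ctrl_b / ctrl_n, np.nan)
        n = case_n + ctrl_n
        det = case_b * ctrl_a - case_a * ctrl_b
        denom = (case_b + case_a) * (ctrl_b + ctrl_a) * (case_b + ctrl_b) * (case_a + ctrl_a)
        chi2 = np.where(denom > 0, n * det**2 / denom, 0.0)
    pvalue = stats.chi2.sf(chi2, df=1)
    pvalue = np.where(chi2 == 0, 1.0, pvalue)

    return pd.DataFrame(
        {
            "freq_case": freq_case,
            "freq_control": freq_ctrl,
            "abs_diff": np.abs(freq_case - freq_ctrl),
            "chi2": chi2,
            "pvalue": pvalue,
        },
        index=pd.Index(train_genotypes.rsids, name="rsid"),
    )


def build_subdataset_ladder(
    scores: pd.DataFrame,
    thresholds: list[float],
    criterion: str = "abs_diff",
    source_population: str = "",
) -> list[SubDataset]:
    """Nested SNP subsets, one per threshold (strict-to-loose).

    For ``criterion='abs_diff'`` thresholds must be descending and a SNP
    enters a rung when ``abs_diff >= threshold``; for ``'pvalue'`` they must
    be ascending with ``pvalue <= threshold``.  Empty rungs are dropped with
    a warning (a sub-dataset with 0 SNPs is ignored); rungs whose SNP set
    duplicates an earlier rung are merged.  Within a rung SNPs are ordered by
    descending score, ties broken by rsid.
    """
    if criterion not in ("abs_diff", "pvalue"):
        raise PreselectError(f"unknown criterion {criterion!r}")
    vals = thresholds
    monotone = all(a > b for a, b in zip(vals, vals[1:])) if criterion == "abs_diff" \
        else all(a < b for a, b in zip(vals, vals[1:]))
    if not monotone:
        raise PreselectError("thresholds must be strictly monotone in selectivity")

    if criterion == "abs_diff":
        ordered = scores.sort_index().sort_values("abs_diff", ascending=False,
                                                  kind="stable")
        metric = ordered["abs_diff"].to_numpy()
        counts = [int((metric >= t).sum()) for t in thresholds]
    else:
        ordered = scores.sort_index().sort_values("pvalue", ascending=True,
                                                  kind="stable")
        metric = ordered["pvalue"].to_numpy()
        counts = [int((metric <= t).sum()) for t in thresholds]

    rsids = ordered.index.to_list()
    ladder: list[SubDataset] = []
    seen_sizes: set[int] = set()
    for t, k in zip(thresholds, counts):
        if k == 0:
            logger.warning("threshold %g selects no SNPs; rung ignored", t)
            continue
        if k in seen_sizes:
            continue
        seen_sizes.add(k)
        ladder.append(SubDataset(
            name=f"snps_{k}",
            snp_ids=tuple(rsids[:k]),
            threshold_used=float(t),
            source_population=source_population,
        ))
    return ladder


def geometric_thresholds(
    scores: pd.DataFrame,
    n_rungs: int = 13,
    loosest_quantile: float = 0.95,
) -> list[float]:
    """A descending geometric ladder of abs_diff thresholds.

    About ``n_rungs`` sub-datasets spanning the top of the observed score
    range, from just under the maximum down to the ``loosest_quantile`` of
    the score distribution.  The default floor keeps the loosest rung at
    roughly 5% of the panel, matching the proportion the study's published
    sub-dataset ladders reach (their largest rungs hold a few percent of the
    common SNPs), and keeps null SNPs from flooding the features.
    """
    diffs = scores["abs_diff"].to_numpy()
    top = np.nanmax(diffs)
    bottom = max(float(np.nanquantile(diffs, loosest_quantile)), 1e-4)
    if top <= bottom:
        return [bottom]
    return list(np.geomspace(top * 0.999, bottom, n_rungs))


def materialize(
    sub: SubDataset,
    splits: dict[str, LabeledSplit],
    missing_policy: str = "ignore",
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Feature matrices (X, y) per split, with identical SNP columns.

    Splits must share the sub-dataset's SNPs; an rsid absent from some split
    (a real-data situation) is handled per ``missing_policy``: ``"ignore"``
    drops the column from every split, ``"mean_impute"`` fills it from the
    TD mean call.  Missing individual calls are always mean-filled from TD.
    """
    available = [set(s.genotypes.rsids) for s in splits.values()]
    usable = [r for r in sub.snp_ids if all(r in a for a in available)]
    dropped = len(sub.snp_ids) - len(usable)
    if missing_policy == "mean_impute":
        cols = list(sub.snp_ids)
    else:
        if dropped:
            logger.warning("materialize: dropped %d SNPs absent from some split",
                           dropped)
        cols = usable
    if not cols:
        raise PreselectError("no usable SNPs after applying the missing policy")

    td = splits.get("TD")
    td_means: dict[str, float] = {}
    if td is not None:
        td_cols = [r for r in cols if r in set(td.genotypes.rsids)]
        sub_td = td.genotypes.subset_snps(td_cols)
        c = sub_td.calls.astype(float)
        c[c == MISSING] = np.nan
        means = np.nanmean(c, axis=0)
        td_means = {r: (0.0 if np.isnan(m) else float(m))
                    for r, m in zip(td_cols, means)}

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, split in splits.items():
        have = set(split.genotypes.rsids)
        present = [r for r in cols if r in have]
        X = np.full((split.n, len(cols)), np.nan)
        if present:
            sub_ds = split.genotypes.subset_snps(present)
            block = sub_ds.calls.astype(float)
            block[block == MISSING] = np.nan
            pos = {r: k for k, r in enumerate(cols)}
            X[:, [pos[r] for r in present]] = block
        for k, r in enumerate(cols):
            col = X[:, k]
            fill = td_means.get(r, np.nanmean(col) if np.isfinite(col).any() else 0.0)
            col[np.isnan(col)] = fill
        out[name] = (X, np.asarray(split.labels))
    return out


def matched_subdataset(
    source_sub: SubDataset,
    target: GenotypeDataset,
    missing_policy: str = "ignore",
) -> SubDataset:
    """The target-population sub-dataset matching a source sub-dataset.

    Transfer requires the target to be classified on the SAME SNPs the source
    model was trained on; the result keeps the source rsid order and is named
    ``snps_transfer_<n>``.  rsids absent from the target are dropped on both
    sides (``"ignore"``) or kept for mean imputation (``"mean_impute"``);
    more than 50% absent is an error.
    """
    have = set(target.rsids)
    present = [r for r in source_sub.snp_ids if r in have]
    n_missing = len(source_sub.snp_ids) - len(present)
    if n_missing > 0.5 * len(source_sub.snp_ids):
        raise PreselectError(
            f"{n_missing}/{len(source_sub.snp_ids)} source SNPs missing from target"
        )
    if missing_policy == "mean_impute":
        kept = source_sub.snp_ids
    else:
        if n_missing:
            logger.warning("matched_subdataset: ignoring %d SNPs absent from target",
                           n_missing)
        kept = tuple(present)
    return SubDataset(
        name=f"snps_transfer_{len(kept)}",
        snp_ids=tuple(kept),
        threshold_used=source_sub.threshold_used,
        source_population=source_sub.source_population,
    )
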