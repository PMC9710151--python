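"""Accuracy, comparison tables and the pooled two-sample t-test.

The headline question — does transfer help? — is answered by comparing the
final-hold-out (FD) accuracies of the no-transfer baseline against the
transfer arms across phenotypes, with a Student (pooled-variance) two-sample
t-test on the two accuracy vectors.  Improvements may be negative (negative
transfer) and the tables preserve that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Percent of correct predictions."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have the same shape")
    if labels.size == 0:
        raise ValueError("empty label vector")
    return float(100.0 * np.mean(predictions == labels))


@dataclass(frozen=True)
class TTestResult:
    """Student pooled-variance two-sample t-test output.

    ``t`` carries the sign of ``mean(group2) - mean(group1)``; ``df`` is
    n1 + n2 - 2; ``se_diff`` is the pooled standard error of the mean
    difference; ``p_two_tailed`` comes from the t distribution.
    """

    t: float
    df: int
    se_diff: float
    p_two_tailed: float


def pooled_two_sample_ttest(group1, group2) -> TTestResult:
    """Student's pooled-variance two-sample t-test (two-tailed).

    Pooled, not Welch: sp^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2),
    SE = sp * sqrt(1/n1 + 1/n2), t = (mean2 - mean1) / SE on n1+n2-2 df.
    Zero pooled variance with equal means gives t=0, p=1; with unequal means
    it is an error (the statistic is undefined).
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = len(x1), len(x2)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / df
    se = float(np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
    diff = float(x2.mean() - x1.mean())
    if se == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, df=df, se_diff=0.0, p_two_tailed=1.0)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, se_diff=se, p_two_tailed=p)


ROW_ORDER = [
    "Results without transfer learning",
    "With snps transfer learning",
    "Improvement with snps transfer learning",
    "With deep transfer learning",
    "Improvement with deep transfer learning",
    "Max achieved",
    "Final improvement",
]


@dataclass
class ComparisonTable:
    """The seven-row per-phenotype comparison report plus its t-test.

    Columns are phenotype codes; rows are the three arms' FD accuracies, the
    two improvements over the no-transfer baseline, the best accuracy
    achieved, and the final improvement (max achieved - baseline).  The
    t-test compares the no-transfer and deep-transfer accuracy vectors.
    """

    table: pd.DataFrame
    ttest: TTestResult

    def __str__(self) -> str:
        lines = [self.table.to_string()]
        lines.append(
            f"Two-tailed P = {self.ttest.p_two_tailed:.4f}, t = {self.ttest.t:.4f}, "
            f"df = {self.ttest.df}, standard error of difference = {self.ttest.se_diff:.3f}"
        )
        return "\n".join(lines)


def build_comparison_table(results: dict[str, dict[str, float]]) -> ComparisonTable:
    """Assemble the comparison table from per-phenotype FD accuracies.

    ``results`` maps phenotype code -> {"no_transfer": acc, "snp_transfer":
    acc, "deep_transfer": acc} (percent).  The identities
    improvement_x = acc_x - acc_no_transfer, max_achieved = max of the three,
    final_improvement = max_achieved - acc_no_transfer hold exactly.
    """
    if not results:
        raise ValueError("no per-phenotype results")
    cols = {}
    for code, accs in results.items():
        base = accs["no_transfer"]
        snp = accs["snp_transfer"]
        deep = accs["deep_transfer"]
        best = max(base, snp, deep)
        cols[code] = [base, snp, snp - base, deep, deep - base, best, best - base]
    table = pd.DataFrame(cols, index=ROW_ORDER)
    no_tl = table.loc["Results without transfer learning"].to_numpy()
    deep_tl = table.loc["With deep transfer learning"].to_numpy()
    ttest = pooled_two_sample_ttest(no_tl, deep_tl)
    return ComparisonTable(table=table, ttest=ttest)
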