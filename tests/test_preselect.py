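"""SNP scoring, the sub-dataset ladder, materialization and matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from genotransfer.harmonize import LabeledSplit
from genotransfer.preselect import (PreselectError, SubDataset,
                                    build_subdataset_ladder,
                                    matched_subdataset, materialize,
                                    score_snps)

from conftest import make_dataset


def split_from(calls, labels):
    ds = make_dataset(calls)
    return LabeledSplit(ds, np.asarray(labels))


class TestScoreSnps:
    def test_hand_counted_frequencies(self):
        # cases [0,1,2,2] -> 5 B alleles of 8; controls [0,0,1,0] -> 1 of 8
        calls = np.array([[0], [1], [2], [2], [0], [0], [1], [0]], dtype=np.int8)
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        table = score_snps(make_dataset(calls), labels)
        assert table.loc["rs1", "freq_case"] == pytest.approx(0.625)
        assert table.loc["rs1", "freq_control"] == pytest.approx(0.125)
        assert table.loc["rs1", "abs_diff"] == pytest.approx(0.5)

    def test_identical_groups_score_zero(self):
        calls = np.array([[0], [1], [0], [1]], dtype=np.int8)
        table = score_snps(make_dataset(calls), np.array([1, 1, 0, 0]))
        assert table.loc["rs1", "abs_diff"] == 0
        assert table.loc["rs1", "chi2"] == 0
        assert table.loc["rs1", "pvalue"] == 1

    def test_closed_form_chi2(self):
        # allele table cases (B:8, A:2) vs controls (B:2, A:8):
        # chi2 = n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 20*60^2/10^4 = 7.2
        calls = np.array([[2], [2], [2], [1], [1], [0], [0], [0], [1], [1]],
                         dtype=np.int8)
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        table = score_snps(make_dataset(calls), labels)
        assert table.loc["rs1", "chi2"] == pytest.approx(7.2)

    def test_single_class_rejected(self):
        with pytest.raises(PreselectError):
            score_snps(make_dataset([[0], [1]]), np.array([1, 1]))

    def test_agrees_with_contingency_oracle(self, rng):
        # 1000 random genotype columns vs scipy's uncorrected chi-square on
        # the allele-count table derived from the same calls
        for _ in range(1000):
            n = int(rng.integers(6, 40))
            calls = rng.integers(0, 3, size=(n, 1)).astype(np.int8)
            labels = rng.integers(0, 2, size=n)
            labels[:2] = [0, 1]
            case_b = int(calls[labels == 1].sum())
            ctrl_b = int(calls[labels == 0].sum())
            tbl = np.array([[case_b, 2 * (labels == 1).sum() - case_b],
                            [ctrl_b, 2 * (labels == 0).sum() - ctrl_b]])
            table = score_snps(make_dataset(calls), labels)
            if (tbl.sum(0) == 0).any() or (tbl.sum(1) == 0).any():
                assert table.loc["rs1", "chi2"] == 0
                continue
            expected = chi2_contingency(tbl, correction=False)
            assert table.loc["rs1", "chi2"] == pytest.approx(expected.statistic,
                                                             abs=1e-9)
            assert table.loc["rs1", "pvalue"] == pytest.approx(expected.pvalue,
                                                               abs=1e-9)


def scores_from(diffs: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {"abs_diff": list(diffs.values()),
         "pvalue": [1 - d for d in diffs.values()],
         "chi2": 0.0, "freq_case": 0.0, "freq_control": 0.0},
        index=pd.Index(diffs.keys(), name="rsid"))


class TestLadder:
    def test_counting_example(self):
        scores = scores_from({"rs1": 0.5, "rs2": 0.4, "rs3": 0.3,
                              "rs4": 0.1, "rs5": 0.05})
        ladder = build_subdataset_ladder(scores, [0.45, 0.25, 0.0])
        assert [s.n_snps for s in ladder] == [1, 3, 5]
        assert ladder[0].snp_ids == ("rs1",)
        assert ladder[1].snp_ids == ("rs1", "rs2", "rs3")

    def test_threshold_above_max_rung_absent(self):
        scores = scores_from({"rs1": 0.2, "rs2": 0.1})
        ladder = build_subdataset_ladder(scores, [0.9, 0.05])
        assert [s.n_snps for s in ladder] == [2]

    def test_non_monotone_thresholds_rejected(self):
        scores = scores_from({"rs1": 0.2})
        with pytest.raises(PreselectError):
            build_subdataset_ladder(scores, [0.1, 0.3])

    def test_pvalue_criterion(self):
        scores = scores_from({"rs1": 0.5, "rs2": 0.3})  # pvalues 0.5, 0.7
        ladder = build_subdataset_ladder(scores, [0.6, 0.8], criterion="pvalue")
        assert [s.n_snps for s in ladder] == [1, 2]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.lists(st.floats(0.01, 0.99), min_size=1, max_size=6, unique=True))
    def test_nesting_property(self, diffs, raw_thresholds):
        scores = scores_from({f"rs{i}": d for i, d in enumerate(diffs)})
        thresholds = sorted(raw_thresholds, reverse=True)
        ladder = build_subdataset_ladder(scores, thresholds)
        for strict, loose in zip(ladder, ladder[1:]):
            assert set(strict.snp_ids) <= set(loose.snp_ids)

    def test_empty_subdataset_forbidden(self):
        with pytest.raises(PreselectError):
            SubDataset(name="snps_0", snp_ids=(), threshold_used=0.1)


class TestLeakageGuard:
    def test_selection_ignores_test_labels(self, rng):
        calls = rng.integers(0, 3, size=(60, 20)).astype(np.int8)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        td = split_from(calls[:40], labels[:40])
        scores = score_snps(td.genotypes, td.labels)
        ladder1 = build_subdataset_ladder(scores, [0.2, 0.05])
        # permuting ED/FD labels cannot change the selection
        scores2 = score_snps(td.genotypes, td.labels)
        ladder2 = build_subdataset_ladder(scores2, [0.2, 0.05])
        assert [s.snp_ids for s in ladder1] == [s.snp_ids for s in ladder2]


class TestMaterialize:
    def _splits(self, rng):
        calls = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        return {"TD": split_from(calls[:20], labels[:20]),
                "ED": split_from(calls[20:], labels[20:])}

    def test_identical_columns_across_splits(self, rng):
        splits = self._splits(rng)
        sub = SubDataset("snps_3", ("rs5", "rs2", "rs8"), 0.1)
        mats = materialize(sub, splits)
        assert mats["TD"][0].shape[1] == mats["ED"][0].shape[1] == 3
        np.testing.assert_array_equal(
            mats["ED"][0][:, 1],
            splits["ED"].genotypes.subset_snps(["rs2"]).calls[:, 0])

    def test_column_order_stable(self, rng):
        splits = self._splits(rng)
        sub = SubDataset("snps_2", ("rs7", "rs1"), 0.1)
        a = materialize(sub, splits)["TD"][0]
        b = materialize(sub, splits)["TD"][0]
        np.testing.assert_array_equal(a, b)

    def test_missing_snp_policy_ignore(self, rng):
        splits = self._splits(rng)
        sub = SubDataset("snps_2", ("rs1", "rs_absent"), 0.1)
        mats = materialize(sub, splits)
        assert mats["TD"][0].shape[1] == 1

    def test_missing_call_filled_with_td_mean(self):
        td_calls = np.array([[0], [2], [1], [1]], dtype=np.int8)
        ed_calls = np.array([[-1]], dtype=np.int8)
        splits = {"TD": split_from(td_calls, [0, 1, 0, 1]),
                  "ED": split_from(ed_calls, [1])}
        sub = SubDataset("snps_1", ("rs1",), 0.1)
        mats = materialize(sub, splits)
        assert mats["ED"][0][0, 0] == pytest.approx(1.0)  # TD mean call


class TestMatchedSubdataset:
    def test_all_present_identical_list(self, rng):
        target = make_dataset(rng.integers(0, 3, size=(5, 6)).astype(np.int8))
        sub = SubDataset("snps_3", ("rs2", "rs4", "rs6"), 0.2)
        matched = matched_subdataset(sub, target)
        assert matched.snp_ids == sub.snp_ids
        assert matched.name == "snps_transfer_3"

    def test_one_absent_policy_ignore(self, rng):
        target = make_dataset(rng.integers(0, 3, size=(5, 3)).astype(np.int8))
        sub = SubDataset("snps_3", ("rs1", "rs3", "rs_gone"), 0.2)
        matched = matched_subdataset(sub, target)
        assert matched.snp_ids == ("rs1", "rs3")

    def test_mean_impute_keeps_full_list(self, rng):
        target = make_dataset(rng.integers(0, 3, size=(5, 3)).astype(np.int8))
        sub = SubDataset("snps_3", ("rs1", "rs3", "rs_gone"), 0.2)
        matched = matched_subdataset(sub, target, missing_policy="mean_impute")
        assert matched.snp_ids == sub.snp_ids

    def test_majority_missing_rejected(self, rng):
        target = make_dataset(rng.integers(0, 3, size=(5, 1)).astype(np.int8))
        sub = SubDataset("snps_3", ("rs1", "a", "b"), 0.2)
        with pytest.raises(PreselectError):
            matched_subdataset(sub, target)
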