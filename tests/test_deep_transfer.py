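"""Freeze-plan semantics, transfer prediction, and the selection sweep."""

import numpy as np
import pytest

from genotransfer.deep_transfer import (ArchitectureSpec, FreezePlan,
                                        TrainingConfig, TransferTask,
                                        build_model, enumerate_freeze_plans,
                                        fine_tune, simple_transfer_predict,
                                        sweep_and_select, train_source)
from genotransfer.harmonize import FinalHoldout, LabeledSplit
from genotransfer.preselect import SubDataset

from conftest import make_dataset


def toy_source(model_id=1, n_snps=6, seed=0, epochs=5, n=60):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.integers(0, 3, size=(n, n_snps)).astype(np.float32)
    X[:, 0] = np.where(y == 1, 2, 0)
    cfg = TrainingConfig(epochs=epochs, seed=seed)
    arch = ArchitectureSpec(model_id=model_id, input_dim=n_snps)
    sub = SubDataset(f"snps_{n_snps}", tuple(f"rs{i + 1}" for i in range(n_snps)),
                     0.1)
    return train_source(arch, (X, y), None, cfg, subdataset=sub), (X, y)


class TestFreezePlan:
    def test_prefix_constraint_enforced(self):
        FreezePlan((False, True, True))
        with pytest.raises(ValueError):
            FreezePlan((True, False, True))

    def test_enumeration_excludes_all_trainable(self):
        plans = enumerate_freeze_plans(4)
        assert [p.t for p in plans] == [0, 1, 2, 3]
        plans = enumerate_freeze_plans(4, include_all_trainable=True)
        assert plans[-1].t == 4

    def test_t_counts_trainable(self):
        assert FreezePlan.top_k(5, 2).t == 2
        assert FreezePlan.top_k(5, 2).trainable_mask == (False,) * 3 + (True,) * 2


class TestTransferTask:
    def test_matched_feature_spaces_required(self):
        TransferTask(("rs1", "rs2"), ("rs1", "rs2"))
        with pytest.raises(ValueError):
            TransferTask(("rs1", "rs2"), ("rs2", "rs1"))


class TestFineTune:
    def test_all_frozen_predicts_like_source(self):
        src, (X, y) = toy_source()
        plan = FreezePlan.top_k(src.net.n_layers, 0)
        tuned = fine_tune(src, plan, (X, y), None, TrainingConfig(epochs=4))
        np.testing.assert_array_equal(tuned.net.predict(X), src.net.predict(X))

    def test_zero_epochs_keeps_all_weights(self):
        src, (X, y) = toy_source()
        plan = FreezePlan.top_k(src.net.n_layers, 2)
        tuned = fine_tune(src, plan, (X, y), None, TrainingConfig(epochs=0))
        for w1, w2 in zip(src.net.get_weights(), tuned.net.get_weights()):
            for k in w1:
                np.testing.assert_array_equal(w1[k], w2[k])

    @pytest.mark.parametrize("model_id", [1, 2, 4, 5, 6, 7])
    def test_frozen_prefix_identical_trainable_suffix_updates(self, model_id):
        src, (X, y) = toy_source(model_id=model_id, epochs=2)
        t = 2
        plan = FreezePlan.top_k(src.net.n_layers, t)
        tuned = fine_tune(src, plan, (X, y), None, TrainingConfig(epochs=2))
        sw, tw = src.net.get_weights(), tuned.net.get_weights()
        n_frozen = src.net.n_layers - t
        for li in range(n_frozen):
            for k in sw[li]:
                np.testing.assert_array_equal(sw[li][k], tw[li][k])
        assert any((sw[li][k] != tw[li][k]).any()
                   for li in range(n_frozen, src.net.n_layers) for k in sw[li])

    def test_source_model_never_mutated(self):
        src, (X, y) = toy_source()
        before = src.net.get_weights()
        plan = FreezePlan.top_k(src.net.n_layers, src.net.n_layers - 1)
        fine_tune(src, plan, (X, y), None, TrainingConfig(epochs=3))
        for w1, w2 in zip(before, src.net.get_weights()):
            for k in w1:
                np.testing.assert_array_equal(w1[k], w2[k])


class TestSimpleTransfer:
    def test_identical_data_identical_accuracy(self):
        src, (X, y) = toy_source(epochs=20)
        preds = simple_transfer_predict(src, X)
        np.testing.assert_array_equal(preds, src.net.predict(X))

    def test_column_count_mismatch_rejected(self):
        src, (X, _) = toy_source()
        with pytest.raises(ValueError, match="columns"):
            simple_transfer_predict(src, X[:, :3])


def _labeled(calls, y):
    prefix = np.random.default_rng(abs(hash(calls.tobytes())) % 2**16)
    ids = [f"x{prefix.integers(10**9)}_{i}" for i in range(len(y))]
    return LabeledSplit(make_dataset(calls, sample_ids=ids), np.asarray(y))


class TestSweep:
    def _small_splits(self, rng, n_snps=6):
        def block(n):
            y = rng.integers(0, 2, size=n)
            calls = rng.integers(0, 3, size=(n, n_snps)).astype(np.int8)
            calls[:, 0] = np.where(y == 1, 2, 0)
            return _labeled(calls, y)
        return {"TD": block(30), "VD": block(8), "ED": block(12)}, block(20)

    def test_single_cell_grid_returns_it(self, rng):
        splits, fd_split = self._small_splits(rng)
        src, _ = toy_source(epochs=3)
        res = sweep_and_select([src], splits, FinalHoldout(fd_split),
                               plans=[0], config=TrainingConfig(epochs=0))
        assert res.best_arch.model_id == 1
        assert res.best_plan.t == 0

    def test_fd_accessed_exactly_once(self, rng):
        splits, fd_split = self._small_splits(rng)
        fd = FinalHoldout(fd_split)
        src1, _ = toy_source(model_id=1, epochs=3)
        src2, _ = toy_source(model_id=2, epochs=3)
        sweep_and_select([src1, src2], splits, fd, plans=[0, 1],
                         config=TrainingConfig(epochs=1))
        assert fd.access_count == 1

    def test_injected_best_cell_is_selected(self, rng):
        # an exhaustively better cell (trained to separate) must win the grid
        splits, fd_split = self._small_splits(rng)
        good, _ = toy_source(model_id=1, epochs=40)   # learns the signal
        bad, _ = toy_source(model_id=2, epochs=0)     # untrained
        res = sweep_and_select([bad, good], splits, FinalHoldout(fd_split),
                               plans=[0], config=TrainingConfig(epochs=0))
        ed_by_arch = {arch.model_id: acc for _, arch, _, acc in res.grid}
        assert ed_by_arch[1] >= ed_by_arch[2]
        assert res.best_arch.model_id == \
            max(ed_by_arch, key=lambda k: (ed_by_arch[k], -k))

    def test_deterministic_selection(self, rng):
        results = []
        for _ in range(2):
            rng2 = np.random.default_rng(99)
            splits, fd_split = self._small_splits(rng2)
            src, _ = toy_source(model_id=1, epochs=3, seed=4)
            res = sweep_and_select([src], splits, FinalHoldout(fd_split),
                                   plans=[0, 1, 2],
                                   config=TrainingConfig(epochs=2, seed=4))
            results.append((res.best_plan.t, res.ed_accuracy, res.fd_accuracy))
        assert results[0] == results[1]


class TestSourceTraining:
    def test_strong_signal_learnable(self):
        # at least one architecture reaches >65% on held-out source data
        rng = np.random.default_rng(0)
        n, n_snps = 300, 10
        y = rng.integers(0, 2, size=n)
        X = rng.integers(0, 3, size=(n, n_snps)).astype(np.float32)
        X[:, 2] = np.where(y == 1, rng.integers(1, 3, size=n), 0)
        cfg = TrainingConfig(epochs=15, seed=0)
        best = 0.0
        for mid in (1, 4):
            arch = ArchitectureSpec(model_id=mid, input_dim=n_snps)
            src = train_source(arch, (X[:200], y[:200]), (X[200:], y[200:]), cfg)
            acc = 100 * (src.net.predict(X[200:]) == y[200:]).mean()
            best = max(best, acc)
        assert best > 65

    def test_input_dim_mismatch_rejected(self):
        arch = ArchitectureSpec(model_id=1, input_dim=5)
        with pytest.raises(ValueError):
            train_source(arch, (np.zeros((10, 4)), np.zeros(10, dtype=int)),
                         None, TrainingConfig(epochs=1))
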