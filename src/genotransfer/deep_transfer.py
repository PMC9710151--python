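"""The nine deep architectures, source training, and freeze-plan fine-tuning.

Deep transfer proceeds in three stages: (1) train every architecture on
every sub-dataset rung of the large population and keep all of them;
(2) for each saved source model, re-train it on the small population's
training split under every freeze plan — a frozen bottom prefix of layers
keeps the population-general representation, a trainable top suffix adapts
to the target; (3) select the (rung, architecture, plan) cell with the best
small-population test (ED) accuracy and evaluate the final hold-out once.

Architecture catalogue (input layer feeds the first listed layer):

=========  =======================================================
model_id   layer stack
=========  =======================================================
1          dense 30 -> 10 -> 2
2          dense 80 -> 70 -> 40 -> 10 -> 2
3          dense 80 -> 70 -> 50 -> 20 -> 10 -> 2
4 / 5 / 6  GRU / LSTM / BiLSTM 50 -> 20, then dense 2
7 / 8 / 9  GRU / LSTM / BiLSTM 50 -> 20, then dense 10 -> 5 -> 2
=========  =======================================================

Recurrent models read the SNP vector as a sequence, one SNP per step (one
feature per step), ordered by genomic position.  The output layer is always
width 2 (control, case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .evaluate import accuracy
from .harmonize import FinalHoldout, LabeledSplit
from .nn import BiLSTM, Dense, GRU, LSTM, SequentialNet
from .preselect import SubDataset, materialize

logger = logging.getLogger(__name__)

_DENSE_STACKS = {1: [30, 10, 2], 2: [80, 70, 40, 10, 2], 3: [80, 70, 50, 20, 10, 2]}
_RECURRENT_CELL = {4: GRU, 5: LSTM, 6: BiLSTM, 7: GRU, 8: LSTM, 9: BiLSTM}
_RECURRENT_HEAD = {4: [2], 5: [2], 6: [2], 7: [10, 5, 2], 8: [10, 5, 2], 9: [10, 5, 2]}


@dataclass(frozen=True)
class ArchitectureSpec:
    """One of the nine catalogue architectures for a given input width."""

    model_id: int
    input_dim: int

    def __post_init__(self) -> None:
        if self.model_id not in range(1, 10):
            raise ValueError(f"unknown model_id {self.model_id} (must be 1..9)")
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")

    @property
    def is_recurrent(self) -> bool:
        return self.model_id >= 4

    @property
    def n_weight_layers(self) -> int:
        if self.model_id in _DENSE_STACKS:
            return len(_DENSE_STACKS[self.model_id])
        return 2 + len(_RECURRENT_HEAD[self.model_id])


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings: E epochs of Adam at a fixed learning rate."""

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass(frozen=True)
class FreezePlan:
    """Frozen-prefix trainable mask over weight-bearing layers.

    Layers are counted bottom (input side) to top (output side); the mask is
    constrained to a frozen prefix followed by a trainable suffix.  ``t`` is
    the number of trainable (top) layers.
    """

    trainable_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        mask = tuple(bool(m) for m in self.trainable_mask)
        object.__setattr__(self, "trainable_mask", mask)
        # frozen prefix, trainable suffix: mask must be non-decreasing
        if any(a and not b for a, b in zip(mask, mask[1:])):
            raise ValueError("mask must be a frozen prefix followed by a "
                             "trainable suffix (bottom to top)")

    @property
    def t(self) -> int:
        return sum(self.trainable_mask)

    @property
    def n_layers(self) -> int:
        return len(self.trainable_mask)

    @classmethod
    def top_k(cls, n_layers: int, t: int) -> "FreezePlan":
        if not (0 <= t <= n_layers):
            raise ValueError("t must be in [0, n_layers]")
        return cls(tuple([False] * (n_layers - t) + [True] * t))


def enumerate_freeze_plans(n_layers: int, include_all_trainable: bool = False):
    """All frozen-prefix plans, t = 0 .. n_layers-1 trainable top layers.

    The all-trainable plan (t = n_layers) is excluded from transfer selection
    by default — transferring and then unfreezing everything discards what
    was transferred — but can be included as a diagnostic.
    """
    top = n_layers + 1 if include_all_trainable else n_layers
    return [FreezePlan.top_k(n_layers, t) for t in range(top)]


@dataclass(frozen=True)
class TransferTask:
    """Domain/task bookkeeping for one transfer experiment.

    A domain is a feature space (the ordered SNP list of a sub-dataset,
    standing in for X and the population's marginal P(X)); a task is the
    binary label space plus the predictor learned on it.  Source and target
    must share the same ordered SNP list.
    """

    source_domain: tuple[str, ...]
    target_domain: tuple[str, ...]
    source_task: str = "case_control"
    target_task: str = "case_control"

    def __post_init__(self) -> None:
        if tuple(self.source_domain) != tuple(self.target_domain):
            raise ValueError("source and target feature spaces must share the "
                             "same ordered SNP list")


def build_model(arch: ArchitectureSpec, seed: int = 0,
                dtype=np.float32) -> SequentialNet:
    """Instantiate one catalogue architecture with seeded initialisation."""
    rng = np.random.default_rng(seed)
    layers = []
    if arch.model_id in _DENSE_STACKS:
        n_in = arch.input_dim
        widths = _DENSE_STACKS[arch.model_id]
        for i, w in enumerate(widths):
            act = "linear" if i == len(widths) - 1 else "relu"
            layers.append(Dense(n_in, w, activation=act, rng=rng, dtype=dtype))
            n_in = w
    else:
        cell = _RECURRENT_CELL[arch.model_id]
        layers.append(cell(1, 50, return_sequences=True, rng=rng, dtype=dtype))
        out1 = 100 if cell is BiLSTM else 50
        layers.append(cell(out1, 20, return_sequences=False, rng=rng, dtype=dtype))
        n_in = 40 if cell is BiLSTM else 20
        widths = _RECURRENT_HEAD[arch.model_id]
        for i, w in enumerate(widths):
            act = "linear" if i == len(widths) - 1 else "relu"
            layers.append(Dense(n_in, w, activation=act, rng=rng, dtype=dtype))
            n_in = w
    return SequentialNet(layers)


@dataclass
class SourceModel:
    """A model trained on the large population, ready for transfer."""

    net: SequentialNet
    arch: ArchitectureSpec
    subdataset: SubDataset
    config: TrainingConfig
    ed_accuracy: float | None = None
    history: dict = field(default_factory=dict, repr=False)


def train_source(
    arch: ArchitectureSpec,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray] | None,
    config: TrainingConfig,
    subdataset: SubDataset | None = None,
) -> SourceModel:
    """Train one architecture on the large population's training split."""
    X, y = train
    if X.shape[1] != arch.input_dim:
        raise ValueError(f"input_dim {arch.input_dim} != feature count {X.shape[1]}")
    net = build_model(arch, seed=config.seed)
    kwargs = {}
    if val is not None:
        kwargs = {"X_val": val[0], "y_val": val[1]}
    history = net.fit(X, y, epochs=config.epochs, batch_size=config.batch_size,
                      lr=config.learning_rate, seed=config.seed, **kwargs)
    sub = subdataset or SubDataset(name=f"snps_{arch.input_dim}",
                                   snp_ids=tuple(f"f{i}" for i in range(arch.input_dim)),
                                   threshold_used=float("nan"))
    return SourceModel(net=net, arch=arch, subdataset=sub, config=config,
                       history=history)


def simple_transfer_predict(source: SourceModel, X_target: np.ndarray) -> np.ndarray:
    """Predict the target population with the source model, no weight updates.

    The target matrix must carry exactly the source sub-dataset's SNP columns
    in the source order (the contract enforced by ``matched_subdataset`` /
    ``materialize``).
    """
    X_target = np.asarray(X_target)
    if X_target.shape[1] != source.arch.input_dim:
        raise ValueError(
            f"target has {X_target.shape[1]} SNP columns, source model expects "
            f"{source.arch.input_dim}: columns must match the source sub-dataset"
        )
    return source.net.predict(X_target)


def fine_tune(
    source: SourceModel,
    plan: FreezePlan,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray] | None,
    config: TrainingConfig,
) -> SourceModel:
    """Re-train a copy of the source model on target data under a freeze plan.

    Frozen layers keep their source weights exactly; the source model itself
    is never mutated.  An all-frozen plan (or ``epochs=0``) returns a model
    that predicts identically to the source.
    """
    if plan.n_layers != source.net.n_layers:
        raise ValueError(f"plan covers {plan.n_layers} layers, model has "
                         f"{source.net.n_layers}")
    net = source.net.copy()
    net.set_trainable(list(plan.trainable_mask))
    X, y = train
    kwargs = {"X_val": val[0], "y_val": val[1]} if val is not None else {}
    history = net.fit(X, y, epochs=config.epochs, batch_size=config.batch_size,
                      lr=config.learning_rate, seed=config.seed, **kwargs)
    return SourceModel(net=net, arch=source.arch, subdataset=source.subdataset,
                       config=config, history=history)


@dataclass
class DeepSelectionResult:
    """Best (rung, architecture, freeze plan) cell and its ED/FD accuracies."""

    best_subdataset: SubDataset
    best_arch: ArchitectureSpec
    best_plan: FreezePlan
    ed_accuracy: float
    fd_accuracy: float
    grid: list = field(default_factory=list, repr=False)


def _plans_for(n_layers: int, plans) -> list[FreezePlan]:
    """Resolve a plan request against one model's depth.

    ``plans`` may be None (enumerate t = 0..n_layers-1), a list of ints
    (trainable-top-layer counts, clamped below all-trainable), or explicit
    FreezePlan objects whose t is re-applied at this depth.
    """
    if plans is None:
        return enumerate_freeze_plans(n_layers)
    resolved = []
    for p in plans:
        t = p if isinstance(p, int) else p.t
        plan = FreezePlan.top_k(n_layers, min(t, n_layers - 1))
        if plan not in resolved:
            resolved.append(plan)
    return resolved


def sweep_and_select(
    source_models: list[SourceModel],
    small_splits: dict[str, LabeledSplit],
    fd: FinalHoldout,
    plans=None,
    config: TrainingConfig | None = None,
) -> DeepSelectionResult:
    """Fine-tune every source model under every plan; select on ED, test FD once.

    ``plans`` may be trainable-top-layer counts (ints), FreezePlan objects, or
    None for the full t = 0..L-1 enumeration.  Ties on ED accuracy are broken
    deterministically: fewer SNPs, then smaller model_id, then more frozen
    layers (smaller t).
    """
    if not source_models:
        raise ValueError("no source models to transfer")
    config = config or TrainingConfig()
    grid = []
    tuned_models = {}
    target_mats = {}
    for src in source_models:
        sub = src.subdataset
        if sub.name not in target_mats:
            target_mats[sub.name] = materialize(sub, small_splits)
        mats = target_mats[sub.name]
        for plan in _plans_for(src.net.n_layers, plans):
            tuned = fine_tune(src, plan, mats["TD"], mats.get("VD"), config)
            ed_acc = accuracy(tuned.net.predict(mats["ED"][0]), mats["ED"][1])
            grid.append((sub, src.arch, plan, ed_acc))
            tuned_models[(sub.name, src.arch.model_id, plan.t)] = tuned
    sub, arch, plan, ed_acc = min(
        grid, key=lambda c: (-c[3], c[0].n_snps, c[1].model_id, c[2].t))

    fd_split = fd.access()
    fd_mat = materialize(sub, {"TD": small_splits["TD"], "FD": fd_split})["FD"]
    best = tuned_models[(sub.name, arch.model_id, plan.t)]
    fd_acc = accuracy(best.net.predict(fd_mat[0]), fd_mat[1])
    logger.info("deep transfer: %s/model%d/t=%d ED=%.1f FD=%.1f",
                sub.name, arch.model_id, plan.t, ed_acc, fd_acc)
    return DeepSelectionResult(sub, arch, plan, ed_acc, fd_acc, grid=grid)
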