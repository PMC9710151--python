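"""The five classical baselines and the sub-dataset selection procedure.

Model families: support vector machine (SVM), decision tree (CART), random
undersampling + tree bagging (RUS), random forest (FOREST), and a bagging
classifier (BAGGING).  Each sub-dataset rung is trained with all five kinds;
the (rung, kind) pair with the best test-split (ED) accuracy is selected and
the final hold-out (FD) is evaluated exactly once, after selection.

Two procedures are built on this:

* :func:`run_small_baseline` — train/select/report entirely within the small
  population ("without transfer learning").
* :func:`run_snp_transfer` — SNP transfer: rungs are selected on the LARGE
  population's training data, models are trained on the large population and
  evaluated directly on the small population's ED/FD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluate import accuracy
from .harmonize import FinalHoldout, LabeledSplit
from .preselect import SubDataset, materialize

logger = logging.getLogger(__name__)

#: Fixed model order, also the tie-break order in selection.
MODEL_KINDS = ("SVM", "CART", "RUS", "FOREST", "BAGGING")


class RandomUnderSampleBagging(BaseEstimator, ClassifierMixin):
    """Bagging of decision trees, each fit on a class-balanced undersample.

    For each estimator the majority class is randomly undersampled to the
    minority class size before fitting a tree; prediction is a majority vote.
    """

    def __init__(self, n_estimators: int = 10, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.random_state)
        counts = {c: int((y == c).sum()) for c in self.classes_}
        n_min = min(counts.values())
        self.estimators_ = []
        for k in range(self.n_estimators):
            idx = np.concatenate([
                rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
                for c in self.classes_
            ])
            tree = DecisionTreeClassifier(random_state=int(rng.integers(2**31 - 1)))
            self.estimators_.append(tree.fit(X[idx], y[idx]))
        return self

    def predict(self, X):
        votes = np.stack([est.predict(np.asarray(X)) for est in self.estimators_])
        # majority vote; ties go to the lower class label
        out = np.empty(votes.shape[1], dtype=self.classes_.dtype)
        for j in range(votes.shape[1]):
            vals, cnt = np.unique(votes[:, j], return_counts=True)
            out[j] = vals[np.argmax(cnt)]
        return out


@dataclass(frozen=True)
class ClassicModelSpec:
    """One of the five classical model kinds plus hyperparameters and seed."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")

    def build(self):
        hp = dict(self.hyperparameters)
        if self.kind == "SVM":
            return SVC(random_state=self.seed, **hp)
        if self.kind == "CART":
            return DecisionTreeClassifier(random_state=self.seed, **hp)
        if self.kind == "RUS":
            return RandomUnderSampleBagging(random_state=self.seed, **hp)
        if self.kind == "FOREST":
            return RandomForestClassifier(random_state=self.seed, **hp)
        return BaggingClassifier(random_state=self.seed, **hp)


def train_classic(spec: ClassicModelSpec, X_train: np.ndarray, y_train: np.ndarray):
    """Fit one classical model; requires both classes in the labels."""
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    return spec.build().fit(np.asarray(X_train, dtype=float), y_train)


@dataclass
class SelectionResult:
    """The selected (sub-dataset, model) pair and its ED/FD accuracies."""

    best_subdataset: SubDataset
    best_model: ClassicModelSpec | object
    ed_accuracy: float
    fd_accuracy: float
    arm: str = ""
    grid: list = field(default_factory=list, repr=False)


def select_best(candidates: list[tuple[SubDataset, ClassicModelSpec, float]]):
    """Arg-max ED accuracy; ties broken by fewer SNPs, then fixed model order.

    Invariant to the enumeration order of ``candidates``.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    return min(
        candidates,
        key=lambda c: (-c[2], c[0].n_snps, MODEL_KINDS.index(c[1].kind)),
    )


def _fit_grid(ladder, train_data, ed_data, seed):
    """Train all 5 kinds on every rung; returns (grid rows, fitted models)."""
    grid, fitted = [], {}
    for sub in ladder:
        X_tr, y_tr = train_data[sub.name]
        X_ed, y_ed = ed_data[sub.name]
        for kind in MODEL_KINDS:
            spec = ClassicModelSpec(kind=kind, seed=seed)
            model = train_classic(spec, X_tr, y_tr)
            ed_acc = accuracy(model.predict(X_ed), y_ed)
            grid.append((sub, spec, ed_acc))
            fitted[(sub.name, kind)] = model
    return grid, fitted


def run_small_baseline(
    small_splits: dict[str, LabeledSplit],
    fd: FinalHoldout,
    ladder: list[SubDataset],
    seed: int = 0,
) -> SelectionResult:
    """The no-transfer baseline: train, select and test within the small population."""
    materialized = {sub.name: materialize(sub, small_splits) for sub in ladder}
    train_data = {n: m["TD"] for n, m in materialized.items()}
    ed_data = {n: m["ED"] for n, m in materialized.items()}
    grid, fitted = _fit_grid(ladder, train_data, ed_data, seed)
    sub, spec, ed_acc = select_best(grid)

    fd_split = fd.access()
    fd_mat = materialize(sub, {"TD": small_splits["TD"], "FD": fd_split})["FD"]
    model = fitted[(sub.name, spec.kind)]
    fd_acc = accuracy(model.predict(fd_mat[0]), fd_mat[1])
    logger.info("baseline: %s/%s ED=%.1f FD=%.1f", sub.name, spec.kind, ed_acc, fd_acc)
    return SelectionResult(sub, spec, ed_acc, fd_acc, arm="no_transfer", grid=grid)


def run_snp_transfer(
    large_splits: dict[str, LabeledSplit],
    small_splits: dict[str, LabeledSplit],
    fd: FinalHoldout,
    large_ladder: list[SubDataset],
    seed: int = 0,
    refit_on_target: bool = False,
) -> SelectionResult:
    """SNP transfer: large-population SNPs (and models) applied to the small one.

    Rungs come from the LARGE population's training data.  By default the
    classifier itself is also transferred (trained on the large population's
    TD, tested on the small population's ED/FD); with ``refit_on_target``
    the selected SNPs are kept but the model is refit on the small TD.
    """
    train_pop = "small" if refit_on_target else "large"
    grid, fitted = [], {}
    for sub in large_ladder:
        tr_split = small_splits["TD"] if refit_on_target else large_splits["TD"]
        mats = materialize(sub, {"TD": tr_split, "ED": small_splits["ED"]})
        X_tr, y_tr = mats["TD"]
        X_ed, y_ed = mats["ED"]
        for kind in MODEL_KINDS:
            spec = ClassicModelSpec(kind=kind, seed=seed)
            model = train_classic(spec, X_tr, y_tr)
            grid.append((sub, spec, accuracy(model.predict(X_ed), y_ed)))
            fitted[(sub.name, kind)] = model
    sub, spec, ed_acc = select_best(grid)

    fd_split = fd.access()
    tr_split = small_splits["TD"] if refit_on_target else large_splits["TD"]
    fd_mat = materialize(sub, {"TD": tr_split, "FD": fd_split})["FD"]
    model = fitted[(sub.name, spec.kind)]
    fd_acc = accuracy(model.predict(fd_mat[0]), fd_mat[1])
    logger.info("snp transfer (train on %s): %s/%s ED=%.1f FD=%.1f",
                train_pop, sub.name, spec.kind, ed_acc, fd_acc)
    return SelectionResult(sub, spec, ed_acc, fd_acc, arm="snp_transfer", grid=grid)
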