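"""Class balancing, probability classifiers, and repeated stratified CV.

The class imbalance is handled by partition ensembling: the majority class
is dealt into minority-sized parts, one model is trained per part plus the
full minority class, and the ensemble probability is the mean of the
sub-models' class-1 probabilities. Feature screening runs inside every
training fold, so validation rows never influence which features are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import evaluation
from .facts import ADRClassLabels, FactsMatrix
from .selection import select_features

_FAMILIES = ("svm_rbf", "logistic")


@dataclass(frozen=True)
class ModelSpec:
    """Classifier family plus the few hyperparameters that matter.

    svm_rbf uses a Gaussian radial-basis kernel with cost C (default 1) and
    gamma defaulting to 1/n_features, the conventional RBF defaults;
    logistic regression is unpenalized.
    """

    family: str = "svm_rbf"
    cost: float = 1.0
    gamma: float | None = None  # None -> 1 / n_features

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.cost <= 0:
            raise ValueError("cost must be > 0")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    def build(self, n_features: int, calibration_cv: int = 5):
        if self.family == "svm_rbf":
            gamma = self.gamma if self.gamma is not None else 1.0 / max(n_features, 1)
            base = SVC(kernel="rbf", C=self.cost, gamma=gamma)
            # Platt-scaled probabilities from the margin, fitted on internal
            # (deterministic, unshuffled) stratified folds
            return CalibratedClassifierCV(base, method="sigmoid",
                                          cv=calibration_cv, ensemble=False)
        # C=inf: unpenalized maximum-likelihood fit
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)


@dataclass
class FoldResult:
    repeat: int
    fold: int
    drug_ids: list[str]
    y_true: np.ndarray
    y_prob: np.ndarray
    n_features: int


@dataclass
class CVResult:
    """Out-of-fold probabilities per (repeat, fold) plus pooled metrics."""

    folds: list[FoldResult]
    repeats: int
    tau: float = 0.5
    repeat_metrics: list[dict[str, float]] = field(default_factory=list)

    def pooled(self, repeat: int) -> tuple[np.ndarray, np.ndarray]:
        fs = [f for f in self.folds if f.repeat == repeat]
        y = np.concatenate([f.y_true for f in fs])
        p = np.concatenate([f.y_prob for f in fs])
        return p, y

    def compute_metrics(self) -> None:
        self.repeat_metrics = []
        for r in range(self.repeats):
            scores, y = self.pooled(r)
            auc = evaluation.roc_auc(scores, y)
            acc, sen, spe = evaluation.threshold_metrics(scores, y, self.tau)
            self.repeat_metrics.append(
                {"auc": auc, "acc": acc, "sen": sen, "spe": spe})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CVResult) or self.repeats != other.repeats:
            return False
        if len(self.folds) != len(other.folds):
            return False
        for a, b in zip(self.folds, other.folds):
            if (a.repeat, a.fold, a.drug_ids) != (b.repeat, b.fold, b.drug_ids):
                return False
            if not (np.array_equal(a.y_true, b.y_true)
                    and np.array_equal(a.y_prob, b.y_prob)):
                return False
        return True


def partition_major_class(major_ids: list, minor_size: int,
                          rng: np.random.Generator) -> list[list]:
    """Deal the majority class into minority-sized, size-balanced parts.

    The number of parts is ``max(1, round(len(major)/minor_size))``; ids are
    shuffled then dealt so part sizes differ by at most one. Parts are
    pairwise disjoint and cover the majority class.
    """
    if minor_size < 1:
        raise ValueError("minor_size must be >= 1")
    if not major_ids:
        raise ValueError("major_ids must be non-empty")
    n_parts = max(1, round(len(major_ids) / minor_size))
    shuffled = [major_ids[i] for i in rng.permutation(len(major_ids))]
    return [list(part) for part in np.array_split(np.array(shuffled, dtype=object),
                                                  n_parts)]


def fit_predict_balanced(train_X: np.ndarray, train_y: np.ndarray,
                         test_X: np.ndarray, spec: ModelSpec,
                         rng: np.random.Generator) -> np.ndarray:
    """Partition-ensemble fit: one model per balanced set, mean probability."""
    train_y = np.asarray(train_y)
    classes = np.unique(train_y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    idx = np.arange(train_y.size)
    pos, neg = idx[train_y == 1], idx[train_y == 0]
    minor, major = (pos, neg) if pos.size <= neg.size else (neg, pos)
    parts = partition_major_class(list(major), minor.size, rng)
    probs = np.zeros(test_X.shape[0], dtype=float)
    for part in parts:
        rows = np.concatenate([np.asarray(part, dtype=int), minor])
        counts = np.bincount(train_y[rows].astype(int), minlength=2)
        smallest = int(counts[counts > 0].min())
        if smallest < 2:
            raise ValueError("each class needs >= 2 training samples for "
                             "probability calibration")
        model = spec.build(train_X.shape[1], calibration_cv=min(5, smallest))
        model.fit(train_X[rows], train_y[rows])
        one = int(np.flatnonzero(model.classes_ == 1)[0])
        probs += model.predict_proba(test_X)[:, one]
    return probs / len(parts)


def cross_validate(X: FactsMatrix, y: ADRClassLabels, spec: ModelSpec,
                   folds: int = 10, repeats: int = 3, alpha: float = 0.05,
                   rng: np.random.Generator | int = 0,
                   global_selection: bool = False) -> CVResult:
    """Repeated stratified k-fold CV with in-fold screening and balancing.

    Per repeat, drugs are dealt into ``folds`` stratified folds; per fold the
    training rows alone undergo feature screening at ``alpha``, then
    majority-class balancing and ensemble fitting; the untouched validation
    fold is scored. When no feature passes the screen, the fold predicts the
    training prevalence for every validation drug.

    ``global_selection=True`` screens once on the full data instead (leaky;
    provided for compatibility experiments only).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if X.drug_ids != y.drug_ids:
        raise ValueError("rows of X are not aligned with labels")
    labels = y.labels
    n_pos, n_neg = int(labels.sum()), int((labels == 0).sum())
    if min(n_pos, n_neg) < folds:
        raise ValueError(
            f"the smaller class has {min(n_pos, n_neg)} members, fewer than "
            f"{folds} folds; use fewer folds")

    global_cols: np.ndarray | None = None
    if global_selection:
        sel = select_features(X, y, alpha)
        keep = {s.feature_id for s in sel}
        global_cols = np.array(
            [j for j, f in enumerate(X.feature_ids) if f in keep], dtype=int)

    fold_results: list[FoldResult] = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31 - 1)))
        for k, (tr, va) in enumerate(skf.split(X.values, labels)):
            tr_y = labels[tr]
            if global_cols is not None:
                cols = global_cols
            else:
                train_facts = FactsMatrix(
                    [X.drug_ids[i] for i in tr],
                    list(X.feature_ids), X.values[tr], X.feature_kind)
                train_labels = ADRClassLabels(
                    [X.drug_ids[i] for i in tr], tr_y)
                sel = select_features(train_facts, train_labels, alpha)
                keep = {s.feature_id for s in sel}
                cols = np.array(
                    [j for j, f in enumerate(X.feature_ids) if f in keep],
                    dtype=int)
            if cols.size == 0:
                prob = np.full(va.size, tr_y.mean())
            else:
                prob = fit_predict_balanced(
                    X.values[tr][:, cols].astype(float), tr_y,
                    X.values[va][:, cols].astype(float), spec, rng)
            fold_results.append(FoldResult(
                repeat=rep, fold=k,
                drug_ids=[X.drug_ids[i] for i in va],
                y_true=labels[va].copy(), y_prob=prob,
                n_features=int(cols.size)))
    result = CVResult(folds=fold_results, repeats=repeats)
    result.compute_metrics()
    return result
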