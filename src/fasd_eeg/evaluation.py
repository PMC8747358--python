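"""Resampling evaluation: repeated shuffled splits, k-fold CV, confusion matrix.

The primary protocol is repeated random subsampling: for each of
``n_trials`` (default 1000) trials, 30 subjects per class are drawn for
training and a disjoint 20 per class for testing, the classifier is
refitted and scored, and per-trial accuracies plus pooled confusion
counts are accumulated.  Stratified 4-fold cross-validation is reported
alongside as a secondary check.  Confusion percentages are normalised per
true class (TP+FN = 100 over the study class, TN+FP = 100 over controls).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nbayes
from .core import ParameterError
from .features import FeatureMatrix

POSITIVE_CLASS = "fasd"  # the study class: "positive" means flagged as affected


@dataclass(frozen=True)
class SplitPlan:
    """Shape of the repeated stratified subsampling protocol."""

    n_train_per_class: int = 30
    n_test_per_class: int = 20
    n_trials: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train_per_class, self.n_test_per_class, self.n_trials) <= 0:
            raise ParameterError("split counts and trials must be positive")


@dataclass(frozen=True)
class EvalReport:
    """Results of the repeated-subsampling evaluation (plus optional CV)."""

    per_trial_accuracies: np.ndarray
    mean_accuracy: float
    sd_accuracy: float
    confusion: dict[str, float]  # tp, fn, tn, fp as percentages
    n_trials: int
    kfold_accuracy: float | None = None

    def to_dict(self) -> dict:
        d = {
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "confusion": self.confusion,
            "n_trials": self.n_trials,
            "kfold_accuracy": self.kfold_accuracy,
            "per_trial_accuracies": np.asarray(self.per_trial_accuracies).tolist(),
        }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _class_indices(labels: tuple[str, ...]) -> dict[str, np.ndarray]:
    labels_arr = np.asarray(labels)
    return {c: np.flatnonzero(labels_arr == c) for c in dict.fromkeys(labels)}


def shuffle_split(
    matrix: FeatureMatrix, plan: SplitPlan, trial_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified disjoint train/test row indices for one trial.

    Deterministic given ``(plan.seed, trial_index)``: each trial draws from
    an independent substream ``seed + trial_index``.
    """
    rng = np.random.default_rng(plan.seed + trial_index)
    train, test = [], []
    for c, idx in _class_indices(matrix.labels).items():
        need = plan.n_train_per_class + plan.n_test_per_class
        if idx.size < need:
            raise ParameterError(
                f"class {c!r} has {idx.size} subjects, need {need} for the plan"
            )
        perm = rng.permutation(idx)
        train.append(perm[: plan.n_train_per_class])
        test.append(perm[plan.n_train_per_class : need])
    return np.concatenate(train), np.concatenate(test)


def confusion_percentages(y_true, y_pred, positive: str = POSITIVE_CLASS) -> dict[str, float]:
    """Per-true-class normalised confusion percentages.

    ``tp`` is the percentage of true study-class items predicted as the
    study class (so tp + fn = 100); ``tn`` the percentage of true controls
    predicted control (tn + fp = 100).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ParameterError("label sequences must be non-empty and aligned")
    pos = y_true == positive
    if not pos.any() or pos.all():
        raise ParameterError("need both classes present in y_true")
    tp = 100.0 * np.mean(y_pred[pos] == positive)
    tn = 100.0 * np.mean(y_pred[~pos] != positive)
    return {"tp": tp, "fn": 100.0 - tp, "tn": tn, "fp": 100.0 - tn}


def repeated_evaluation(matrix: FeatureMatrix, plan: SplitPlan) -> EvalReport:
    """Run the full repeated-subsampling protocol.

    Confusion counts are summed over all trials and then normalised (rather
    than averaging per-trial percentages); with balanced test sets of fixed
    size the two pooling rules coincide.
    """
    X = matrix.values
    y = np.asarray(matrix.labels)
    accs = np.empty(plan.n_trials)
    pos_correct = pos_total = neg_correct = neg_total = 0
    for t in range(plan.n_trials):
        tr, te = shuffle_split(matrix, plan, t)
        model = nbayes.fit(X[tr], y[tr])
        pred = nbayes.predict(model, X[te])
        truth = y[te]
        accs[t] = np.mean(pred == truth)
        pos = truth == POSITIVE_CLASS
        pos_correct += int(np.sum(pred[pos] == POSITIVE_CLASS))
        pos_total += int(pos.sum())
        neg_correct += int(np.sum(pred[~pos] != POSITIVE_CLASS))
        neg_total += int((~pos).sum())
    tp = 100.0 * pos_correct / pos_total
    tn = 100.0 * neg_correct / neg_total
    return EvalReport(
        per_trial_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if plan.n_trials > 1 else 0.0,
        confusion={"tp": tp, "fn": 100.0 - tp, "tn": tn, "fp": 100.0 - tn},
        n_trials=plan.n_trials,
    )


def kfold_cv(matrix: FeatureMatrix, k: int = 4, seed: int = 0) -> float:
    """Stratified k-fold cross-validated accuracy (mean over held-out folds)."""
    if k < 2:
        raise ParameterError("k must be at least 2")
    X = matrix.values
    y = np.asarray(matrix.labels)
    rng = np.random.default_rng(seed)
    folds: list[list[np.ndarray]] = [[] for _ in range(k)]
    for c, idx in _class_indices(matrix.labels).items():
        if idx.size < k:
            raise ParameterError(f"class {c!r} has {idx.size} < k={k} subjects")
        perm = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(perm, k)):
            folds[f].append(chunk)
    fold_accs = []
    for f in range(k):
        test = np.concatenate(folds[f])
        train = np.concatenate(
            [np.concatenate(folds[g]) for g in range(k) if g != f]
        )
        model = nbayes.fit(X[train], y[train])
        fold_accs.append(float(np.mean(nbayes.predict(model, X[test]) == y[test])))
    return float(np.mean(fold_accs))
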