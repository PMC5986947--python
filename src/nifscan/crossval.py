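"""Validation harnesses: stratified k-fold CV, jackknife (leave-one-out)
multi-class evaluation, and repeated balanced-undersampling CV for the
imbalanced nif / non-nif problem.

The balanced harness addresses the fact that in a real proteome the
negative (non-nif) class outnumbers the positive class by orders of
magnitude: each of M sample sets draws exactly |pos| negatives at random
without replacement, runs stratified k-fold CV on the balanced set, and the
reported figures are the mean and standard error of the per-set means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .encoders import FeatureMatrix, concat_matrices
from .metrics import (
    METRIC_NAMES,
    MetricSet,
    confusion_counts,
    mean_metrics,
    metrics_from_counts,
)
from .svm import KernelSpec, predict_scores, train_svm

__all__ = [
    "CVResult",
    "MulticlassReport",
    "stratified_folds",
    "kfold_cv",
    "jackknife_cv",
    "balanced_resampling_cv",
]


@dataclass(frozen=True)
class CVResult:
    """Per-unit metric sets (folds, or sample-set means) with their grand
    mean and standard error."""

    per_unit: tuple[MetricSet, ...]
    mean: MetricSet
    se: MetricSet
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        blob = {
            "config": self.config,
            "per_unit": [m.as_dict() for m in self.per_unit],
            "mean": self.mean.as_dict(),
            "se": self.se.as_dict(),
        }
        with open(path, "w") as fh:
            json.dump(blob, fh, indent=2)


@dataclass(frozen=True)
class MulticlassReport:
    """Aggregated multi-class confusion matrix (rows = true, columns =
    predicted) with per-class one-vs-rest metrics."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    per_class: dict[str, MetricSet]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def diagonal_fraction(self) -> float:
        return float(np.trace(self.matrix) / self.matrix.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels), columns=list(self.labels))

    def metrics_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {lab: m.as_dict() for lab, m in self.per_class.items()}
        ).T[list(METRIC_NAMES)]


def stratified_folds(
    y: Sequence[str], k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold split indices (train, test) per fold.

    The test folds partition the dataset: every sample is tested exactly
    once; folds hold approximately equal class proportions.
    """
    y = np.asarray(y, dtype=object)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot build {k} stratified folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def kfold_cv(
    X: FeatureMatrix,
    y: Sequence[str],
    k: int = 5,
    kernel: KernelSpec = KernelSpec(),
    seed: int = 0,
    positive_label: str | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of a binary SVM.

    ``positive_label`` defaults to ``"nif"`` when present, else the
    canonically first label.
    """
    y = np.asarray(y, dtype=object)
    labels = sorted(np.unique(y).tolist())
    if positive_label is None:
        positive_label = "nif" if "nif" in labels else labels[0]
    per_fold = []
    for tr, te in stratified_folds(y, k, seed):
        model = train_svm(X.take(tr), y[tr], kernel=kernel, seed=seed)
        preds = [s.label for s in predict_scores(model, X.take(te))]
        per_fold.append(
            metrics_from_counts(confusion_counts(y[te], preds, positive_label))
        )
    mean, se = mean_metrics(per_fold)
    return CVResult(
        per_unit=tuple(per_fold),
        mean=mean,
        se=se,
        config={"k": k, "seed": seed, "kernel": kernel.name,
                "positive_label": positive_label, "n": len(y)},
    )


def jackknife_cv(
    X: FeatureMatrix,
    y: Sequence[str],
    kernel: KernelSpec = KernelSpec(),
    seed: int = 0,
) -> MulticlassReport:
    """Leave-one-out evaluation of the multi-class SVM.

    Each sample is predicted by a model trained on all others; the n
    predictions are aggregated into one confusion matrix, and per-class
    metrics treat that class as positive against the rest.
    """
    y = np.asarray(y, dtype=object)
    labels, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        small = labels[counts < 2].tolist()
        raise ValueError(f"jackknife needs >= 2 members per class; too small: {small}")
    n = len(y)
    if n < 3:
        raise ValueError("jackknife needs at least 3 samples")
    labels = tuple(sorted(labels.tolist()))
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    matrix = np.zeros((len(labels), len(labels)), dtype=int)
    all_idx = np.arange(n)
    for i in range(n):
        tr = np.delete(all_idx, i)
        model = train_svm(X.take(tr), y[tr], kernel=kernel, seed=seed)
        pred = predict_scores(model, X.take([i]))[0].label
        matrix[lab_idx[y[i]], lab_idx[pred]] += 1
    per_class = {}
    for lab in labels:
        r = lab_idx[lab]
        n_pos = int(matrix[r].sum())
        tp = int(matrix[r, r])
        fp = int(matrix[:, r].sum() - tp)
        per_class[lab] = metrics_from_counts(
            confusion_counts_from_ovr(n_pos=n_pos, n_neg=n - n_pos, tp=tp, fp=fp)
        )
    return MulticlassReport(labels=labels, matrix=matrix, per_class=per_class)


def confusion_counts_from_ovr(n_pos: int, n_neg: int, tp: int, fp: int):
    """One-vs-rest collapse of a multi-class matrix row/column into counts."""
    from .metrics import ConfusionCounts

    return ConfusionCounts(n_pos=n_pos, n_neg=n_neg, fp=fp, fn=n_pos - tp)


def balanced_resampling_cv(
    pos: FeatureMatrix,
    neg: FeatureMatrix,
    M: int = 100,
    k: int = 5,
    kernel: KernelSpec = KernelSpec(),
    seed: int = 0,
    pos_label: str = "nif",
    neg_label: str = "non-nif",
) -> CVResult:
    """Repeated balanced-undersampling CV of the binary classifier.

    For m = 1..M, draws |pos| negatives without replacement (seeded by
    ``seed + m``), runs stratified k-fold CV on the balanced set, and
    records the per-set mean metrics. Returns the M per-set means with
    their grand mean and standard error.
    """
    if len(neg) < len(pos):
        raise ValueError(
            f"negative pool ({len(neg)}) must be at least as large as the "
            f"positive set ({len(pos)})"
        )
    if M < 1:
        raise ValueError("M must be >= 1")
    per_set = []
    for m in range(1, M + 1):
        rng = np.random.default_rng(seed + m)
        sel = np.sort(rng.choice(len(neg), size=len(pos), replace=False))
        Xm = concat_matrices(pos, neg.take(sel))
        ym = np.array([pos_label] * len(pos) + [neg_label] * len(pos), dtype=object)
        res = kfold_cv(Xm, ym, k=k, kernel=kernel, seed=seed + m,
                       positive_label=pos_label)
        per_set.append(res.mean)
    mean, se = mean_metrics(per_set)
    return CVResult(
        per_unit=tuple(per_set),
        mean=mean,
        se=se,
        config={"M": M, "k": k, "seed": seed, "kernel": kernel.name,
                "n_pos": len(pos), "n_neg_pool": len(neg)},
    )
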