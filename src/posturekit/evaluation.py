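"""Confusion-matrix metrics and the 10-fold 80/10/10 evaluation protocol.

Per-class counts are one-vs-rest: treating a class as positive, TP/TN/FP/FN
follow and give

    Acc = (TP+TN)/(TP+TN+FP+FN)      Pr = TP/(TP+FP)
    Re  = TP/(TP+FN)                 F1 = 2·TP/(2·TP+FP+FN)

Overall accuracy is trace/total; precision, recall and F1 are reported
macro-averaged (each class weighted equally) alongside the per-class
breakdown. 0/0 ratios are reported as 0 with a warning.

Cross-validation builds 10 stratified folds; each repetition trains on 8,
reserves 1 as a validation set (available for model selection) and scores
the held-out test fold, so every sample is tested exactly once and never
appears simultaneously in train and test. When group ids are present
(default: contiguous recording segments), whole groups stay inside a single
fold so overlapping sliding windows can never straddle the train/test
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from . import models as _models
from .errors import ConfigurationError, ValidationError
from .features import FeatureMatrix
from .models import ModelConfig, predict, train
from .signal_io import AccelStream


@dataclass
class ConfusionMatrix:
    """Square count matrix indexed (true, predicted) over a fixed label order."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match {k} labels"
            )
        if (self.counts < 0).any():
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def class_counts(self, label: str) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, TN, FP, FN) for ``label``."""
        i = self.labels.index(label)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i, :].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValidationError("cannot add confusion matrices with different labels")
        return ConfusionMatrix(self.counts + other.counts, self.labels)


def confusion(y_true, y_pred, labels: tuple[str, ...] | None = None) -> ConfusionMatrix:
    """Exact (true, predicted) counts. Label order defaults to the canonical
    posture order when applicable, else sorted unique labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    if labels is None:
        seen = set(map(str, y_true)) | set(map(str, y_pred))
        if seen <= set(_models.LABEL_ORDER):
            labels = tuple(l for l in _models.LABEL_ORDER if l in seen) or _models.LABEL_ORDER
        else:
            labels = tuple(sorted(seen))
    index = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(map(str, y_true), map(str, y_pred)):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


@dataclass
class ClassMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass
class MetricsReport:
    """Overall and per-class scores; CV runs add per-fold values."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict[str, ClassMetrics] = field(default_factory=dict)
    fold_accuracies: list[float] | None = None
    accuracy_std: float | None = None
    fold_reports: list["MetricsReport"] | None = None

    def summary(self) -> str:
        lines = [
            f"accuracy  {self.accuracy:.4f}"
            + (f" ± {self.accuracy_std:.4f}" if self.accuracy_std is not None else ""),
            f"precision {self.precision:.4f}",
            f"recall    {self.recall:.4f}",
            f"f1        {self.f1:.4f}",
        ]
        return "\n".join(lines)


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 reported as 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Scores from a confusion matrix; macro averages over classes."""
    if cm.total == 0:
        raise ValidationError("cannot compute metrics of an empty confusion matrix")
    per_class: dict[str, ClassMetrics] = {}
    for label in cm.labels:
        tp, tn, fp, fn = cm.class_counts(label)
        per_class[label] = ClassMetrics(
            tp=tp, tn=tn, fp=fp, fn=fn,
            accuracy=_ratio(tp + tn, tp + tn + fp + fn, f"accuracy[{label}]"),
            precision=_ratio(tp, tp + fp, f"precision[{label}]"),
            recall=_ratio(tp, tp + fn, f"recall[{label}]"),
            f1=_ratio(2 * tp, 2 * tp + fp + fn, f"f1[{label}]"),
        )
    return MetricsReport(
        accuracy=float(np.trace(cm.counts)) / cm.total,
        precision=float(np.mean([m.precision for m in per_class.values()])),
        recall=float(np.mean([m.recall for m in per_class.values()])),
        f1=float(np.mean([m.f1 for m in per_class.values()])),
        per_class=per_class,
    )


@dataclass
class CVPlan:
    """Fold assignment and per-repetition train/validation/test roles."""

    fold_of: np.ndarray  # fold index per row
    folds: int
    seed: int

    def roles(self, repetition: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(train_idx, validation_idx, test_idx) for one repetition: the
        repetition's fold is the test set, the next fold (cyclically) the
        validation set, the remaining 8 the training set."""
        test = np.flatnonzero(self.fold_of == repetition)
        val = np.flatnonzero(self.fold_of == (repetition + 1) % self.folds)
        train_idx = np.flatnonzero(
            (self.fold_of != repetition)
            & (self.fold_of != (repetition + 1) % self.folds)
        )
        return train_idx, val, test


def make_cv_plan(
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> CVPlan:
    """Stratified (optionally group-aware) fold assignment."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        small = classes[counts.argmin()]
        raise ConfigurationError(
            f"class {small!r} has {counts.min()} members; stratified "
            f"{folds}-fold CV needs at least {folds} per class"
        )
    if groups is not None:
        if len(np.unique(groups)) < folds:
            raise ConfigurationError(
                f"grouped CV needs at least {folds} groups, got "
                f"{len(np.unique(groups))}"
            )
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(len(labels)), labels, groups)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(len(labels)), labels)
    fold_of = np.full(len(labels), -1, dtype=int)
    for k, (_, test_idx) in enumerate(split_iter):
        fold_of[test_idx] = k
    return CVPlan(fold_of=fold_of, folds=folds, seed=seed)


def cross_validate(
    matrix,
    labels=None,
    config: ModelConfig | None = None,
    folds: int = 10,
    seed: int = 0,
    groups: np.ndarray | str | None = "auto",
) -> MetricsReport:
    """10-repetition evaluation with an 80/10/10 train/validation/test split.

    ``groups="auto"`` uses the matrix's ``group`` column when present (and
    plain stratified folds otherwise); pass ``None`` to force ungrouped
    folds. Deterministic given ``seed``.
    """
    config = config or ModelConfig.default("RF")
    if isinstance(matrix, FeatureMatrix):
        y = np.asarray(labels if labels is not None else matrix.labels)
        X_source = matrix
    else:
        y = np.asarray(labels)
        X_source = np.asarray(matrix, dtype=float)
    if isinstance(groups, str) and groups == "auto":
        groups = matrix.groups if isinstance(matrix, FeatureMatrix) else None
    plan = make_cv_plan(y, folds=folds, seed=seed, groups=groups)

    def rows(idx):
        if isinstance(X_source, FeatureMatrix):
            return FeatureMatrix(
                data=X_source.data.iloc[idx].reset_index(drop=True),
                families=X_source.families,
            )
        return X_source[idx]

    fold_reports: list[MetricsReport] = []
    pooled: ConfusionMatrix | None = None
    label_order = tuple(
        l for l in _models.LABEL_ORDER if l in set(map(str, y))
    ) or tuple(sorted(set(map(str, y))))
    for rep in range(folds):
        train_idx, _val_idx, test_idx = plan.roles(rep)
        model = train(rows(train_idx), y[train_idx], config)
        y_hat = predict(model, rows(test_idx))
        cm = confusion(y[test_idx], y_hat, labels=label_order)
        fold_reports.append(metrics(cm))
        pooled = cm if pooled is None else pooled + cm
    fold_acc = [r.accuracy for r in fold_reports]
    overall = metrics(pooled)
    return MetricsReport(
        accuracy=float(np.mean(fold_acc)),
        precision=float(np.mean([r.precision for r in fold_reports])),
        recall=float(np.mean([r.recall for r in fold_reports])),
        f1=float(np.mean([r.f1 for r in fold_reports])),
        per_class=overall.per_class,
        fold_accuracies=fold_acc,
        accuracy_std=float(np.std(fold_acc)),
        fold_reports=fold_reports,
    )


def downsample(stream: AccelStream, target_fs: float) -> AccelStream:
    """Integer-factor decimation (e.g. 50 → 25 Hz keeps every 2nd sample).

    Intended to run after the 10 Hz low-pass, which already acts as the
    anti-alias filter for a 12.5 Hz Nyquist.
    """
    ratio = stream.fs / target_fs
    factor = round(ratio)
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ConfigurationError(
            f"target fs {target_fs:g} Hz must divide source fs {stream.fs:g} Hz"
        )
    labels = stream.labels[::factor] if stream.labels is not None else None
    return AccelStream(
        t=stream.t[::factor].copy(),
        a=stream.a[::factor].copy(),
        fs=target_fs,
        units=stream.units,
        labels=labels,
    )
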