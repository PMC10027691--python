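"""Six-class linear SVM decoding with leave-one-run-out cross-validation.

The classifier is libsvm's C-SVC with a linear kernel and C = 1, the
one-vs-one multiclass scheme of that family.  With 4 runs x 6 classes each
fold trains on 18 exemplars (3 runs) and tests on the held-out run's 6.

Two equivalent backends are provided: ``"sklearn"`` fits
``sklearn.svm.SVC`` per fold, while the default ``"fast"`` calls sklearn's
low-level libsvm bindings on a precomputed Gram matrix — the same solver
without per-fit validation overhead, which matters when the permutation
test needs hundreds of thousands of decodes.  Their predictions are
identical whenever every training fold contains all classes (the pipeline
guarantees this; a missing class raises).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC, _libsvm as libsvm

from .connectivity import PatternFeatures

libsvm.set_verbosity_wrap(0)

__all__ = [
    "DecodeResult",
    "gram_matrix",
    "loro_cv_decode",
    "loro_cv_decode_gram",
    "group_mean_accuracy",
    "normalize_confusion",
]

SVM_C = 1.0


@dataclass
class DecodeResult:
    """Cross-validated decoding outcome for one (subject, unit)."""

    accuracy: float
    confusion: np.ndarray  # n_classes x n_classes counts, rows = true class
    per_fold: np.ndarray  # accuracy per held-out run
    subject: str = ""
    unit: str = ""
    label_source: str = "wm_item"

    @property
    def n_test(self) -> int:
        return int(self.confusion.sum())


def gram_matrix(X: np.ndarray) -> np.ndarray:
    """Linear-kernel Gram matrix of an exemplar matrix (exemplars x features)."""
    X = np.asarray(X, dtype=np.float64)
    return np.ascontiguousarray(X @ X.T)


def _check_folds(labels: np.ndarray, runs: np.ndarray) -> np.ndarray:
    unique_runs = np.unique(runs)
    if len(unique_runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    classes = np.unique(labels)
    for r in unique_runs:
        train_classes = np.unique(labels[runs != r])
        missing = set(classes) - set(train_classes)
        if missing:
            raise ValueError(f"classes {sorted(missing)} missing from training fold (run {r})")
    return unique_runs


def make_fold_cache(G: np.ndarray, runs: np.ndarray) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Pre-slice per-fold Gram blocks (train x train, test x train).

    Label permutations leave the Gram matrix untouched, so the permutation
    null can reuse these blocks across all permutations.
    """
    folds = []
    for r in np.unique(runs):
        tr = np.where(runs != r)[0]
        te = np.where(runs == r)[0]
        folds.append(
            (tr, te, np.ascontiguousarray(G[np.ix_(tr, tr)]), np.ascontiguousarray(G[np.ix_(te, tr)]))
        )
    return folds


def accuracy_from_fold_cache(folds, y: np.ndarray) -> float:
    """LORO accuracy given pre-sliced fold blocks and float64 class labels."""
    correct = 0
    total = 0
    for tr, te, Gtr, Gte in folds:
        (support, SV, nSV, sv_coef, intercept,
         probA, probB, _status, _n_iter) = libsvm.fit(
            Gtr, y[tr], svm_type=0, kernel="precomputed", C=SVM_C
        )
        pred = libsvm.predict(
            Gte, support, SV, nSV, sv_coef, intercept, probA, probB,
            svm_type=0, kernel="precomputed",
        )
        correct += int(np.sum(pred == y[te]))
        total += len(te)
    return correct / total


def loro_cv_decode_gram(
    G: np.ndarray,
    labels: np.ndarray,
    runs: np.ndarray,
    *,
    with_confusion: bool = True,
    subject: str = "",
    unit: str = "",
    label_source: str = "wm_item",
) -> DecodeResult:
    """Leave-one-run-out decoding from a precomputed linear Gram matrix."""
    labels = np.asarray(labels)
    runs = np.asarray(runs)
    unique_runs = _check_folds(labels, runs)
    classes, yi = np.unique(labels, return_inverse=True)
    yi = yi.astype(np.float64)
    n_classes = len(classes)
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    per_fold = np.empty(len(unique_runs))
    n_correct = n_total = 0
    for k, r in enumerate(unique_runs):
        tr, te = runs != r, runs == r
        Gtr = np.ascontiguousarray(G[np.ix_(tr, tr)])
        (support, SV, nSV, sv_coef, intercept,
         probA, probB, _status, _n_iter) = libsvm.fit(
            Gtr, yi[tr], svm_type=0, kernel="precomputed", C=SVM_C
        )
        Gte = np.ascontiguousarray(G[np.ix_(te, tr)])
        pred = libsvm.predict(
            Gte, support, SV, nSV, sv_coef, intercept, probA, probB,
            svm_type=0, kernel="precomputed",
        )
        true = yi[te].astype(int)
        pred = pred.astype(int)
        per_fold[k] = float(np.mean(pred == true))
        n_correct += int(np.sum(pred == true))
        n_total += len(true)
        if with_confusion:
            np.add.at(confusion, (true, pred), 1)
    accuracy = n_correct / n_total
    return DecodeResult(
        accuracy=accuracy, confusion=confusion, per_fold=per_fold,
        subject=subject, unit=unit, label_source=label_source,
    )


def _loro_sklearn(X, labels, runs, subject, unit, label_source) -> DecodeResult:
    unique_runs = _check_folds(labels, runs)
    classes = np.unique(labels)
    cls_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    per_fold = np.empty(len(unique_runs))
    n_correct = n_total = 0
    for k, r in enumerate(unique_runs):
        tr, te = runs != r, runs == r
        clf = SVC(kernel="linear", C=SVM_C).fit(X[tr], labels[tr])
        pred = clf.predict(X[te])
        per_fold[k] = float(np.mean(pred == labels[te]))
        n_correct += int(np.sum(pred == labels[te]))
        n_total += len(pred)
        for t, p in zip(labels[te], pred):
            confusion[cls_index[t], cls_index[p]] += 1
    return DecodeResult(
        accuracy=n_correct / n_total, confusion=confusion, per_fold=per_fold,
        subject=subject, unit=unit, label_source=label_source,
    )


def loro_cv_decode(
    features: PatternFeatures | np.ndarray,
    labels: np.ndarray | None = None,
    runs: np.ndarray | None = None,
    *,
    backend: str = "fast",
    subject: str = "",
    unit: str = "",
) -> DecodeResult:
    """Leave-one-run-out six-class decoding of an exemplar matrix.

    ``features`` is a :class:`PatternFeatures` (labels and run tags
    included) or a raw exemplars x features array with ``labels`` and
    ``runs`` given separately.  Deterministic given the features.
    """
    label_source = "wm_item"
    if isinstance(features, PatternFeatures):
        X, labels, runs = features.exemplars, features.labels, features.runs
        unit = unit or features.unit
        label_source = features.label_source
    else:
        X = np.asarray(features, dtype=float)
        if labels is None or runs is None:
            raise ValueError("raw feature arrays require labels and runs")
        labels, runs = np.asarray(labels), np.asarray(runs)
    if backend == "fast":
        return loro_cv_decode_gram(
            gram_matrix(X), labels, runs,
            subject=subject, unit=unit, label_source=label_source,
        )
    if backend == "sklearn":
        return _loro_sklearn(X, labels, runs, subject, unit, label_source)
    raise ValueError(f"unknown backend {backend!r}")


def group_mean_accuracy(accuracies) -> tuple[float, float]:
    """Mean and standard error (sd / sqrt(n)) of per-subject accuracies."""
    acc = np.asarray(
        [a.accuracy if isinstance(a, DecodeResult) else float(a) for a in accuracies]
    )
    if len(acc) < 2:
        raise ValueError("group statistics need at least 2 subjects")
    return float(acc.mean()), float(acc.std(ddof=1) / math.sqrt(len(acc)))


def normalize_confusion(confusion: np.ndarray) -> np.ndarray:
    """Row-normalize a confusion-count matrix; all-zero rows stay zero."""
    confusion = np.asarray(confusion, dtype=float)
    if (confusion < 0).any():
        raise ValueError("confusion counts must be non-negative")
    sums = confusion.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        warnings.warn("zero rows in confusion matrix left as zeros")
    return np.divide(confusion, sums, out=np.zeros_like(confusion), where=sums > 0)
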