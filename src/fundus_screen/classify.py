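"""Binary maculopathy classification and its evaluation protocol.

Images are labelled maculopathy-positive or -negative (the four
"with maculopathy" grading stages versus everything else, including the
disease-free stage and advanced diabetic eye disease).  Four classifiers
are supported: 1-nearest-neighbour, polynomial- and RBF-kernel support
vector machines, and Gaussian naive Bayes.  Because the area/SD features
live on very different scales, features are z-scored with training-fold
statistics before the distance- and margin-based models.

Evaluation follows a Monte-Carlo cross-validation protocol: repeated
seeded stratified 90/10 train/test splits with metrics averaged over the
repeats.  Class imbalance is handled by random duplication oversampling of
the minority class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .expert_stats import STAGE_NAMES

MODEL_TAGS = ("knn1", "svm_poly", "svm_rbf", "naive_bayes")


@dataclass(frozen=True)
class Dataset:
    """Feature matrix (n x 6) with boolean maculopathy labels."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=bool)
        if X.ndim != 2:
            raise ValueError(f"feature matrix must be 2-D, got shape {X.shape}")
        if len(X) != len(y):
            raise ValueError("features and labels must have equal length")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.y)

    @property
    def class_counts(self) -> tuple[int, int]:
        """(negative, positive) counts."""
        pos = int(self.y.sum())
        return len(self.y) - pos, pos


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts with the derived screening metrics.

    Positive class = maculopathy detected.  Sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), accuracy = (TP+TN)/total, misclassification
    error = 1 - accuracy.  Undefined ratios are NaN, never zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    misclassification_error: float

    @classmethod
    def from_confusion(cls, tp: int, fp: int, tn: int, fn: int) -> "EvalResult":
        total = tp + fp + tn + fn
        sens = tp / (tp + fn) if tp + fn else math.nan
        spec = tn / (tn + fp) if tn + fp else math.nan
        acc = (tp + tn) / total if total else math.nan
        return cls(tp, fp, tn, fn, sens, spec, acc, 1.0 - acc if total else math.nan)

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "misclassification_error": self.misclassification_error,
        }


def make_model(tag: str):
    """Instantiate one of the four supported classifiers by tag."""
    if tag == "knn1":
        clf = KNeighborsClassifier(n_neighbors=1)
    elif tag == "svm_poly":
        clf = SVC(kernel="poly", degree=3, C=1.0, gamma="scale")
    elif tag == "svm_rbf":
        clf = SVC(kernel="rbf", C=1.0, gamma="scale")
    elif tag == "naive_bayes":
        return GaussianNB()
    else:
        raise ValueError(f"unknown model tag {tag!r}; expected one of {MODEL_TAGS}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def oversample_minority(d: Dataset, target: int | None = None, seed: int = 0) -> Dataset:
    """Grow the minority class to ``target`` rows by seeded random duplication.

    The majority class is untouched; added rows are exact copies of existing
    minority rows; the row order of the result is a seeded shuffle.  The
    default target is the majority-class size (class parity).
    """
    neg, pos = d.class_counts
    if min(neg, pos) == 0:
        raise ValueError("cannot oversample: one class is empty")
    minority_label = pos <= neg
    n_min = min(neg, pos)
    if target is None:
        target = max(neg, pos)
    if target < n_min:
        raise ValueError(f"target {target} is below the minority count {n_min}")
    rng = np.random.default_rng(seed)
    idx_min = np.flatnonzero(d.y == minority_label)
    extra = rng.choice(idx_min, size=target - n_min, replace=True)
    idx = np.concatenate([np.arange(len(d)), extra])
    rng.shuffle(idx)
    return Dataset(d.X[idx], d.y[idx])


def evaluate(
    d: Dataset,
    model: str = "knn1",
    repeats: int = 10,
    train_frac: float = 0.9,
    seed: int = 0,
) -> EvalResult:
    """Monte-Carlo cross-validation of one classifier.

    Per repeat: a seeded stratified split holds out ``1 - train_frac`` of
    the data, the model is fit on the rest and the held-out fold predicted.
    Metrics are averaged over repeats, skipping any repeat where a ratio is
    undefined (e.g. a fold without positives); confusion counts are summed.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must lie in (0, 1), got {train_frac}")
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    neg, pos = d.class_counts
    if min(neg, pos) < 2:
        raise ValueError("need at least 2 examples of each class")

    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(0, 2**31 - 1, size=repeats)
    totals = np.zeros(4, dtype=int)  # tp fp tn fn
    per_repeat: list[EvalResult] = []
    for r in range(repeats):
        X_tr, X_te, y_tr, y_te = train_test_split(
            d.X,
            d.y,
            train_size=train_frac,
            stratify=d.y,
            random_state=int(split_seeds[r]),
        )
        clf = make_model(model)
        clf.fit(X_tr, y_tr)
        pred = np.asarray(clf.predict(X_te), dtype=bool)
        tp = int(np.sum(pred & y_te))
        fp = int(np.sum(pred & ~y_te))
        tn = int(np.sum(~pred & ~y_te))
        fn = int(np.sum(~pred & y_te))
        totals += (tp, fp, tn, fn)
        per_repeat.append(EvalResult.from_confusion(tp, fp, tn, fn))

    def _nanmean(vals: list[float]) -> float:
        arr = np.asarray(vals, dtype=float)
        return float(np.nanmean(arr)) if not np.all(np.isnan(arr)) else math.nan

    return EvalResult(
        tp=int(totals[0]),
        fp=int(totals[1]),
        tn=int(totals[2]),
        fn=int(totals[3]),
        sensitivity=_nanmean([e.sensitivity for e in per_repeat]),
        specificity=_nanmean([e.specificity for e in per_repeat]),
        accuracy=_nanmean([e.accuracy for e in per_repeat]),
        misclassification_error=_nanmean([e.misclassification_error for e in per_repeat]),
    )


def label_from_stage(stage: str) -> bool:
    """Binary maculopathy label for a 10-stage grading name.

    True for the four "with maculopathy" stages; False for the disease-free
    stage, the "without maculopathy" stages and advanced diabetic eye
    disease.
    """
    if stage not in STAGE_NAMES:
        raise ValueError(f"unknown retinopathy stage {stage!r}")
    return "with maculopathy" in stage
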