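"""Linear-SVM diagnostic model, cross-validated evaluation and weight reports.

The diagnostic model is a linear support-vector machine over the predictor
vector [pairwise metrics..., IQ scores, sex, age, mean FD], label 1 for a
patient and 0 for a control.  Features are z-scored with statistics of the
training fold only; weights are therefore reported in standardized-feature
units, which makes their magnitudes comparable across predictors.  A
positive weight marks a predictor elevated in patients, a negative weight
one reduced.

Evaluation follows two protocols: leave-one-out cross-validation (one
held-out prediction per subject) and R-times repeated stratified 10-fold
cross-validation, each repeat using a fresh seeded partition and pooling
the fold confusion counts into one performance estimate.  Discriminative
patterns are summarized by (a) the signed weights of a fitted model and
(b) how often each feature lands in the per-repeat top-k by absolute
weight across the repeated 10-fold runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


@dataclass
class DiagnosticModel:
    """A trained linear SVM plus the training-fold standardization."""

    weights: np.ndarray          # in standardized-feature units
    intercept: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    feature_names: tuple[str, ...] = ()

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale
        return Xs @ self.weights + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


@dataclass
class CVPerformance:
    """Pooled confusion counts and the derived performance metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tn + self.tp) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass
class WeightFrequencyReport:
    """Per-feature top-k membership counts over repeated CV runs."""

    counts: np.ndarray
    mean_weights: np.ndarray
    k: int
    n_repeats: int
    feature_names: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or tuple(f"f{i}" for i in range(len(self.counts)))
        return (
            pd.DataFrame(
                {"feature": names, "top_k_count": self.counts, "mean_weight": self.mean_weights}
            )
            .sort_values("top_k_count", ascending=False, kind="stable")
            .reset_index(drop=True)
        )


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_samples, n_features) aligned with y")
    if not np.isfinite(X).all():
        raise ValueError("X contains missing or non-finite values")
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two classes in y")
    return X, y


def train_linear_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    feature_names: tuple[str, ...] = (),
) -> DiagnosticModel:
    """Fit a soft-margin linear SVM on z-scored features.

    The optimizer is the SMO-type solver of libsvm; any exact solver of
    the same convex objective yields the same hyperplane.  Constant
    features get unit scale so they contribute zero after centering.
    """
    X, y = _validate_xy(X, y)
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples per class")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    svc = SVC(kernel="linear", C=C)
    svc.fit(Xs, y)
    return DiagnosticModel(
        weights=svc.coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        scaler_mean=mean,
        scaler_scale=scale,
        feature_names=tuple(feature_names),
    )


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """accuracy, sensitivity, specificity from pooled confusion counts."""
    for v in (tp, fp, tn, fn):
        if v < 0 or int(v) != v:
            raise ValueError("confusion counts must be nonnegative integers")
    if tp + fn == 0:
        raise ValueError("no positive samples: sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no negative samples: specificity undefined")
    accuracy = (tn + tp) / (tn + fn + tp + fp)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return accuracy, sensitivity, specificity


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, fp, tn, fn


def loocv(
    X: np.ndarray, y: np.ndarray, C: float = 1.0
) -> tuple[CVPerformance, np.ndarray]:
    """Leave-one-out CV: one held-out decision score per subject.

    Standardization is refit on each training fold, so no test-subject
    statistics leak into the model.  Returns the pooled performance (with
    AUC over the held-out scores) and the per-subject scores.
    """
    X, y = _validate_xy(X, y)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 subjects for LOOCV")
    scores = np.empty(n)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        model = train_linear_svm(X[tr], y[tr], C=C)
        scores[i] = model.decision_function(X[i: i + 1])[0]
    y_pred = (scores > 0).astype(int)
    tp, fp, tn, fn = _confusion(y, y_pred)
    auc_value, _, _ = roc_auc(scores, y)
    return CVPerformance(tp=tp, fp=fp, tn=tn, fn=fn, auc=auc_value), scores


def repeated_kfold(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    repeats: int = 1000,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[list[CVPerformance], np.ndarray]:
    """Repeated stratified k-fold CV with a fresh seeded partition per repeat.

    Each repeat pools its k fold confusion matrices into one performance
    estimate (AUC from the pooled held-out decision scores) and records
    the mean of the k fold-model weight vectors.  Returns all repeats'
    performances and the (repeats x n_features) weight matrix.
    """
    X, y = _validate_xy(X, y)
    if k > y.size:
        raise ValueError(f"k={k} exceeds n={y.size}")
    if k < 2:
        raise ValueError("k must be at least 2")
    ss = np.random.SeedSequence([int(seed), 97])
    repeat_seeds = [int(s) for s in ss.generate_state(repeats) % (2**31 - 1)]
    performances: list[CVPerformance] = []
    weight_rows = np.empty((repeats, X.shape[1]))
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=repeat_seeds[r])
        scores = np.empty(y.size)
        fold_weights = np.empty((k, X.shape[1]))
        for f, (tr, te) in enumerate(skf.split(X, y)):
            model = train_linear_svm(X[tr], y[tr], C=C)
            scores[te] = model.decision_function(X[te])
            fold_weights[f] = model.weights
        y_pred = (scores > 0).astype(int)
        tp, fp, tn, fn = _confusion(y, y_pred)
        auc_value, _, _ = roc_auc(scores, y)
        performances.append(CVPerformance(tp=tp, fp=fp, tn=tn, fn=fn, auc=auc_value))
        weight_rows[r] = fold_weights.mean(axis=0)
    return performances, weight_rows


def roc_auc(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and ROC curve points from decision scores.

    AUC equals the probability that a random positive outscores a random
    negative, ties counting one half (the normalized Mann-Whitney U).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y, dtype=int).ravel()
    if scores.size != y.size:
        raise ValueError("scores and labels must align")
    if len(np.unique(y)) != 2:
        raise ValueError("need both classes for a ROC curve")
    fpr, tpr, _ = roc_curve(y, scores)
    return float(sk_auc(fpr, tpr)), fpr, tpr


def top_k_frequency(
    weight_vectors: np.ndarray,
    k: int = 10,
    feature_names: tuple[str, ...] = (),
) -> WeightFrequencyReport:
    """Count, per feature, its appearances in the per-repeat top-k by |weight|.

    Ties in |weight| are broken by canonical feature order (lower index
    wins), via a stable sort on descending absolute weight.
    """
    W = np.asarray(weight_vectors, dtype=float)
    if W.ndim != 2:
        raise ValueError("weight_vectors must be (n_repeats, n_features)")
    if not 1 <= k <= W.shape[1]:
        raise ValueError(f"k={k} outside [1, {W.shape[1]}]")
    counts = np.zeros(W.shape[1], dtype=int)
    for row in W:
        top = np.argsort(-np.abs(row), kind="stable")[:k]
        counts[top] += 1
    return WeightFrequencyReport(
        counts=counts,
        mean_weights=W.mean(axis=0),
        k=k,
        n_repeats=W.shape[0],
        feature_names=tuple(feature_names),
    )


def weight_sign_report(model: DiagnosticModel) -> pd.DataFrame:
    """Signed weight per feature with its diagnostic direction.

    Positive weight: the (standardized) predictor is elevated in patients;
    negative: reduced.  Rows keep the canonical feature order.
    """
    if model.weights is None or len(model.weights) == 0:
        raise ValueError("model has no trained weights")
    names = model.feature_names or tuple(f"f{i}" for i in range(len(model.weights)))
    direction = np.where(model.weights >= 0, "higher in patients", "lower in patients")
    return pd.DataFrame({"feature": names, "weight": model.weights, "direction": direction})
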