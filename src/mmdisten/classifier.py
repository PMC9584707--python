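"""Feed-forward neural classifier and cross-validated evaluation.

A small fully-connected network — ReLU hidden layers, a single sigmoid
output unit, binary cross-entropy loss — trained by backpropagation with
the RMSprop update rule.  Evaluation follows the standard protocol for
per-subject emotion classification: stratified 10-fold cross-validation
with per-feature standardization fit on each training split only, a 0.5
decision threshold, and precision/recall/F1/accuracy in percent

    precision = TP/(TP+FP)·100        recall   = TP/(TP+FN)·100
    F1 = 2·TP/(2·TP+FP+FN)·100        accuracy = (TP+TN)/total·100

reported per fold and as mean ± SD across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features_pipeline import LabeledFeatureSet

__all__ = [
    "NetworkSpec",
    "TrainedModel",
    "FoldResult",
    "ClassificationReport",
    "Metrics",
    "metrics",
    "train",
    "predict",
    "cross_validate",
    "write_report_csv",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and optimization settings.

    The hidden layout, epochs and batch size are free choices (exposed
    here); the activation/optimizer/loss combination — ReLU hidden
    layers, RMSprop, binary cross-entropy — is the method's fixed
    training recipe.  Training stops early when the epoch loss has not
    improved by ``tol`` for ``patience`` epochs.
    """

    hidden_layers: tuple[int, ...] = (64, 32)
    learning_rate: float = 1e-3
    rho: float = 0.9            # RMSprop decay of the squared-gradient average
    epsilon: float = 1e-8
    epochs: int = 300
    batch_size: int = 16
    patience: int = 20
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_layers) < 1 or any(w < 1 for w in self.hidden_layers):
            raise ValueError("need ≥1 hidden layer of positive width")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs and batch_size must be positive")


class Metrics(NamedTuple):
    precision: float
    recall: float
    f1: float
    accuracy: float


def metrics(TP: int, FP: int, TN: int, FN: int) -> Metrics:
    """Confusion-count metrics in percent.

    A degenerate denominator (e.g. no positive predictions) yields a 0%
    sentinel with a warning instead of NaN, so batch reports never fail.
    """
    counts = {"TP": TP, "FP": FP, "TN": TN, "FN": FN}
    for name, v in counts.items():
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    total = TP + FP + TN + FN
    if total == 0:
        raise ValueError("confusion counts sum to 0")

    def _ratio(num: float, den: float, label: str) -> float:
        if den == 0:
            warnings.warn(f"{label} undefined (zero denominator); reporting 0%", stacklevel=3)
            return 0.0
        return num / den * 100.0

    return Metrics(
        precision=_ratio(TP, TP + FP, "precision"),
        recall=_ratio(TP, TP + FN, "recall"),
        f1=_ratio(2 * TP, 2 * TP + FP + FN, "F1"),
        accuracy=(TP + TN) / total * 100.0,
    )


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """Weights plus the training split's standardization parameters."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    spec: NetworkSpec
    final_loss: float
    epochs_run: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(X) - self.feat_mean) / self.feat_sd
        return _forward(Z, self.weights, self.biases)[-1].ravel()

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def _forward(Z: np.ndarray, W: list[np.ndarray], b: list[np.ndarray]) -> list[np.ndarray]:
    """Activations per layer; ReLU hidden, sigmoid output."""
    acts = [Z]
    for layer, (w, bi) in enumerate(zip(W, b)):
        pre = acts[-1] @ w + bi
        if layer < len(W) - 1:
            acts.append(np.maximum(pre, 0.0))
        else:
            acts.append(1.0 / (1.0 + np.exp(-pre)))
    return acts


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def train(features: LabeledFeatureSet, spec: NetworkSpec) -> TrainedModel:
    """Train the network by backpropagation with RMSprop.

    Features are standardized with the training set's own per-feature
    mean/SD (constant features get SD 1), and those parameters travel
    with the model.  Deterministic for a fixed seed.
    """
    X = features.features
    y = features.labels.astype(float)
    if np.unique(features.labels).size < 2 or min(np.bincount(features.labels, minlength=2)) < 2:
        raise ValueError("training set needs ≥2 examples of each class")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd

    rng = np.random.default_rng(spec.seed)
    sizes = [X.shape[1], *spec.hidden_layers, 1]
    # He initialization, suited to ReLU layers
    W = [rng.standard_normal((a, b)) * np.sqrt(2.0 / a) for a, b in zip(sizes, sizes[1:])]
    b = [np.zeros(n) for n in sizes[1:]]
    cache_W = [np.zeros_like(w) for w in W]
    cache_b = [np.zeros_like(bi) for bi in b]

    n = Z.shape[0]
    best_loss = np.inf
    stall = 0
    epoch = 0
    for epoch in range(1, spec.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            acts = _forward(Z[idx], W, b)
            # sigmoid + BCE: output-layer delta simplifies to (p − y)/batch
            delta = (acts[-1] - y[idx, None]) / idx.size
            for layer in range(len(W) - 1, -1, -1):
                gW = acts[layer].T @ delta
                gb = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ W[layer].T) * (acts[layer] > 0)
                cache_W[layer] = spec.rho * cache_W[layer] + (1 - spec.rho) * gW**2
                cache_b[layer] = spec.rho * cache_b[layer] + (1 - spec.rho) * gb**2
                W[layer] -= spec.learning_rate * gW / (np.sqrt(cache_W[layer]) + spec.epsilon)
                b[layer] -= spec.learning_rate * gb / (np.sqrt(cache_b[layer]) + spec.epsilon)
        loss = _bce(y, _forward(Z, W, b)[-1].ravel())
        if loss < best_loss - spec.tol:
            best_loss = loss
            stall = 0
        else:
            stall += 1
            if stall >= spec.patience:
                break

    return TrainedModel(
        weights=W, biases=b, feat_mean=mean, feat_sd=sd,
        spec=spec, final_loss=best_loss, epochs_run=epoch,
    )


def predict(model: TrainedModel, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Class predictions at the given probability threshold."""
    return model.predict(X, threshold=threshold)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldResult:
    fold: int
    TP: int
    FP: int
    TN: int
    FN: int
    metrics: Metrics

    @property
    def test_size(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class ClassificationReport:
    """Per-fold confusion counts and mean ± SD metrics across folds."""

    folds: tuple[FoldResult, ...]

    def _stack(self) -> np.ndarray:
        return np.array([list(f.metrics) for f in self.folds])

    @property
    def mean(self) -> Metrics:
        return Metrics(*self._stack().mean(axis=0))

    @property
    def sd(self) -> Metrics:
        return Metrics(*self._stack().std(axis=0))


def cross_validate(
    features: LabeledFeatureSet, spec: NetworkSpec, k: int = 10
) -> ClassificationReport:
    """Stratified k-fold cross-validation with leakage-free scaling.

    Standardization and all weights are fit on each training split only.
    Fold assignment is shuffled with the spec's seed, so the report is
    reproducible.
    """
    y = features.labels
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < k:
        raise ValueError(
            f"smallest class has {class_counts.min()} trials, fewer than k={k} folds; "
            f"use k ≤ {class_counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    folds = []
    for i, (tr, te) in enumerate(skf.split(features.features, y)):
        sub = LabeledFeatureSet(
            features=features.features[tr],
            labels=y[tr],
            trial_ids=tuple(features.trial_ids[j] for j in tr),
            subject_id=features.subject_id,
        )
        model = train(sub, spec)
        pred = model.predict(features.features[te])
        truth = y[te]
        TP = int(((pred == 1) & (truth == 1)).sum())
        FP = int(((pred == 1) & (truth == 0)).sum())
        TN = int(((pred == 0) & (truth == 0)).sum())
        FN = int(((pred == 0) & (truth == 1)).sum())
        folds.append(FoldResult(fold=i + 1, TP=TP, FP=FP, TN=TN, FN=FN,
                                metrics=metrics(TP, FP, TN, FN)))
    return ClassificationReport(folds=tuple(folds))


def write_report_csv(report: ClassificationReport, path: str | Path) -> None:
    """Report CSV: one row per fold plus mean and SD summary rows."""
    rows = [
        {"fold": f.fold, "TP": f.TP, "FP": f.FP, "TN": f.TN, "FN": f.FN,
         "precision": f.metrics.precision, "recall": f.metrics.recall,
         "f1": f.metrics.f1, "accuracy": f.metrics.accuracy}
        for f in report.folds
    ]
    for label, m in (("mean", report.mean), ("sd", report.sd)):
        rows.append({"fold": label, "TP": "", "FP": "", "TN": "", "FN": "",
                     "precision": m.precision, "recall": m.recall,
                     "f1": m.f1, "accuracy": m.accuracy})
    pd.DataFrame(rows).to_csv(path, index=False)
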