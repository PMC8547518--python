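"""Classification metrics, stratified cross-validation and the label-flip
permutation significance test.

ASD (case) is the positive class throughout. The permutation test follows
the label-flip variant: each permutation randomly flips a fixed fraction
(default 20%) of the diagnosis labels and re-runs the identical training and
evaluation procedure; the p-value uses the add-one estimator
p = (1 + #{null >= observed}) / (1 + n_perm), which can never be exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .model import ModelConfig, TrainedModel, fast_config, model_forward, train_model
from .network import MorphNetwork

__all__ = [
    "Metrics",
    "CVResult",
    "PermutationResult",
    "confusion_metrics",
    "roc_auc",
    "stratified_cross_validate",
    "permutation_test",
]


@dataclass
class Metrics:
    """Confusion counts and the derived ratios; undefined ratios are None."""

    TP: int
    FP: int
    TN: int
    FN: int
    accuracy: float | None = field(init=False)
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)
    f1: float | None = field(init=False)

    def __post_init__(self) -> None:
        def ratio(num: int, den: int) -> float | None:
            return num / den if den else None

        self.accuracy = ratio(self.TP + self.TN, self.TP + self.TN + self.FP + self.FN)
        self.sensitivity = ratio(self.TP, self.TP + self.FN)
        self.specificity = ratio(self.TN, self.TN + self.FP)
        self.f1 = ratio(2 * self.TP, 2 * self.TP + self.FP + self.FN)

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "f1": self.f1,
        }


def confusion_metrics(predictions: Sequence[int], labels: Sequence[int]) -> Metrics:
    """Accuracy, sensitivity, specificity and F1 from binary predictions."""
    pred = np.asarray(predictions)
    y = np.asarray(labels)
    if pred.shape != y.shape or pred.size == 0:
        raise ValueError("predictions and labels must be equal-length, non-empty")
    if not (set(np.unique(pred)) <= {0, 1} and set(np.unique(y)) <= {0, 1}):
        raise ValueError("predictions and labels must be binary 0/1")
    return Metrics(
        TP=int(np.sum((pred == 1) & (y == 1))),
        FP=int(np.sum((pred == 1) & (y == 0))),
        TN=int(np.sum((pred == 0) & (y == 0))),
        FN=int(np.sum((pred == 0) & (y == 1))),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC with midrank tie handling (the normalised Mann-Whitney U)."""
    y = np.asarray(labels)
    if len(set(np.unique(y))) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


@dataclass
class CVResult:
    """Per-fold and aggregate cross-validation outcome."""

    fold_metrics: list[Metrics]
    mean_metrics: dict[str, float | None]
    pooled_scores: np.ndarray
    pooled_predictions: np.ndarray
    pooled_labels: np.ndarray
    fold_assignment: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return self.mean_metrics["accuracy"]

    @property
    def auc(self) -> float:
        return roc_auc(self.pooled_scores, self.pooled_labels)


def _mean_over_folds(folds: list[Metrics]) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for key in ("accuracy", "sensitivity", "specificity", "f1"):
        vals = [getattr(m, key) for m in folds if getattr(m, key) is not None]
        out[key] = float(np.mean(vals)) if vals else None
    return out


def stratified_cross_validate(
    networks: Sequence[MorphNetwork],
    labels: Sequence[int],
    config: ModelConfig,
    k_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Seeded stratified k-fold CV: train on k-1 folds, score the held-out fold."""
    y = np.asarray(labels, dtype=int)
    if min(np.sum(y == 0), np.sum(y == 1)) < k_folds:
        raise ValueError(f"each class needs >= {k_folds} members for {k_folds}-fold CV")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=int(seed))
    n = len(y)
    fold_assignment = np.full(n, -1, dtype=int)
    scores = np.zeros(n)
    preds = np.zeros(n, dtype=int)
    fold_metrics: list[Metrics] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(n), y)):
        fold_assignment[test_idx] = fold
        fold_cfg = ModelConfig(**{**config.__dict__,
                                  "seed": (config.seed + 1000003 * fold) & 0x7FFFFFFF})
        model = train_model([networks[i] for i in train_idx], y[train_idx], fold_cfg)
        for i in test_idx:
            record = model_forward(networks[i], model)
            scores[i] = record.probability
            preds[i] = int(record.probability >= 0.5)
        fold_metrics.append(confusion_metrics(preds[test_idx], y[test_idx]))
    return CVResult(
        fold_metrics=fold_metrics,
        mean_metrics=_mean_over_folds(fold_metrics),
        pooled_scores=scores,
        pooled_predictions=preds,
        pooled_labels=y,
        fold_assignment=fold_assignment,
    )


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    flip_fraction: float
    n_perm: int
    seed: int


def permutation_test(
    networks: Sequence[MorphNetwork],
    labels: Sequence[int],
    config: ModelConfig,
    n_perm: int = 10_000,
    flip_fraction: float = 0.2,
    seed: int = 0,
    k_folds: int = 5,
    fast: bool = False,
    refit: bool = True,
) -> PermutationResult:
    """Label-flip permutation test of cross-validated accuracy.

    Each of the n_perm permutations flips round(flip_fraction * n) randomly
    chosen labels and reruns the identical stratified-CV procedure (refit) or
    re-scores the fixed observed models (refit=False). ``fast`` caps training
    at a reduced epoch count for desk-scale runs.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0.0 < flip_fraction < 1.0:
        raise ValueError("flip_fraction must lie in (0, 1)")
    y = np.asarray(labels, dtype=int)
    n = len(y)
    n_flip = int(round(flip_fraction * n))
    if n_flip == 0:
        raise ValueError(f"flip_fraction {flip_fraction} flips 0 of {n} labels")
    cfg = fast_config(config) if fast else config

    observed = stratified_cross_validate(networks, y, cfg, k_folds=k_folds, seed=seed)
    observed_acc = observed.mean_accuracy

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 2]))
    null = np.empty(n_perm)
    for b in range(n_perm):
        flipped = y.copy()
        idx = rng.choice(n, size=n_flip, replace=False)
        flipped[idx] = 1 - flipped[idx]
        if min(np.sum(flipped == 0), np.sum(flipped == 1)) < k_folds:
            # extreme flip left a class too small to stratify; score as chance
            null[b] = 0.5
            continue
        if refit:
            cv = stratified_cross_validate(
                networks, flipped, cfg, k_folds=k_folds,
                seed=(seed + 7919 * (b + 1)) & 0x7FFFFFFF)
            null[b] = cv.mean_accuracy
        else:
            null[b] = float(np.mean(observed.pooled_predictions == flipped))
    p_value = (1.0 + np.sum(null >= observed_acc)) / (1.0 + n_perm)
    return PermutationResult(
        observed_accuracy=float(observed_acc),
        null_accuracies=null,
        p_value=float(p_value),
        flip_fraction=flip_fraction,
        n_perm=n_perm,
        seed=int(seed),
    )
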