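"""kNN wrapper fitness for binary feature masks.

A candidate mask is scored by the weighted sum of the validation error of
a k-nearest-neighbor classifier trained on the masked columns and the
selected-feature ratio:

    F(mask) = alpha * (1 - accuracy) + beta * n_selected / n_total

with alpha = 0.99 and beta = 0.01 by default, so classification error
dominates and the size term breaks ties toward smaller subsets.  Features
are min-max scaled on the training rows only.  The all-zero mask is
degenerate (nothing to classify on) and scores the supremum F = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import MinMaxScaler

from .containers import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class FitnessSpec:
    """Configuration of the wrapper fitness.

    ``alpha``/``beta`` must sum to 1; ``validation_scheme`` is either a
    stratified ``holdout`` carved from the training rows (default 80/20)
    or stratified ``kfold`` with ``n_folds`` folds.
    """

    alpha: float = 0.99
    beta: float = 0.01
    k_neighbors: int = 5
    validation_scheme: str = "holdout"
    val_fraction: float = 0.2
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.validation_scheme not in ("holdout", "kfold"):
            raise ValueError("validation_scheme must be 'holdout' or 'kfold'")


@dataclass
class MaskEvaluation:
    """Score of one mask: fitness, accuracy and subset size."""

    fitness: float
    accuracy: float
    n_selected: int
    n_total: int


def fitness_value(
    accuracy: float, n_selected: int, n_total: int, alpha: float = 0.99, beta: float = 0.01
) -> float:
    """The error/size trade-off ``alpha*(1-accuracy) + beta*(n_selected/n_total)``."""
    return alpha * (1.0 - accuracy) + beta * (n_selected / n_total)


def masked_knn_accuracy(
    mask: np.ndarray,
    train: FeatureMatrix,
    val: FeatureMatrix,
    k_neighbors: int = 5,
) -> float:
    """Accuracy of kNN trained on the masked training columns.

    Min-max scaling is fitted on training rows only and applied to the
    validation rows.
    """
    mask = np.asarray(mask).astype(bool)
    xtr = train.values[:, mask]
    xva = val.values[:, mask]
    scaler = MinMaxScaler().fit(xtr)
    knn = KNeighborsClassifier(n_neighbors=min(k_neighbors, xtr.shape[0]))
    knn.fit(scaler.transform(xtr), train.labels)
    return float(knn.score(scaler.transform(xva), val.labels))


def knn_fitness(
    mask: np.ndarray,
    train: FeatureMatrix,
    val: FeatureMatrix,
    spec: FitnessSpec | None = None,
) -> MaskEvaluation:
    """Score a binary mask with the kNN wrapper fitness.

    Raises a schema error when the views disagree on columns or when the
    validation labels are unseen in training; returns the documented
    supremum F = 1.0 for the all-zero mask without fitting.
    """
    spec = spec or FitnessSpec()
    mask = np.asarray(mask).astype(bool)
    if mask.shape[0] != train.n_features:
        raise ValueError(
            f"mask length {mask.shape[0]} != feature count {train.n_features}"
        )
    if train.column_ids != val.column_ids:
        raise ValueError("train and validation tables disagree on columns")
    if train.labels is None or val.labels is None:
        raise ValueError("both tables must carry labels")
    if not set(np.unique(val.labels)) <= set(np.unique(train.labels)):
        raise ValueError("validation labels not present in training data")

    n_total = train.n_features
    n_sel = int(mask.sum())
    if n_sel == 0:
        logger.debug("all-zero mask: degenerate fitness 1.0")
        return MaskEvaluation(1.0, 0.0, 0, n_total)
    acc = masked_knn_accuracy(mask, train, val, spec.k_neighbors)
    return MaskEvaluation(
        fitness=fitness_value(acc, n_sel, n_total, spec.alpha, spec.beta),
        accuracy=acc,
        n_selected=n_sel,
        n_total=n_total,
    )


def mask_objective(
    features: FeatureMatrix, spec: FitnessSpec | None = None
) -> Callable[[np.ndarray], float]:
    """Build a bits -> fitness callable for the optimizers.

    The accuracy term is computed on a validation scheme carved from the
    supplied (training) rows — never on any final test split — to keep the
    selection loop leakage-free.  Holdout splits once up front so every
    mask is scored on the same partition; k-fold averages accuracy over
    stratified folds.
    """
    from .metrics import stratified_split_indices  # local import: avoid cycle

    spec = spec or FitnessSpec()
    if spec.validation_scheme == "holdout":
        tr_idx, va_idx = stratified_split_indices(
            features.labels, 1.0 - spec.val_fraction, spec.seed
        )
        fm_tr = features.take(tr_idx)
        fm_va = features.take(va_idx)

        def objective(bits: np.ndarray) -> float:
            return knn_fitness(bits, fm_tr, fm_va, spec).fitness

    else:
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
        folds = [
            (features.take(tr), features.take(va))
            for tr, va in skf.split(features.values, features.labels)
        ]

        def objective(bits: np.ndarray) -> float:
            bits = np.asarray(bits).astype(bool)
            if bits.sum() == 0:
                return 1.0
            accs = [
                masked_knn_accuracy(bits, tr, va, spec.k_neighbors) for tr, va in folds
            ]
            return fitness_value(
                float(np.mean(accs)), int(bits.sum()), features.n_features,
                spec.alpha, spec.beta,
            )

    return objective
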