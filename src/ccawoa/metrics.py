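"""Splitting, confusion-matrix metrics, multi-run aggregation, t-tests.

Per-class rates follow the usual one-vs-rest reading of a C-class
confusion matrix (rows = true, columns = predicted): TPR = diag/rowsum,
FNR = 1 - TPR, PPV = diag/colsum, FDR = 1 - PPV.  Cells whose denominator
is zero are reported as NaN (undefined) rather than 0, so an absent
prediction class never silently inflates precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split

from .containers import FeatureMatrix
from .exceptions import DegenerateVarianceError, StratificationError


def stratified_split_indices(
    labels: np.ndarray, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test row indices with per-class proportions
    preserved within rounding."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < 2:
            raise StratificationError(
                f"class {cls!r} has {cnt} sample(s); need >= 2 to stratify"
            )
    idx = np.arange(labels.shape[0])
    tr, te = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=labels,
        random_state=int(seed) % (2**32 - 1),
    )
    return np.sort(tr), np.sort(te)


def stratified_split(
    data: FeatureMatrix, train_fraction: float, seed: int
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified row partition of a labeled feature matrix."""
    if data.labels is None:
        raise ValueError("stratified_split requires labels")
    tr, te = stratified_split_indices(data.labels, train_fraction, seed)
    return data.take(tr), data.take(te)


@dataclass
class ConfusionReport:
    """C-class confusion matrix with per-class TPR/FNR/PPV/FDR and accuracy."""

    matrix: np.ndarray
    class_order: list
    tpr: np.ndarray
    fnr: np.ndarray
    ppv: np.ndarray
    fdr: np.ndarray
    accuracy: float

    def to_frame(self) -> pd.DataFrame:
        """One row per class, suitable for writing as a delimited table."""
        return pd.DataFrame(
            {
                "class": self.class_order,
                "n_true": self.matrix.sum(axis=1),
                "n_predicted": self.matrix.sum(axis=0),
                "TPR": self.tpr,
                "FNR": self.fnr,
                "PPV": self.ppv,
                "FDR": self.fdr,
            }
        )


def confusion(y_true, y_pred, class_order) -> ConfusionReport:
    """Build the multiclass confusion report (rows = true, cols = predicted)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape[0] != y_pred.shape[0]:
        raise ValueError("y_true and y_pred must have equal length")
    class_order = list(class_order)
    known = set(class_order)
    unknown = (set(np.unique(y_true)) | set(np.unique(y_pred))) - known
    if unknown:
        raise ValueError(f"unknown label(s) {sorted(map(str, unknown))!r}")
    m = _sk_confusion(y_true, y_pred, labels=class_order)
    diag = np.diag(m).astype(float)
    row = m.sum(axis=1).astype(float)
    col = m.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(row > 0, diag / row, np.nan)
        ppv = np.where(col > 0, diag / col, np.nan)
    return ConfusionReport(
        matrix=m,
        class_order=class_order,
        tpr=tpr,
        fnr=1.0 - tpr,
        ppv=ppv,
        fdr=1.0 - ppv,
        accuracy=float(np.trace(m)) / float(m.sum()),
    )


def compare_runs(
    acc_a, acc_b, paired: bool = True
) -> tuple[float, float]:
    """Two-sided t-test on two lists of per-run accuracies.

    Paired Student's t when ``paired`` (run counts must match), otherwise
    Welch's two-sample t.  Zero variance (of the paired differences, or
    of both samples) is degenerate and raises.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each accuracy list needs at least 2 runs")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal run counts")
        if np.std(a - b, ddof=1) == 0:
            raise DegenerateVarianceError(
                "paired differences have zero variance; t is undefined"
            )
        t, p = stats.ttest_rel(a, b)
    else:
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            raise DegenerateVarianceError(
                "both samples have zero variance; t is undefined"
            )
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class RunSummary:
    """Per-run accuracies with their sample mean and (n-1) standard deviation."""

    accuracies: list[float]
    mean: float
    std: float
    n_runs: int


def aggregate_runs(accuracies) -> RunSummary:
    """Summarize run accuracies as mean +/- sample std (std 0 for one run)."""
    acc = [float(a) for a in accuracies]
    if len(acc) == 0:
        raise ValueError("cannot aggregate an empty run list")
    std = float(np.std(acc, ddof=1)) if len(acc) > 1 else 0.0
    return RunSummary(
        accuracies=acc, mean=float(np.mean(acc)), std=std, n_runs=len(acc)
    )
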