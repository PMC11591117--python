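"""Labeled feature-matrix container and its delimited-text I/O.

A :class:`FeatureMatrix` is the package's in-memory currency: an
``n_samples x n_features`` real matrix with optional class labels and
stable column names.  On disk it is a comma-separated table with a header
row and a final ``label`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LABEL_COLUMN = "label"


@dataclass
class FeatureMatrix:
    """Samples-by-features real matrix with optional per-sample class labels.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` array of finite reals.
    labels
        Optional class id per sample, length ``n_samples``.
    column_ids
        Stable column names; generated as ``f0..f{p-1}`` when omitted.
    """

    values: np.ndarray
    labels: np.ndarray | None = None
    column_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN or Inf entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ValueError(
                    f"labels length {self.labels.shape[0]} != "
                    f"sample count {self.values.shape[0]}"
                )
        if not self.column_ids:
            self.column_ids = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.column_ids) != self.values.shape[1]:
            raise ValueError("column_ids length must equal feature count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take(self, indices: np.ndarray) -> "FeatureMatrix":
        """Row subset (new object; labels follow)."""
        labels = None if self.labels is None else self.labels[indices]
        return FeatureMatrix(self.values[indices], labels, list(self.column_ids))

    def select_columns(self, mask: np.ndarray) -> "FeatureMatrix":
        """Column subset by boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != self.n_features:
            raise ValueError("mask length must equal feature count")
        cols = [c for c, keep in zip(self.column_ids, mask) if keep]
        return FeatureMatrix(self.values[:, mask], self.labels, cols)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_ids)
        if self.labels is not None:
            df[LABEL_COLUMN] = self.labels
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        labels = None
        if LABEL_COLUMN in df.columns:
            labels = df[LABEL_COLUMN].to_numpy()
            df = df.drop(columns=[LABEL_COLUMN])
        return cls(df.to_numpy(dtype=float), labels, [str(c) for c in df.columns])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path))
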