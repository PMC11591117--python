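"""Canonical correlation analysis for two-view feature fusion.

CCA finds paired linear projections ``Wx``, ``Wy`` of two feature views
that maximize the correlation of the projected components,

    sigma = max_{Wx, Wy}  Wx' Cxy Wy / sqrt(Wx' Cxx Wx * Wy' Cyy Wy),

classically solved as a generalized eigenproblem on the covariance blocks
``Cxx^{-1} Cxy Cyy^{-1} Cyx``.  Here the equivalent — and numerically far
stabler — symmetric formulation is used: Cholesky-whiten each view's
(ridge-regularized) covariance and take the SVD of the whitened
cross-covariance.  The singular values are the canonical correlations,
sorted non-increasing, and the fused representation stacks (or sums) the
two projected views.

With high-dimensional deep features (p in the thousands, a few thousand
samples) the per-view covariances are singular, so a small ridge is added
by default: ``ridge = 1e-6 * trace(C)/p`` per view, user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg

from .containers import FeatureMatrix
from .exceptions import AlignmentError, NumericalRankError

RANK_RTOL = 1e-10  # singular values below RANK_RTOL * s_max are rank noise


@dataclass
class CCAModel:
    """Fitted CCA projections for two views.

    Attributes
    ----------
    Wx, Wy
        ``(p1, d)`` / ``(p2, d)`` projection matrices; training components
        ``(X - mean_x) @ Wx`` have unit variance under the regularized
        covariance.
    correlations
        The ``d`` canonical correlations, non-increasing, each in [0, 1].
    """

    Wx: np.ndarray
    Wy: np.ndarray
    correlations: np.ndarray
    mean_x: np.ndarray
    mean_y: np.ndarray
    std_x: np.ndarray | None
    std_y: np.ndarray | None
    ridge_x: float
    ridge_y: float

    @property
    def d(self) -> int:
        return self.Wx.shape[1]

    def truncate(self, d: int) -> "CCAModel":
        """Model restricted to the leading ``d`` canonical pairs."""
        if not 1 <= d <= self.d:
            raise ValueError(f"d must lie in [1, {self.d}]")
        return CCAModel(
            Wx=self.Wx[:, :d],
            Wy=self.Wy[:, :d],
            correlations=self.correlations[:d],
            mean_x=self.mean_x,
            mean_y=self.mean_y,
            std_x=self.std_x,
            std_y=self.std_y,
            ridge_x=self.ridge_x,
            ridge_y=self.ridge_y,
        )

    def _center(self, values: np.ndarray, mean: np.ndarray, std) -> np.ndarray:
        out = values - mean
        if std is not None:
            out = out / std
        return out

    def transform_x(self, X: FeatureMatrix) -> np.ndarray:
        if X.n_features != self.Wx.shape[0]:
            raise ValueError(
                f"view-1 has {X.n_features} columns, model expects {self.Wx.shape[0]}"
            )
        return self._center(X.values, self.mean_x, self.std_x) @ self.Wx

    def transform_y(self, Y: FeatureMatrix) -> np.ndarray:
        if Y.n_features != self.Wy.shape[0]:
            raise ValueError(
                f"view-2 has {Y.n_features} columns, model expects {self.Wy.shape[0]}"
            )
        return self._center(Y.values, self.mean_y, self.std_y) @ self.Wy

    def save(self, path) -> None:
        np.savez(
            path,
            Wx=self.Wx,
            Wy=self.Wy,
            correlations=self.correlations,
            mean_x=self.mean_x,
            mean_y=self.mean_y,
            std_x=np.array([]) if self.std_x is None else self.std_x,
            std_y=np.array([]) if self.std_y is None else self.std_y,
            ridge=np.array([self.ridge_x, self.ridge_y]),
        )

    @classmethod
    def load(cls, path) -> "CCAModel":
        with np.load(Path(path)) as z:
            std_x = z["std_x"] if z["std_x"].size else None
            std_y = z["std_y"] if z["std_y"].size else None
            return cls(
                Wx=z["Wx"],
                Wy=z["Wy"],
                correlations=z["correlations"],
                mean_x=z["mean_x"],
                mean_y=z["mean_y"],
                std_x=std_x,
                std_y=std_y,
                ridge_x=float(z["ridge"][0]),
                ridge_y=float(z["ridge"][1]),
            )


def _auto_ridge(cov: np.ndarray) -> float:
    p = cov.shape[0]
    return 1e-6 * float(np.trace(cov)) / p


def _whitener(cov: np.ndarray, ridge: float, view: str) -> np.ndarray:
    """Lower Cholesky factor of the regularized covariance."""
    p = cov.shape[0]
    try:
        return linalg.cholesky(cov + ridge * np.eye(p), lower=True)
    except linalg.LinAlgError as exc:
        raise NumericalRankError(
            f"{view} covariance is numerically singular with ridge={ridge}; "
            "pass ridge > 0 (or ridge='auto')"
        ) from exc


def fit_cca(
    X: FeatureMatrix,
    Y: FeatureMatrix,
    ridge: float | str = "auto",
    max_components: int | None = None,
    scale: bool = False,
) -> CCAModel:
    """Fit CCA on two aligned views.

    Parameters
    ----------
    ridge
        Non-negative scalar added to the diagonal of each within-view
        covariance, or ``"auto"`` for ``1e-6 * trace(C)/p`` per view.
    max_components
        Cap on the number of canonical pairs; default is
        ``min(p1, p2, n-1)`` truncated to the numerical rank of the
        whitened cross-covariance.
    scale
        If True, z-score each column before fitting (mean-centering alone
        is the default).
    """
    if X.n_samples != Y.n_samples:
        raise AlignmentError(
            f"views have {X.n_samples} and {Y.n_samples} samples; they must align"
        )
    n = X.n_samples
    if n < 3:
        raise ValueError("CCA needs at least 3 samples")
    if isinstance(ridge, str):
        if ridge != "auto":
            raise ValueError("ridge must be a non-negative scalar or 'auto'")
    elif ridge < 0:
        raise ValueError("ridge must be non-negative")

    mean_x = X.values.mean(axis=0)
    mean_y = Y.values.mean(axis=0)
    Xc = X.values - mean_x
    Yc = Y.values - mean_y
    std_x = std_y = None
    if scale:
        std_x = Xc.std(axis=0, ddof=1)
        std_y = Yc.std(axis=0, ddof=1)
        std_x[std_x == 0] = 1.0
        std_y[std_y == 0] = 1.0
        Xc = Xc / std_x
        Yc = Yc / std_y

    Cxx = Xc.T @ Xc / (n - 1)
    Cyy = Yc.T @ Yc / (n - 1)
    Cxy = Xc.T @ Yc / (n - 1)

    rx = _auto_ridge(Cxx) if ridge == "auto" else float(ridge)
    ry = _auto_ridge(Cyy) if ridge == "auto" else float(ridge)
    Lx = _whitener(Cxx, rx, "view-1")
    Ly = _whitener(Cyy, ry, "view-2")

    # K = Lx^{-1} Cxy Ly^{-T}; svd(K) gives canonical correlations
    K = linalg.solve_triangular(Lx, Cxy, lower=True)
    K = linalg.solve_triangular(Ly, K.T, lower=True).T
    U, s, Vt = linalg.svd(K, full_matrices=False)

    d = min(X.n_features, Y.n_features, n - 1)
    if s.size and s[0] > 0:
        d = min(d, int(np.sum(s > RANK_RTOL * s[0])))
    if max_components is not None:
        d = min(d, int(max_components))
    d = max(d, 1)

    Wx = linalg.solve_triangular(Lx, U[:, :d], lower=True, trans="T")
    Wy = linalg.solve_triangular(Ly, Vt.T[:, :d], lower=True, trans="T")
    corr = np.clip(s[:d], 0.0, None)
    return CCAModel(
        Wx=Wx,
        Wy=Wy,
        correlations=corr,
        mean_x=mean_x,
        mean_y=mean_y,
        std_x=std_x,
        std_y=std_y,
        ridge_x=rx,
        ridge_y=ry,
    )


def n_significant_components(model: CCAModel, n: int, alpha: float = 0.05) -> int:
    """Number of canonical pairs significant by Bartlett's sequential test.

    Tests H0: correlations k+1..d are all zero, via the chi-square
    approximation of Wilks' lambda,

        chi2_k = -(n - 1 - (p1 + p2 + 1)/2) * sum_{i>k} ln(1 - r_i^2)

    on ``(p1 - k)(p2 - k)`` degrees of freedom, stopping at the first
    non-significant k.  At least one component is always retained, so the
    fused representation is never empty.
    """
    from scipy import stats

    p1 = model.Wx.shape[0]
    p2 = model.Wy.shape[0]
    r2 = np.clip(model.correlations**2, 0.0, 1.0 - 1e-12)
    factor = n - 1 - (p1 + p2 + 1) / 2.0
    k = 0
    for k in range(model.d):
        chi2 = -factor * np.sum(np.log1p(-r2[k:]))
        df = (p1 - k) * (p2 - k)
        if factor <= 0 or stats.chi2.sf(chi2, df) >= alpha:
            break
    else:
        k = model.d
    return max(k, 1)


def fuse(
    model: CCAModel,
    X: FeatureMatrix,
    Y: FeatureMatrix,
    mode: str = "concat",
) -> FeatureMatrix:
    """Fuse two views through a fitted CCA model.

    ``sum`` returns ``Wx'(x - mean_x) + Wy'(y - mean_y)`` (width d);
    ``concat`` stacks the two projections side by side (width 2d), which
    preserves view-specific information and is the default.  Labels pass
    through unchanged (the two views must agree on them).
    """
    if mode not in ("sum", "concat"):
        raise ValueError("mode must be 'sum' or 'concat'")
    if X.n_samples != Y.n_samples:
        raise AlignmentError("views must have identical sample counts")
    labels = X.labels if X.labels is not None else Y.labels
    if (
        X.labels is not None
        and Y.labels is not None
        and not np.array_equal(X.labels, Y.labels)
    ):
        raise AlignmentError("views carry conflicting labels")
    zx = model.transform_x(X)
    zy = model.transform_y(Y)
    if mode == "sum":
        values = zx + zy
        cols = [f"cc{i}" for i in range(model.d)]
    else:
        values = np.hstack([zx, zy])
        cols = [f"ccx{i}" for i in range(model.d)] + [
            f"ccy{i}" for i in range(model.d)
        ]
    return FeatureMatrix(values, labels, cols)
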