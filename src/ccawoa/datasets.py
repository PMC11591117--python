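"""Synthetic dual-view feature data and optimizer benchmark objectives.

The generator emulates the situation where two deep networks describe the
same set of images: each sample has a class identity (e.g. four dementia
stages) and each "view" is a real-valued feature vector in which only a
known subset of dimensions carries class signal.  The informative
dimensions of the two views are driven by a shared latent factor model, so
their cross-view canonical structure is tunable — which is exactly what
CCA fusion exploits — while the remaining dimensions are pure noise.

Generative model, for a sample of class ``c``::

    z_x = sqrt(rho) * z + sqrt(1 - rho) * e_x      (view-1 latent noise)
    z_y = sqrt(rho) * z + sqrt(1 - rho) * e_y      (view-2 latent noise)
    L_x = mu_c + z_x,   L_y = mu_c + z_y
    X_info = L_x @ A + noise_sd * N(0, 1)
    Y_info = L_y @ B + noise_sd * N(0, 1)

with ``z, e_x, e_y ~ N(0, I)`` latent vectors, ``mu_c`` class centroids
shared by both views, and ``A``, ``B`` random unit-column loadings.
``rho`` (``view_correlation``) is the correlation of the within-class
latent variation between the views; the class-mean structure is always
shared, because both views describe the same samples.  Non-informative
columns are independent standard normal noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .containers import FeatureMatrix


@dataclass
class DualViewDataset:
    """Two aligned feature views of the same labeled samples.

    ``informative_mask_x`` / ``informative_mask_y`` mark the planted
    class-informative columns of each view (ground truth for feature
    selection experiments).
    """

    X: FeatureMatrix
    Y: FeatureMatrix
    labels: np.ndarray
    informative_mask_x: np.ndarray
    informative_mask_y: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.n_samples != self.Y.n_samples:
            raise ValueError("views must have identical sample counts")

    @property
    def n_samples(self) -> int:
        return self.X.n_samples


def generate_dual_view(
    n_per_class: int | Sequence[int] = 1000,
    n_classes: int = 4,
    p1: int = 1280,
    p2: int = 1280,
    n_informative: int = 128,
    latent_dim: int = 8,
    noise_sd: float = 2.0,
    view_correlation: float = 0.9,
    seed: int = 0,
    class_sep: float = 6.0,
) -> DualViewDataset:
    """Generate a dual-view labeled dataset with planted informative columns.

    Parameters
    ----------
    n_per_class
        Samples per class; a scalar for balanced classes (the default 1000
        mirrors a balanced four-stage dementia dataset) or one count per
        class for imbalanced regimes.
    p1, p2
        Total feature count of each view.
    n_informative
        Number of class-informative columns planted in *each* view
        (``<= min(p1, p2)``); positions are randomized and returned as
        boolean masks.
    latent_dim
        Rank of the shared latent factor space.
    noise_sd
        Standard deviation of i.i.d. measurement noise added to the
        informative columns.
    view_correlation
        In ``[0, 1]``; correlation of the within-class latent variation
        between views (1 = the views share their latents exactly).
    class_sep
        Total expected distance scale between class centroids in latent
        space; spread over ``latent_dim`` dimensions.
    """
    if np.isscalar(n_per_class):
        counts = np.full(n_classes, int(n_per_class))
    else:
        counts = np.asarray(n_per_class, dtype=int)
        if counts.shape[0] != n_classes:
            raise ValueError("per-class counts must have length n_classes")
    if np.any(counts < 2):
        raise ValueError("n_per_class must be >= 2 for every class")
    if min(p1, p2, latent_dim, n_classes) < 1:
        raise ValueError("dimensions must be positive")
    if not 0 <= n_informative <= min(p1, p2):
        raise ValueError("n_informative must be in [0, min(p1, p2)]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0.0 <= view_correlation <= 1.0:
        raise ValueError("view_correlation must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    n = int(counts.sum())
    labels = np.repeat(np.arange(n_classes), counts)

    mu = rng.normal(0.0, class_sep / np.sqrt(latent_dim), size=(n_classes, latent_dim))
    z = rng.standard_normal((n, latent_dim))
    ex = rng.standard_normal((n, latent_dim))
    ey = rng.standard_normal((n, latent_dim))
    rho = view_correlation
    zx = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * ex
    zy = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * ey
    lat_x = mu[labels] + zx
    lat_y = mu[labels] + zy

    def _loadings(p_info: int) -> np.ndarray:
        a = rng.standard_normal((latent_dim, p_info))
        return a / np.linalg.norm(a, axis=0, keepdims=True)

    def _view(lat: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
        values = rng.standard_normal((n, p))  # noise columns
        mask = np.zeros(p, dtype=bool)
        if n_informative > 0:
            pos = rng.permutation(p)[:n_informative]
            mask[pos] = True
            info = lat @ _loadings(n_informative)
            if noise_sd > 0:
                info = info + noise_sd * rng.standard_normal(info.shape)
            values[:, pos] = info
        return values, mask

    xv, mask_x = _view(lat_x, p1)
    yv, mask_y = _view(lat_y, p2)

    params = dict(
        n_per_class=counts.tolist(),
        n_classes=n_classes,
        p1=p1,
        p2=p2,
        n_informative=n_informative,
        latent_dim=latent_dim,
        noise_sd=noise_sd,
        view_correlation=view_correlation,
        class_sep=class_sep,
        seed=int(seed),
    )
    return DualViewDataset(
        X=FeatureMatrix(xv, labels, [f"v1_{i}" for i in range(p1)]),
        Y=FeatureMatrix(yv, labels, [f"v2_{i}" for i in range(p2)]),
        labels=labels,
        informative_mask_x=mask_x,
        informative_mask_y=mask_y,
        seed=int(seed),
        params=params,
    )


def write_dataset(dataset: DualViewDataset, out_dir) -> dict[str, Path]:
    """Write views, ground-truth masks and a manifest to ``out_dir``.

    Views are comma-separated tables with a final ``label`` column; masks
    are one 0/1 per line aligned with the view's columns; the manifest
    records the generator parameters verbatim so the dataset can be
    regenerated byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "view1": out / "view1.csv",
        "view2": out / "view2.csv",
        "mask1": out / "informative_mask_view1.txt",
        "mask2": out / "informative_mask_view2.txt",
        "manifest": out / "manifest.json",
    }
    dataset.X.write_csv(paths["view1"])
    dataset.Y.write_csv(paths["view2"])
    np.savetxt(paths["mask1"], dataset.informative_mask_x.astype(int), fmt="%d")
    np.savetxt(paths["mask2"], dataset.informative_mask_y.astype(int), fmt="%d")
    paths["manifest"].write_text(json.dumps(dataset.params, indent=2) + "\n")
    return paths


def dataset_from_manifest(manifest_path) -> DualViewDataset:
    """Regenerate a dataset from a manifest written by :func:`write_dataset`."""
    params = json.loads(Path(manifest_path).read_text())
    return generate_dual_view(**params)


@dataclass
class ObjectiveFunction:
    """Box-bounded scalar objective for optimizer sanity checks."""

    name: str
    dim: int
    lower: np.ndarray
    upper: np.ndarray
    evaluate: Callable[[np.ndarray], float]
    known_optimum: float
    optimum_position: np.ndarray


def benchmark_objective(name: str, dim: int) -> ObjectiveFunction:
    """Standard continuous test functions (minimum 0 at the origin).

    ``sphere``: f(y) = sum(y^2), bounds [-100, 100]^D.
    ``rastrigin``: f(y) = 10 D + sum(y^2 - 10 cos(2 pi y)), bounds
    [-5.12, 5.12]^D.
    """
    if dim < 1:
        raise ValueError("dimension must be >= 1")
    if name == "sphere":
        lo, hi = -100.0, 100.0

        def f(y: np.ndarray) -> float:
            return float(np.sum(np.square(y)))

    elif name == "rastrigin":
        lo, hi = -5.12, 5.12

        def f(y: np.ndarray) -> float:
            y = np.asarray(y, dtype=float)
            return float(10.0 * dim + np.sum(y * y - 10.0 * np.cos(2.0 * np.pi * y)))

    else:
        raise ValueError(f"unsupported objective {name!r}; choose sphere or rastrigin")
    return ObjectiveFunction(
        name=name,
        dim=dim,
        lower=np.full(dim, lo),
        upper=np.full(dim, hi),
        evaluate=f,
        known_optimum=0.0,
        optimum_position=np.zeros(dim),
    )


def random_mask_fitness_baseline(
    fitness: Callable[[np.ndarray], float],
    dim: int,
    n_masks: int,
    density: float,
    seed: int,
) -> list[float]:
    """Fitness of independent Bernoulli(density) masks — a null distribution.

    Any wrapper optimizer worth running should beat the minimum of this
    baseline on a planted problem.
    """
    if not 0.0 < density < 1.0:
        raise ValueError("density must lie strictly in (0, 1)")
    if n_masks < 1:
        raise ValueError("n_masks must be >= 1")
    rng = np.random.default_rng(seed)
    masks = (rng.random((n_masks, dim)) < density).astype(int)
    return [float(fitness(m)) for m in masks]
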