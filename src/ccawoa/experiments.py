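"""Canned benchmark experiments: planted-feature recovery and ablation.

These wire the synthetic generator, wrapper fitness, optimizers and
evaluation into the two study designs the package is validated on:

* **Planted recovery** — generate a dual-view dataset with known
  informative columns, run bE-WOA on the concatenated views, and measure
  how much of the planted ground truth the best mask recovers, alongside
  a random-mask null baseline.
* **Ablation** — compare test accuracy of each raw view, the CCA-fused
  representation, and the fused representation after WOA / bE-WOA
  selection, over repeated stratified splits.

The default problem sizes (600 samples, 50 columns per view with 10
informative each, rank-10 latents) keep a full multi-seed experiment
within minutes on one CPU; `docs/methods.md` discusses the choice of
generator parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bewoa import SelectionResult, run_bewoa
from .containers import FeatureMatrix
from .datasets import generate_dual_view, random_mask_fitness_baseline
from .fitness import FitnessSpec, mask_objective
from .metrics import stratified_split
from .pipeline import PipelineConfig, PipelineResult, run_pipeline

#: Desk-scale planted-problem conditions shared by tests and scripts.
PLANTED_CONDITIONS = dict(
    n_per_class=150,
    n_classes=4,
    p1=50,
    p2=50,
    n_informative=10,
    latent_dim=10,
    noise_sd=2.0,
    view_correlation=0.9,
    class_sep=6.0,
)


@dataclass
class RecoveryOutcome:
    """Per-seed result of one planted-recovery run."""

    seed: int
    recovered_fraction: float
    n_selected: int
    best_fitness: float
    baseline_min: float
    selection: SelectionResult = field(repr=False, default=None)

    @property
    def beats_baseline(self) -> bool:
        return self.best_fitness <= self.baseline_min


def concatenated_views(dataset) -> tuple[FeatureMatrix, np.ndarray]:
    """Stack the two views column-wise; return the matrix and the
    concatenated ground-truth informative mask."""
    combined = FeatureMatrix(
        np.hstack([dataset.X.values, dataset.Y.values]),
        dataset.labels,
        dataset.X.column_ids + dataset.Y.column_ids,
    )
    truth = np.concatenate(
        [dataset.informative_mask_x, dataset.informative_mask_y]
    )
    return combined, truth


def planted_recovery_run(
    seed: int,
    n_whales: int = 30,
    max_it: int = 150,
    n_baseline_masks: int = 50,
    conditions: dict | None = None,
) -> RecoveryOutcome:
    """One planted-recovery run: bE-WOA on concatenated views vs ground truth.

    The wrapper fitness uses stratified 5-fold validation inside the
    training split (low-noise guidance); the random-mask baseline draws
    Bernoulli(0.5) masks scored by the same objective.
    """
    cond = dict(PLANTED_CONDITIONS)
    if conditions:
        cond.update(conditions)
    data = generate_dual_view(seed=100 + seed, **cond)
    combined, truth = concatenated_views(data)
    train, _test = stratified_split(combined, 0.8, seed=seed)
    objective = mask_objective(
        train, FitnessSpec(seed=seed, validation_scheme="kfold")
    )
    result = run_bewoa(
        objective,
        dim=combined.n_features,
        n_whales=n_whales,
        max_it=max_it,
        seed=seed,
    )
    baseline = random_mask_fitness_baseline(
        objective, combined.n_features, n_baseline_masks, 0.5, seed=1000 + seed
    )
    recovered = float(
        (result.best_mask.astype(bool) & truth).sum() / truth.sum()
    )
    return RecoveryOutcome(
        seed=seed,
        recovered_fraction=recovered,
        n_selected=result.n_selected,
        best_fitness=result.best_fitness,
        baseline_min=float(min(baseline)),
        selection=result,
    )


def ablation_experiment(
    seed: int = 0,
    n_runs: int = 5,
    n_whales: int = 20,
    max_it: int = 60,
    arms: tuple[str, ...] = ("view1", "view2", "fused", "fused+bewoa"),
    conditions: dict | None = None,
) -> PipelineResult:
    """Multi-run ablation of the pipeline arms on the planted problem."""
    cond = dict(PLANTED_CONDITIONS)
    if conditions:
        cond.update(conditions)
    config = PipelineConfig(
        synthetic=cond,
        n_whales=n_whales,
        max_it=max_it,
        n_runs=n_runs,
        arms=arms,
        validation_scheme="kfold",
    )
    return run_pipeline(config, seed=seed)
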