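"""End-to-end fusion/selection pipeline and its ablation arms.

The full pipeline mirrors a dual-view classification study: stratified
80:20 train/test split -> CCA fitted on the training rows only -> both
splits projected and fused -> wrapper feature selection on the fused
training features (with an inner validation split, never the test set)
-> final kNN classifier scored on the held-out test rows.  Ablation arms
evaluate each single view raw, the fused vector without selection, and
the fused vector after conventional binary WOA or binary-enhanced WOA
selection.

Every run is reproducible from (config, seed): per-run split, fitness
and optimizer seeds are spawned from one seed sequence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bewoa import SelectionResult, run_bewoa, run_binary_woa
from .cca import fit_cca, fuse, n_significant_components
from .containers import FeatureMatrix
from .datasets import DualViewDataset, generate_dual_view
from .fitness import FitnessSpec, masked_knn_accuracy, mask_objective
from .metrics import (
    ConfusionReport,
    RunSummary,
    aggregate_runs,
    compare_runs,
    confusion,
    stratified_split_indices,
)

ALL_ARMS = ("view1", "view2", "fused", "fused+woa", "fused+bewoa")


@dataclass
class PipelineConfig:
    """Fully describes one pipeline experiment.

    Either ``view1_path``/``view2_path`` point at feature tables on disk,
    or ``synthetic`` holds generator parameters for
    :func:`~ccawoa.datasets.generate_dual_view`.
    """

    view1_path: str | None = None
    view2_path: str | None = None
    synthetic: dict = field(default_factory=dict)
    train_fraction: float = 0.8
    # CCA
    ridge: float | str = "auto"
    fusion_mode: str = "concat"
    max_components: int | None = None
    component_rule: str = "bartlett"  # or "rank": keep all numerically valid pairs
    # optimizer
    optimizer: str = "bewoa"
    n_whales: int = 20
    max_it: int = 60
    pool_capacity: int | None = None
    migrate_fraction: float = 0.1
    transfer: str = "sigmoid"
    # wrapper fitness
    k_neighbors: int = 5
    validation_scheme: str = "holdout"
    val_fraction: float = 0.2
    # protocol
    n_runs: int = 5
    arms: tuple[str, ...] = ALL_ARMS

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "arms" in raw:
            raw["arms"] = tuple(raw["arms"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """Per-run records, per-arm summaries, confusion reports, and the paired
    t-test of the selected-vs-fused arms when both were run."""

    records: pd.DataFrame
    summaries: dict[str, RunSummary]
    reports: dict[str, ConfusionReport]
    selection: SelectionResult | None
    ttest_bewoa_vs_fused: tuple[float, float] | None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "runs.csv", index=False)
        rows = [
            {"arm": arm, "mean": s.mean, "std": s.std, "n_runs": s.n_runs}
            for arm, s in self.summaries.items()
        ]
        pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
        for arm, rep in self.reports.items():
            safe = arm.replace("+", "_")
            rep.to_frame().to_csv(out / f"confusion_{safe}.csv", index=False)


def _load_views(config: PipelineConfig, seed: int) -> DualViewDataset:
    if config.view1_path and config.view2_path:
        X = FeatureMatrix.read_csv(config.view1_path)
        Y = FeatureMatrix.read_csv(config.view2_path)
        return DualViewDataset(
            X=X,
            Y=Y,
            labels=X.labels,
            informative_mask_x=np.zeros(X.n_features, dtype=bool),
            informative_mask_y=np.zeros(Y.n_features, dtype=bool),
            seed=seed,
        )
    params = dict(config.synthetic)
    params.setdefault("seed", seed)
    return generate_dual_view(**params)


def _final_accuracy(
    train: FeatureMatrix,
    test: FeatureMatrix,
    k_neighbors: int,
    mask: np.ndarray | None = None,
):
    full = np.ones(train.n_features, dtype=bool) if mask is None else mask
    acc = masked_knn_accuracy(full, train, test, k_neighbors)
    return acc


def _predictions(train, test, k_neighbors, mask=None):
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.preprocessing import MinMaxScaler

    m = np.ones(train.n_features, dtype=bool) if mask is None else np.asarray(mask, bool)
    scaler = MinMaxScaler().fit(train.values[:, m])
    knn = KNeighborsClassifier(n_neighbors=k_neighbors)
    knn.fit(scaler.transform(train.values[:, m]), train.labels)
    return knn.predict(scaler.transform(test.values[:, m]))


def run_pipeline(config: PipelineConfig, seed: int = 0) -> PipelineResult:
    """Execute the configured arms for ``config.n_runs`` runs.

    Data are generated (or loaded) once; each run redraws the train/test
    split and the optimizer seed, which is the run-to-run variability the
    mean +/- std summaries describe.
    """
    ss = np.random.SeedSequence(seed)
    data_seed, *run_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_runs + 1)
    ]
    data = _load_views(config, data_seed)

    rows: list[dict] = []
    reports: dict[str, ConfusionReport] = {}
    last_selection: SelectionResult | None = None
    class_order = np.unique(data.labels).tolist()

    for run, rseed in enumerate(run_seeds):
        tr_idx, te_idx = stratified_split_indices(
            data.labels, config.train_fraction, rseed
        )
        x_tr, x_te = data.X.take(tr_idx), data.X.take(te_idx)
        y_tr, y_te = data.Y.take(tr_idx), data.Y.take(te_idx)

        need_fused = any(a.startswith("fused") for a in config.arms)
        if need_fused:
            model = fit_cca(
                x_tr, y_tr, ridge=config.ridge, max_components=config.max_components
            )
            if config.component_rule == "bartlett":
                model = model.truncate(n_significant_components(model, x_tr.n_samples))
            elif config.component_rule != "rank":
                raise ValueError(f"unknown component_rule {config.component_rule!r}")
            fused_tr = fuse(model, x_tr, y_tr, config.fusion_mode)
            fused_te = fuse(model, x_te, y_te, config.fusion_mode)

        for arm in config.arms:
            mask = None
            n_selected = None
            if arm == "view1":
                train, test = x_tr, x_te
            elif arm == "view2":
                train, test = y_tr, y_te
            elif arm in ("fused", "fused+woa", "fused+bewoa"):
                train, test = fused_tr, fused_te
                if arm != "fused":
                    spec = FitnessSpec(
                        k_neighbors=config.k_neighbors,
                        validation_scheme=config.validation_scheme,
                        val_fraction=config.val_fraction,
                        seed=rseed,
                    )
                    objective = mask_objective(train, spec)
                    if arm == "fused+bewoa":
                        sel = run_bewoa(
                            objective,
                            dim=train.n_features,
                            n_whales=config.n_whales,
                            max_it=config.max_it,
                            pool_capacity=config.pool_capacity,
                            migrate_fraction=config.migrate_fraction,
                            transfer=config.transfer,
                            seed=rseed,
                        )
                        last_selection = sel
                    else:
                        sel = run_binary_woa(
                            objective,
                            dim=train.n_features,
                            n_whales=config.n_whales,
                            max_it=config.max_it,
                            transfer=config.transfer,
                            seed=rseed,
                        )
                    mask = sel.best_mask.astype(bool)
                    n_selected = sel.n_selected
            else:
                raise ValueError(f"unknown ablation arm {arm!r}")
            acc = _final_accuracy(train, test, config.k_neighbors, mask)
            rows.append(
                {
                    "run": run,
                    "arm": arm,
                    "accuracy": acc,
                    "n_selected": n_selected
                    if n_selected is not None
                    else train.n_features,
                    "seed": rseed,
                }
            )
            if run == len(run_seeds) - 1:
                pred = _predictions(train, test, config.k_neighbors, mask)
                reports[arm] = confusion(test.labels, pred, class_order)

    records = pd.DataFrame(rows)
    summaries = {
        arm: aggregate_runs(records.loc[records.arm == arm, "accuracy"])
        for arm in config.arms
    }
    ttest = None
    if "fused" in config.arms and "fused+bewoa" in config.arms and config.n_runs >= 2:
        try:
            ttest = compare_runs(
                summaries["fused+bewoa"].accuracies,
                summaries["fused"].accuracies,
                paired=True,
            )
        except Exception:  # zero-variance runs: no test to report
            ttest = None
    return PipelineResult(
        records=records,
        summaries=summaries,
        reports=reports,
        selection=last_selection,
        ttest_bewoa_vs_fused=ttest,
    )
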