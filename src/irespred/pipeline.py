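"""End-to-end glue: featurize, screen, train, evaluate, interpret."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import MetricSet, pooled_test_metrics
from .interpret import FeatureEffect, feature_effects
from .kmers import FeaturizationConfig, FeatureMatrix, build_matrix
from .preselect import PreselectionConfig
from .records import SequenceRecord
from .training import (
    CVPlan,
    FoldModel,
    HyperparameterGrid,
    double_loop_cv,
    stratified_folds,
)


@dataclass
class PipelineResult:
    matrix: FeatureMatrix
    folds: list[FoldModel]
    metrics: MetricSet
    activity: np.ndarray
    active: np.ndarray

    def effects(self, threshold: float = 0.1) -> list[FeatureEffect]:
        return feature_effects(self.folds, self.matrix, threshold=threshold)


def run_pipeline(
    records: list[SequenceRecord],
    fcfg: FeaturizationConfig = FeaturizationConfig(),
    pre_cfg: PreselectionConfig = PreselectionConfig(),
    grid: HyperparameterGrid = HyperparameterGrid(),
    n_outer: int = 10,
    n_inner: int = 10,
    n_trees: int = 1000,
    seed: int = 0,
    backend: str = "lightgbm",
) -> PipelineResult:
    """Run the full modelling pipeline on one set of records."""
    activity = np.array([r.activity for r in records])
    active = np.array([r.active for r in records])
    matrix = build_matrix(records, fcfg)
    plan = stratified_folds(active, n_outer, seed)
    folds = double_loop_cv(
        matrix,
        activity,
        active,
        grid,
        plan,
        pre_cfg=pre_cfg,
        n_inner=n_inner,
        n_trees=n_trees,
        seed=seed,
        backend=backend,
    )
    metrics = pooled_test_metrics(folds, activity, active)
    return PipelineResult(matrix, folds, metrics, activity, active)
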