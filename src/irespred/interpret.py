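"""From trained fold models to feature-level conclusions.

Feature importances (total split-induced variance reduction averaged over
trees) are normalized per model by the model's maximum, then averaged
across the outer-CV fold models in which the feature was pre-selected.
A feature is *robust* when every fold retained it and *predictive* when
its mean normalized importance reaches a threshold (default 0.1).  The
direction of a feature's effect comes from its partial dependence curve:
substitute each observed value into the feature's column for all training
rows, average the model predictions, average across folds, and classify
by the sign of the mean finite-difference slope (flat or undefined slopes
count as negative).  Positional effects of one k-mer can form "islands"
of consecutive robust windows; effects shared by several groups yield a
per-window consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kmers import FeatureDescriptor, FeatureMatrix
from .training import FoldModel

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class ImportanceProfile:
    feature: FeatureDescriptor
    per_fold: dict[int, float]
    folds_selected: int
    mean_norm_importance: float


@dataclass
class PartialDependenceCurve:
    feature: FeatureDescriptor
    values: np.ndarray
    ybar: np.ndarray


@dataclass(frozen=True)
class FeatureEffect:
    feature: FeatureDescriptor
    direction: str
    signed_effect: float


@dataclass
class PositionalIsland:
    kmer: str
    windows: list[tuple[int, int]]
    effects: list[float]

    @property
    def span(self) -> tuple[int, int]:
        return (self.windows[0][0], self.windows[-1][1])


@dataclass
class ConsensusEffect:
    kmer: str
    window: tuple[int, int]
    effect: float | None
    supporting_groups: list[str]


def fold_importances(fold: FoldModel) -> dict[FeatureDescriptor, float]:
    """Raw importances of one fold model divided by the fold's maximum."""
    raw = fold.raw_importances()
    if len(raw) == 0:
        return {}
    top = raw.max()
    if top <= 0:
        return {d: 0.0 for d in fold.descriptors}
    return {d: float(v / top) for d, v in zip(fold.descriptors, raw)}


def aggregate_importances(
    folds: Sequence[FoldModel],
) -> list[ImportanceProfile]:
    """Mean normalized importance per feature over the folds holding it."""
    if not folds:
        raise ValueError("no fold models to aggregate")
    per_feature: dict[FeatureDescriptor, dict[int, float]] = {}
    for fold in folds:
        for d, v in fold_importances(fold).items():
            per_feature.setdefault(d, {})[fold.fold] = v
    return [
        ImportanceProfile(
            feature=d,
            per_fold=by_fold,
            folds_selected=len(by_fold),
            mean_norm_importance=float(np.mean(list(by_fold.values()))),
        )
        for d, by_fold in per_feature.items()
    ]


def partial_dependence(
    folds: Sequence[FoldModel],
    matrix: FeatureMatrix,
    feature: FeatureDescriptor,
) -> PartialDependenceCurve:
    """Average substitution-based partial dependence across fold models.

    The value grid is the sorted unique observed values of the feature;
    for each fold retaining the feature, each grid value is substituted
    into that column for all of the fold's training rows and predictions
    averaged.
    """
    col_full = matrix.descriptors.index(feature)
    grid = np.unique(matrix.values[:, col_full]).astype(float)
    curves = []
    for fold in folds:
        if feature not in fold.descriptors:
            continue
        j = fold.descriptors.index(feature)
        X = matrix.values[np.ix_(fold.train_idx, fold.columns)].astype(float)
        stacked = np.repeat(X, len(grid), axis=0)
        stacked[:, j] = np.tile(grid, X.shape[0])
        preds = fold.model.predict(stacked).reshape(X.shape[0], len(grid))
        curves.append(preds.mean(axis=0))
    if not curves:
        raise ValueError("feature retained by no fold model")
    return PartialDependenceCurve(feature, grid, np.mean(curves, axis=0))


def classify_direction(curve: PartialDependenceCurve) -> str:
    """Sign of the mean finite-difference slope; non-positive -> negative."""
    if len(curve.values) < 2:
        return NEGATIVE
    slopes = np.diff(curve.ybar) / np.diff(curve.values)
    return POSITIVE if slopes.mean() > 0 else NEGATIVE


def select_robust_predictive(
    profiles: Sequence[ImportanceProfile],
    directions: Mapping[FeatureDescriptor, str],
    threshold: float = 0.1,
    n_folds: int = 10,
) -> list[FeatureEffect]:
    """Features retained by every fold with mean importance >= threshold."""
    effects = []
    for prof in profiles:
        if prof.folds_selected != n_folds:
            continue
        if prof.mean_norm_importance < threshold:
            continue
        direction = directions[prof.feature]
        sign = 1.0 if direction == POSITIVE else -1.0
        effects.append(
            FeatureEffect(
                feature=prof.feature,
                direction=direction,
                signed_effect=sign * prof.mean_norm_importance,
            )
        )
    return effects


def feature_effects(
    folds: Sequence[FoldModel],
    matrix: FeatureMatrix,
    threshold: float = 0.1,
) -> list[FeatureEffect]:
    """Aggregate, select robust/predictive features, attach directions."""
    profiles = aggregate_importances(folds)
    candidates = [
        p
        for p in profiles
        if p.folds_selected == len(folds) and p.mean_norm_importance >= threshold
    ]
    directions = {
        p.feature: classify_direction(partial_dependence(folds, matrix, p.feature))
        for p in candidates
    }
    return select_robust_predictive(
        candidates, directions, threshold=threshold, n_folds=len(folds)
    )


def common_and_unique(
    per_group: Mapping[str, Sequence[FeatureEffect]],
) -> tuple[set[FeatureDescriptor], dict[FeatureDescriptor, str]]:
    """Features selected by >= 2 groups vs by exactly one.

    Returns ``(common, unique)`` where ``unique`` maps a feature to its
    single selecting group.  Identity is (kmer, scope, window).
    """
    if len(per_group) < 2:
        raise ValueError("need effects from at least two groups")
    seen: dict[FeatureDescriptor, list[str]] = {}
    for group, effects in per_group.items():
        for eff in effects:
            seen.setdefault(eff.feature, []).append(group)
    common = {d for d, gs in seen.items() if len(gs) >= 2}
    unique = {d: gs[0] for d, gs in seen.items() if len(gs) == 1}
    return common, unique


def find_islands(
    window_effects: Mapping[tuple[int, int], float],
    kmer: str,
    step: int = 10,
) -> list[PositionalIsland]:
    """Maximal runs of >= 2 consecutive robust windows for one k-mer."""
    wins = sorted(window_effects)
    islands: list[PositionalIsland] = []
    run: list[tuple[int, int]] = []
    for win in wins:
        if run and win[0] - run[-1][0] == step:
            run.append(win)
        else:
            if len(run) >= 2:
                islands.append(
                    PositionalIsland(kmer, run, [window_effects[w] for w in run])
                )
            run = [win]
    if len(run) >= 2:
        islands.append(
            PositionalIsland(kmer, run, [window_effects[w] for w in run])
        )
    return islands


def consensus_effects(
    group_window_effects: Mapping[str, Mapping[tuple[int, int], float]],
    kmer: str,
) -> list[ConsensusEffect]:
    """Per-window consensus across groups for one k-mer.

    A window has a consensus when at least two groups hold a robust
    effect of the same sign there; its magnitude is the largest
    supporting |effect| (the largest effect supported by multiple
    groups).  Sign conflicts with no two-group majority give none.
    """
    if len(group_window_effects) < 2:
        return []
    windows = sorted(
        {w for effects in group_window_effects.values() for w in effects}
    )
    out = []
    for win in windows:
        entries = [
            (g, effects[win])
            for g, effects in group_window_effects.items()
            if win in effects
        ]
        pos = [(g, e) for g, e in entries if e > 0]
        neg = [(g, e) for g, e in entries if e <= 0]
        best: tuple[float, list[str]] | None = None
        for side in (pos, neg):
            if len(side) >= 2:
                mag = max(abs(e) for _, e in side)
                if best is None or mag > best[0]:
                    signed = mag if side is pos else -mag
                    best = (abs(signed), [g for g, _ in side])
                    best_signed = signed
        if best is None:
            out.append(ConsensusEffect(kmer, win, None, []))
        else:
            out.append(ConsensusEffect(kmer, win, best_signed, best[1]))
    return out


def gc_content(rna: str) -> float:
    """G+C fraction of one sequence."""
    return (rna.count("G") + rna.count("C")) / len(rna)


def gc_content_compare(
    group_a: Sequence[str], group_b: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-sequence GC distributions and a two-sided rank-sum p-value."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    gc_a = np.array([gc_content(s) for s in group_a])
    gc_b = np.array([gc_content(s) for s in group_b])
    p = float(
        stats.mannwhitneyu(gc_a, gc_b, alternative="two-sided").pvalue
    )
    return gc_a, gc_b, p


def effects_table(
    per_group: Mapping[str, Sequence[FeatureEffect]],
) -> pd.DataFrame:
    """Long-format effects table mirroring the heat-map figures."""
    rows = []
    for group, effects in per_group.items():
        for eff in effects:
            d = eff.feature
            rows.append(
                {
                    "group": group,
                    "kmer": d.kmer,
                    "scope": d.scope,
                    "window_start": d.window[0] if d.window else pd.NA,
                    "window_end": d.window[1] if d.window else pd.NA,
                    "direction": eff.direction,
                    "signed_effect": eff.signed_effect,
                }
            )
    return pd.DataFrame(rows)
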