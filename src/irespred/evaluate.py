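"""Performance metrics and the supporting resampling experiments.

Five headline metrics: R-squared (1 - SS_res/SS_tot on the given pairs),
Pearson r, Spearman rho on the regression task; AUC-ROC and AUC-PR on
the induced active/inactive classification (scores are the predicted
activities).  Headline values are computed on predictions pooled across
the outer test folds; per-fold summaries carry the dispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

if TYPE_CHECKING:  # pragma: no cover
    from .records import SequenceRecord
    from .training import FoldModel


@dataclass(frozen=True)
class MetricSet:
    r2: float
    pearson: float
    spearman: float
    auc_roc: float
    auc_pr: float
    n: int
    n_positive: int


def regression_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float]:
    """(R-squared, Pearson r, Spearman rho) for one prediction vector."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance y_true: R-squared undefined")
    r2 = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot
    if np.all(y_pred == y_pred[0]):
        return r2, 0.0, 0.0
    pearson = float(stats.pearsonr(y_true, y_pred).statistic)
    spearman = float(stats.spearmanr(y_true, y_pred).statistic)
    return r2, pearson, spearman


def classification_metrics(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[float, float]:
    """(AUC-ROC, AUC-PR) separating active from inactive sequences.

    AUC-ROC follows the rank (Mann-Whitney) formulation with mid-ranked
    ties; AUC-PR is the step-wise integral of the precision-recall curve
    (no linear interpolation).
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("both classes required for classification metrics")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def metric_set(
    y_true: np.ndarray, y_pred: np.ndarray, labels: np.ndarray
) -> MetricSet:
    r2, pe, sp = regression_metrics(y_true, y_pred)
    labels = np.asarray(labels, dtype=bool)
    if labels.any() and not labels.all():
        roc, pr = classification_metrics(labels, y_pred)
    else:
        warnings.warn("single-class fold: AUC metrics undefined")
        roc, pr = float("nan"), float("nan")
    return MetricSet(
        r2=r2,
        pearson=pe,
        spearman=sp,
        auc_roc=roc,
        auc_pr=pr,
        n=len(y_true),
        n_positive=int(labels.sum()),
    )


def pooled_test_metrics(
    folds: "Sequence[FoldModel]", activity: np.ndarray, active: np.ndarray
) -> MetricSet:
    """Metrics on outer-fold test predictions pooled over all folds."""
    activity = np.asarray(activity, dtype=float)
    active = np.asarray(active, dtype=bool)
    idx = np.concatenate([f.test_idx for f in folds])
    if len(np.unique(idx)) != len(idx):
        raise ValueError("fold test sets overlap")
    pred = np.concatenate([f.y_pred for f in folds])
    return metric_set(activity[idx], pred, active[idx])


def per_fold_metrics(
    folds: "Sequence[FoldModel]", activity: np.ndarray, active: np.ndarray
) -> pd.DataFrame:
    """Per-fold metric table with a mean +/- sd summary row."""
    activity = np.asarray(activity, dtype=float)
    active = np.asarray(active, dtype=bool)
    rows = []
    for f in folds:
        ms = metric_set(activity[f.test_idx], f.y_pred, active[f.test_idx])
        rows.append(
            {"fold": f.fold, "r2": ms.r2, "pearson": ms.pearson,
             "spearman": ms.spearman, "auc_roc": ms.auc_roc,
             "auc_pr": ms.auc_pr, "n": ms.n, "n_positive": ms.n_positive}
        )
    table = pd.DataFrame(rows)
    return table


def group_division_test(
    records: "list[SequenceRecord]",
    observed_r2: Mapping[str, float],
    pipeline: Callable[["list[SequenceRecord]"], float],
    n_perm: int = 200,
    seed: int = 0,
    statistic: str = "variance",
) -> float:
    """Permutation support for the chosen division into origin groups.

    Group labels are permuted across records (group sizes preserved), the
    per-group pipeline is rerun on each permuted division, and the spread
    of per-group test R-squared (variance by default, ``range`` as an
    alternative) is compared against the observed spread.  Returns the
    add-one permutation p-value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(observed_r2) < 2:
        raise ValueError("need at least two groups")

    def spread(values: Iterable[float]) -> float:
        v = np.asarray(list(values), dtype=float)
        return float(np.var(v)) if statistic == "variance" else float(
            v.max() - v.min()
        )

    observed = spread(observed_r2.values())
    groups = [r.group for r in records]
    rng = np.random.default_rng(seed)
    from dataclasses import replace

    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        permuted = [replace(r, group=g) for r, g in zip(records, perm)]
        by_group: dict[str, list] = {}
        for r in permuted:
            by_group.setdefault(r.group, []).append(r)
        r2s = [pipeline(members) for g, members in sorted(by_group.items())]
        if spread(r2s) >= observed:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def incidence_subsample_curve(
    records: "list[SequenceRecord]",
    target_positive_counts: Sequence[int],
    evaluate: Callable[["list[SequenceRecord]"], float],
    n_reps: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Model performance as the number of positive sequences shrinks.

    For each target count, positives are randomly downsampled to that
    count (all negatives kept), the pipeline is retrained and its test
    R-squared recorded, over ``n_reps`` subsamples per target.
    """
    positives = [r for r in records if r.active]
    negatives = [r for r in records if not r.active]
    rng = np.random.default_rng(seed)
    rows = []
    for target in target_positive_counts:
        if target > len(positives):
            raise ValueError(f"target {target} exceeds available positives")
        r2s = []
        for _ in range(n_reps):
            chosen = rng.choice(len(positives), size=target, replace=False)
            subset = [positives[i] for i in chosen] + negatives
            r2s.append(evaluate(subset))
        rows.append(
            {
                "target_positives": target,
                "mean_r2": float(np.mean(r2s)),
                "sd_r2": float(np.std(r2s, ddof=1)) if n_reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
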