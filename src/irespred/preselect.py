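"""Univariate feature screening with FDR control and a prevalence floor.

Each candidate feature is tested for association with IRES activity on a
training partition only: Spearman rank correlation for count features,
two-sided Mann-Whitney U (activity of carriers vs non-carriers) for
presence features.  P-values are adjusted with the Benjamini-Hochberg
step-up over all candidates jointly; a feature survives when its adjusted
p is at or below the FDR (default 0.05) and it is non-zero in at least a
minimum fraction of the partition's samples (default 10%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kmers import COUNT, PRESENCE, FeatureDescriptor, FeatureMatrix


@dataclass(frozen=True)
class PreselectionConfig:
    fdr: float = 0.05
    min_prevalence: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if not 0 <= self.min_prevalence < 1:
            raise ValueError("min_prevalence must be in [0, 1)")


@dataclass
class AssociationResult:
    feature: FeatureDescriptor
    statistic: float
    p: float
    q: float
    prevalence: float
    kept: bool


def associate(
    values: np.ndarray, activity: np.ndarray, representation: str
) -> tuple[float, float]:
    """Association of one feature with activity.

    Counts: Spearman rho with two-sided p.  Presence: two-sided
    Mann-Whitney U comparing activity where the feature is present vs
    absent.  A zero-variance feature yields (nan, 1.0).
    """
    values = np.asarray(values, dtype=float)
    activity = np.asarray(activity, dtype=float)
    if len(values) != len(activity) or len(values) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(values == values[0]):
        return float("nan"), 1.0
    if representation == COUNT:
        res = stats.spearmanr(values, activity)
        return float(res.statistic), float(res.pvalue)
    if representation == PRESENCE:
        a1 = activity[values != 0]
        a0 = activity[values == 0]
        res = stats.mannwhitneyu(a1, a0, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown representation {representation!r}")


def _spearman_columns(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Spearman rho and two-sided p (t approximation, as in
    the scalar routine), vectorized over features."""
    n = X.shape[0]
    rx = pd.DataFrame(X).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx.T @ ry) / denom
    rho = np.clip(rho, -1.0, 1.0)
    p = np.ones_like(rho)
    ok = np.isfinite(rho) & (np.abs(rho) < 1.0)
    t = rho[ok] * np.sqrt((n - 2) / (1.0 - rho[ok] ** 2))
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    exact = np.isfinite(rho) & (np.abs(rho) == 1.0)
    p[exact] = 0.0
    p[~np.isfinite(rho)] = 1.0
    rho[~np.isfinite(rho)] = np.nan
    return rho, p


def _mannwhitney_columns(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise two-sided Mann-Whitney U with tie correction and
    continuity correction (normal approximation), carriers vs rest."""
    n = X.shape[0]
    present = (X != 0).astype(float)
    r = stats.rankdata(y)
    n1 = present.sum(axis=0)
    n2 = n - n1
    R1 = present.T @ r
    U1 = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, t_counts = np.unique(y, return_counts=True)
    tie_term = float((t_counts**3 - t_counts).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        sigma = np.sqrt(sigma2)
        z = (np.abs(U1 - mu) - 0.5) / sigma
    z = np.maximum(z, 0.0)
    p = np.where((n1 == 0) | (n2 == 0) | (sigma == 0), 1.0, 2.0 * stats.norm.sf(z))
    p = np.clip(p, 0.0, 1.0)
    stat = np.where((n1 == 0) | (n2 == 0), np.nan, U1)
    return stat, p


def benjamini_hochberg(
    ps: np.ndarray, fdr: float
) -> tuple[np.ndarray, np.ndarray]:
    """Standard BH step-up.

    Returns monotone-enforced adjusted p-values ``q`` and the rejection
    mask ``q <= fdr``.
    """
    ps = np.asarray(ps, dtype=float)
    m = len(ps)
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    qs_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qs_sorted = np.clip(qs_sorted, 0.0, 1.0)
    qs = np.empty(m)
    qs[order] = qs_sorted
    return qs, qs <= fdr


def _screen(
    X: np.ndarray, reps: np.ndarray, activity: np.ndarray, cfg: PreselectionConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Core screen: per-column statistic, p, q, prevalence, kept mask."""
    prevalence = (X != 0).mean(axis=0)
    stat = np.full(X.shape[1], np.nan)
    p = np.ones(X.shape[1])
    count_cols = np.flatnonzero(reps == COUNT)
    pres_cols = np.flatnonzero(reps == PRESENCE)
    if count_cols.size:
        stat[count_cols], p[count_cols] = _spearman_columns(
            X[:, count_cols].astype(float), activity
        )
    if pres_cols.size:
        stat[pres_cols], p[pres_cols] = _mannwhitney_columns(
            X[:, pres_cols], activity
        )
    # constant columns carry no information
    const = np.all(X == X[0:1, :], axis=0)
    p[const] = 1.0
    stat[const] = np.nan

    q, rejected = benjamini_hochberg(p, cfg.fdr)
    kept = rejected & (prevalence >= cfg.min_prevalence)
    return stat, p, q, prevalence, kept


def select_columns(
    matrix: FeatureMatrix,
    rows: np.ndarray,
    activity: np.ndarray,
    cfg: PreselectionConfig,
) -> np.ndarray:
    """Indices of surviving columns, screening only the given rows.

    Lightweight variant of :func:`preselect` for cross-validation loops,
    where the screen is recomputed on every training partition.
    """
    reps = np.array([d.representation for d in matrix.descriptors])
    *_, kept = _screen(
        matrix.values[rows], reps, np.asarray(activity, dtype=float)[rows], cfg
    )
    return np.flatnonzero(kept)


def preselect(
    matrix: FeatureMatrix,
    activity: np.ndarray,
    cfg: PreselectionConfig = PreselectionConfig(),
) -> tuple[FeatureMatrix, list[AssociationResult]]:
    """Screen every column of ``matrix`` against ``activity``.

    BH is applied across all candidate features as one family; the
    surviving columns keep their original order.  An empty survivor set
    is returned as an empty matrix with a warning (training must then
    refuse or fall back).
    """
    activity = np.asarray(activity, dtype=float)
    if matrix.n_samples != len(activity):
        raise ValueError("matrix rows do not align with activity vector")
    reps = np.array([d.representation for d in matrix.descriptors])
    stat, p, q, prevalence, kept = _screen(matrix.values, reps, activity, cfg)

    results = [
        AssociationResult(
            feature=matrix.descriptors[j],
            statistic=float(stat[j]),
            p=float(p[j]),
            q=float(q[j]),
            prevalence=float(prevalence[j]),
            kept=bool(kept[j]),
        )
        for j in range(matrix.n_features)
    ]
    kept_cols = np.flatnonzero(kept)
    if kept_cols.size == 0:
        warnings.warn("no features survive pre-selection")
    return matrix.subset_columns(kept_cols), results


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = r.feature
        rows.append(
            {
                "kmer": d.kmer,
                "scope": d.scope,
                "window_start": d.window[0] if d.window else pd.NA,
                "window_end": d.window[1] if d.window else pd.NA,
                "representation": d.representation,
                "statistic": r.statistic,
                "p": r.p,
                "q": r.q,
                "prevalence": r.prevalence,
                "kept": r.kept,
            }
        )
    return pd.DataFrame(rows)
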