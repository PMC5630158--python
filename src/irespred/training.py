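"""Boosted regression forests with nested cross-validated tuning.

The learner is stochastic gradient boosting of least-squares regression
trees: each new tree fits the gradient of the residual error on a random
fraction ``f`` of the training samples, split search draws
``floor(sqrt(M'))`` of the M' pre-selected features at every node, tree
depth is unbounded and leaves must hold at least ``m`` samples.  ``m``,
the learning rate ``r`` and ``f`` are chosen by a double-loop (nested)
10-fold cross-validation: for each outer training set, an inner 10-fold
loop scores every grid cell by validation R-squared, and the winning cell
is refit on the full outer training set and evaluated on the held-out
outer fold.  Folds are stratified so active (above-floor) sequences are
balanced across folds.

The ensemble backend is LightGBM by default, configured to the contract
above; scikit-learn's ``GradientBoostingRegressor`` is available as an
alternative backend.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product

import numpy as np

from .evaluate import regression_metrics
from .kmers import FeatureDescriptor, FeatureMatrix
from .preselect import PreselectionConfig, select_columns

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Hyperparameters:
    """(m, r, f) plus ensemble size; features per split follow sqrt(M')."""

    m: int = 15
    r: float = 0.1
    f: float = 0.8
    n_trees: int = 1000

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.m < 1 or self.r <= 0 or not 0 < self.f <= 1:
            raise ValueError(f"invalid hyperparameters {self}")


@dataclass(frozen=True)
class HyperparameterGrid:
    m: tuple[int, ...] = (15, 30, 60)
    r: tuple[float, ...] = (0.01, 0.05, 0.1)
    f: tuple[float, ...] = (0.5, 0.8)

    def cells(self, n_trees: int) -> list[Hyperparameters]:
        if not (self.m and self.r and self.f):
            raise ValueError("empty hyperparameter grid")
        return [
            Hyperparameters(m=m, r=r, f=f, n_trees=n_trees)
            for m, r, f in product(self.m, self.r, self.f)
        ]


@dataclass
class CVPlan:
    """Fold assignment with active/inactive strata balanced across folds."""

    n_folds: int
    fold_of: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def stratified_folds(
    active: np.ndarray, n_folds: int, seed: int
) -> CVPlan:
    """Random partition into folds, splitting each activity stratum evenly."""
    active = np.asarray(active, dtype=bool)
    n = len(active)
    if n < n_folds:
        raise ValueError("fewer samples than folds")
    if active.sum() < n_folds:
        logger.warning("fewer active samples than folds; some folds get none")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=np.int32)
    for stratum in (True, False):
        idx = np.flatnonzero(active == stratum)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % n_folds
    return CVPlan(n_folds=n_folds, fold_of=fold_of, seed=seed)


class MeanPredictor:
    """Constant fallback used when pre-selection leaves no features."""

    def __init__(self, mean: float):
        self.mean = float(mean)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self.mean)

    def raw_importances(self) -> np.ndarray:
        return np.zeros(0)


class BoostedForest:
    """Trained ensemble satisfying the predictor contract.

    ``raw_importances`` are total split-induced variance-reduction (gain)
    values accumulated per feature and averaged across trees; a feature
    never used for a split scores exactly 0.
    """

    def __init__(self, model, n_trees: int, backend: str):
        self._model = model
        self.n_trees = n_trees
        self.backend = backend

    def predict(self, X: np.ndarray) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper warns about absent feature names
            # even though fitting and prediction both use plain arrays
            warnings.simplefilter("ignore", UserWarning)
            return self._model.predict(np.asarray(X, dtype=np.float64))

    def raw_importances(self) -> np.ndarray:
        if self.backend == "lightgbm":
            gain = self._model.booster_.feature_importance(importance_type="gain")
            return np.asarray(gain, dtype=float) / self.n_trees
        total = np.zeros(self._model.n_features_in_)
        for stage in self._model.estimators_:
            tree = stage[0].tree_
            total += tree.compute_feature_importances(normalize=False)
        return total / self.n_trees


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    hp: Hyperparameters,
    seed: int,
    backend: str = "lightgbm",
) -> BoostedForest:
    """Fit one boosted forest; deterministic given ``seed``."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, M = X.shape
    if M < 1:
        raise ValueError("refusing to train on an empty feature matrix")
    if backend == "lightgbm":
        import lightgbm as lgb

        model = lgb.LGBMRegressor(
            n_estimators=hp.n_trees,
            learning_rate=hp.r,
            subsample=hp.f,
            subsample_freq=1 if hp.f < 1 else 0,
            min_child_samples=hp.m,
            min_child_weight=1e-9,
            num_leaves=int(min(4096, max(2, math.ceil(n / hp.m)))),
            max_depth=-1,
            max_bin=63,
            min_data_in_bin=1,
            feature_fraction_bynode=max(1, math.isqrt(M)) / M,
            n_jobs=1,
            random_state=seed,
            deterministic=True,
            verbose=-1,
        )
        model.fit(X, y)
    elif backend == "sklearn":
        from sklearn.ensemble import GradientBoostingRegressor

        model = GradientBoostingRegressor(
            n_estimators=hp.n_trees,
            learning_rate=hp.r,
            subsample=hp.f,
            min_samples_leaf=hp.m,
            max_features="sqrt",
            max_depth=None,
            random_state=seed,
        )
        model.fit(X, y)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return BoostedForest(model, hp.n_trees, backend)


@dataclass
class FoldModel:
    """One outer-fold predictor with its pre-selected features and metrics."""

    fold: int
    hyperparameters: Hyperparameters
    columns: np.ndarray
    descriptors: list[FeatureDescriptor]
    model: BoostedForest | MeanPredictor
    train_idx: np.ndarray
    test_idx: np.ndarray
    y_pred: np.ndarray
    inner_scores: dict[Hyperparameters, float]
    r2: float

    def raw_importances(self) -> np.ndarray:
        imp = self.model.raw_importances()
        if len(imp) != len(self.descriptors):
            return np.zeros(len(self.descriptors))
        return imp


def double_loop_cv(
    matrix: FeatureMatrix,
    activity: np.ndarray,
    active: np.ndarray,
    grid: HyperparameterGrid,
    plan: CVPlan,
    pre_cfg: PreselectionConfig = PreselectionConfig(),
    n_inner: int = 10,
    n_trees: int = 1000,
    seed: int = 0,
    backend: str = "lightgbm",
) -> list[FoldModel]:
    """Nested-CV training: one tuned model per outer fold.

    Pre-selection is recomputed on every inner training set and on every
    outer training set, so held-out data never influence screening or
    fitting.  A training partition whose screen keeps no features falls
    back to a constant mean predictor (with a log warning); a grid cell
    that fails to train scores -inf.
    """
    activity = np.asarray(activity, dtype=float)
    active = np.asarray(active, dtype=bool)
    cells = grid.cells(n_trees)
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(plan.n_folds * 2)

    folds: list[FoldModel] = []
    for ofold in range(plan.n_folds):
        train_idx = plan.train_indices(ofold)
        test_idx = plan.test_indices(ofold)
        inner_plan = stratified_folds(
            active[train_idx], n_inner, int(fold_seeds[2 * ofold]) % (2**31)
        )
        fit_seed = int(fold_seeds[2 * ofold + 1]) % (2**31)

        # inner loop: screen once per inner split, score every grid cell
        scores = {hp: [] for hp in cells}
        for ifold in range(n_inner):
            itrain = train_idx[inner_plan.train_indices(ifold)]
            ival = train_idx[inner_plan.test_indices(ifold)]
            cols = select_columns(matrix, itrain, activity, pre_cfg)
            for hp in cells:
                if len(cols) == 0 or len(itrain) < 2 * hp.m:
                    scores[hp].append(-np.inf)
                    logger.warning("grid cell %s untrainable on inner fold", hp)
                    continue
                try:
                    est = train_ensemble(
                        matrix.values[np.ix_(itrain, cols)],
                        activity[itrain],
                        hp,
                        fit_seed,
                        backend,
                    )
                    pred = est.predict(matrix.values[np.ix_(ival, cols)])
                    r2, _, _ = regression_metrics(activity[ival], pred)
                    scores[hp].append(r2)
                except Exception as exc:  # noqa: BLE001 - cell-level failure
                    logger.warning("grid cell %s failed: %s", hp, exc)
                    scores[hp].append(-np.inf)
        mean_scores = {hp: float(np.mean(s)) for hp, s in scores.items()}
        # highest mean inner R2; ties -> smaller r, larger m, grid order
        best = min(
            enumerate(cells),
            key=lambda ic: (-mean_scores[ic[1]], ic[1].r, -ic[1].m, ic[0]),
        )[1]

        # final model on the full outer training set
        cols = select_columns(matrix, train_idx, activity, pre_cfg)
        if len(cols) == 0:
            logger.warning("outer fold %d: empty screen, mean fallback", ofold)
            model: BoostedForest | MeanPredictor = MeanPredictor(
                activity[train_idx].mean()
            )
        else:
            model = train_ensemble(
                matrix.values[np.ix_(train_idx, cols)],
                activity[train_idx],
                best,
                fit_seed,
                backend,
            )
        y_pred = model.predict(matrix.values[np.ix_(test_idx, cols)]) if len(
            cols
        ) else model.predict(matrix.values[test_idx])
        r2, _, _ = regression_metrics(activity[test_idx], y_pred)
        folds.append(
            FoldModel(
                fold=ofold,
                hyperparameters=best,
                columns=cols,
                descriptors=[matrix.descriptors[j] for j in cols],
                model=model,
                train_idx=train_idx,
                test_idx=test_idx,
                y_pred=y_pred,
                inner_scores=mean_scores,
                r2=r2,
            )
        )
    return folds
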