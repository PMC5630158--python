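import numpy as np
import pytest

from irespred.interpret import (
    NEGATIVE,
    POSITIVE,
    ConsensusEffect,
    FeatureEffect,
    ImportanceProfile,
    PartialDependenceCurve,
    aggregate_importances,
    classify_direction,
    common_and_unique,
    consensus_effects,
    feature_effects,
    find_islands,
    fold_importances,
    gc_content,
    gc_content_compare,
    partial_dependence,
    select_robust_predictive,
)
from irespred.kmers import COUNT, FeatureDescriptor, FeatureMatrix
from irespred.preselect import PreselectionConfig
from irespred.training import HyperparameterGrid, double_loop_cv, stratified_folds


def desc(kmer, window=None):
    scope = "global" if window is None else "window"
    return FeatureDescriptor(kmer, scope, COUNT, window)


class _StubFold:
    """FoldModel stand-in exposing just what interpretation needs."""

    def __init__(self, fold, descriptors, raw, model=None, train_idx=None,
                 columns=None):
        self.fold = fold
        self.descriptors = descriptors
        self._raw = np.asarray(raw, float)
        self.model = model
        self.train_idx = train_idx
        self.columns = columns

    def raw_importances(self):
        return self._raw


class _StumpModel:
    """Single decision stump on column j: x <= cut -> lo else hi."""

    def __init__(self, j, cut=0.5, lo=0.0, hi=1.0):
        self.j, self.cut, self.lo, self.hi = j, cut, lo, hi

    def predict(self, X):
        return np.where(X[:, self.j] <= self.cut, self.lo, self.hi)


class TestFoldImportances:
    def test_normalized_by_fold_maximum(self):
        fold = _StubFold(0, [desc("A"), desc("C"), desc("G")], [2.0, 4.0, 1.0])
        norm = fold_importances(fold)
        assert norm[desc("A")] == 0.5
        assert norm[desc("C")] == 1.0
        assert norm[desc("G")] == 0.25

    def test_unused_feature_scores_zero_and_argmax_invariant(self):
        fold = _StubFold(0, [desc("A"), desc("C")], [3.0, 0.0])
        norm = fold_importances(fold)
        assert norm[desc("C")] == 0.0
        assert max(norm, key=norm.get) == desc("A")

    def test_all_zero_importances_flagged_as_zeros(self):
        fold = _StubFold(0, [desc("A"), desc("C")], [0.0, 0.0])
        assert set(fold_importances(fold).values()) == {0.0}


class TestAggregation:
    def test_mean_and_folds_selected(self):
        descs = [desc("A")]
        folds = [_StubFold(i, descs, [1.0]) for i in range(10)]
        profiles = aggregate_importances(folds)
        assert profiles[0].folds_selected == 10
        assert profiles[0].mean_norm_importance == 1.0

    def test_feature_absent_from_one_fold(self):
        folds = [_StubFold(i, [desc("A"), desc("C")], [1.0, 0.5]) for i in range(9)]
        folds.append(_StubFold(9, [desc("A")], [1.0]))
        by_feature = {p.feature: p for p in aggregate_importances(folds)}
        assert by_feature[desc("C")].folds_selected == 9
        assert by_feature[desc("A")].folds_selected == 10

    def test_empty_fold_list_is_error(self):
        with pytest.raises(ValueError):
            aggregate_importances([])


class TestPartialDependence:
    def _stump_setup(self):
        X = np.array([[0], [0], [1], [1], [2]], dtype=np.int32)
        matrix = FeatureMatrix(
            [f"s{i}" for i in range(5)], [desc("A")], X
        )
        fold = _StubFold(
            0, [desc("A")], [1.0],
            model=_StumpModel(0),
            train_idx=np.arange(5),
            columns=np.array([0]),
        )
        return matrix, fold

    def test_stump_curve_matches_brute_force_substitution(self):
        matrix, fold = self._stump_setup()
        curve = partial_dependence([fold], matrix, desc("A"))
        assert curve.values.tolist() == [0.0, 1.0, 2.0]
        # brute force: substitute v for every row, average predictions
        for v, ybar in zip(curve.values, curve.ybar):
            X = matrix.values.astype(float).copy()
            X[:, 0] = v
            assert ybar == pytest.approx(_StumpModel(0).predict(X).mean())
        assert curve.ybar.tolist() == [0.0, 1.0, 1.0]

    def test_constant_model_gives_flat_curve(self):
        matrix, fold = self._stump_setup()
        fold.model = _StumpModel(0, lo=2.0, hi=2.0)
        curve = partial_dependence([fold], matrix, desc("A"))
        assert np.all(curve.ybar == 2.0)

    def test_feature_in_no_fold_is_error(self):
        matrix, fold = self._stump_setup()
        with pytest.raises(ValueError):
            partial_dependence([fold], matrix, desc("C"))


class TestDirection:
    @pytest.mark.parametrize(
        "v,ybar,expected",
        [
            ([0, 1, 2], [0, 1, 2], POSITIVE),
            ([0, 1, 2], [2, 1, 0], NEGATIVE),
            ([0, 1], [1, 1], NEGATIVE),  # flat counts as negative
            ([0], [5.0], NEGATIVE),  # single point: undefined -> negative
        ],
    )
    def test_average_derivative_rule(self, v, ybar, expected):
        curve = PartialDependenceCurve(
            desc("A"), np.asarray(v, float), np.asarray(ybar, float)
        )
        assert classify_direction(curve) == expected

    def test_nonuniform_grid_uses_slopes_not_differences(self):
        # increments: +1 over width 1, -0.5 over width 10; mean slope > 0
        curve = PartialDependenceCurve(
            desc("A"), np.array([0.0, 1.0, 11.0]), np.array([0.0, 1.0, 0.5])
        )
        assert classify_direction(curve) == POSITIVE


class TestSelection:
    def _profile(self, d, folds_selected, mean):
        return ImportanceProfile(d, {}, folds_selected, mean)

    def test_robust_and_predictive_kept_with_sign(self):
        profiles = [
            self._profile(desc("A"), 10, 0.15),
            self._profile(desc("C"), 9, 0.9),
            self._profile(desc("G"), 10, 0.05),
        ]
        directions = {desc("A"): POSITIVE}
        effects = select_robust_predictive(profiles, directions, 0.1, n_folds=10)
        assert len(effects) == 1
        assert effects[0].feature == desc("A")
        assert effects[0].signed_effect == pytest.approx(0.15)

    def test_negative_direction_flips_sign(self):
        profiles = [self._profile(desc("A"), 5, 0.4)]
        effects = select_robust_predictive(
            profiles, {desc("A"): NEGATIVE}, 0.1, n_folds=5
        )
        assert effects[0].signed_effect == pytest.approx(-0.4)


class TestCommonUnique:
    def test_set_algebra(self):
        eff = lambda d: FeatureEffect(d, POSITIVE, 0.5)
        per_group = {
            "dsrna": [eff(desc("A")), eff(desc("C"))],
            "retro": [eff(desc("A")), eff(desc("G"))],
        }
        common, unique = common_and_unique(per_group)
        assert common == {desc("A")}
        assert unique == {desc("C"): "dsrna", desc("G"): "retro"}
        all_selected = {desc("A"), desc("C"), desc("G")}
        assert common | set(unique) == all_selected
        assert not common & set(unique)

    def test_single_group_is_error(self):
        with pytest.raises(ValueError):
            common_and_unique({"retro": []})


class TestIslands:
    def test_three_consecutive_windows_form_one_island(self):
        effects = {(-60, -40): 0.3, (-50, -30): 0.4, (-40, -20): 0.2}
        islands = find_islands(effects, "UU", step=10)
        assert len(islands) == 1
        assert islands[0].span == (-60, -20)

    def test_nonadjacent_windows_form_no_island(self):
        assert find_islands({(-60, -40): 0.3, (-30, -10): 0.4}, "UU") == []

    def test_two_separate_runs_are_two_islands(self):
        effects = {
            (-160, -140): 0.2, (-150, -130): 0.2,
            (-60, -40): 0.3, (-50, -30): 0.4,
        }
        islands = find_islands(effects, "G")
        assert len(islands) == 2


class TestConsensus:
    def test_agreeing_groups_take_max_magnitude(self):
        res = consensus_effects(
            {"dsrna": {(-60, -40): 0.3}, "retro": {(-60, -40): 0.2}}, "CU"
        )
        assert res[0].effect == pytest.approx(0.3)
        assert set(res[0].supporting_groups) == {"dsrna", "retro"}

    def test_sign_disagreement_gives_none(self):
        res = consensus_effects(
            {"dsrna": {(-60, -40): 0.3}, "retro": {(-60, -40): -0.2}}, "CU"
        )
        assert res[0].effect is None

    def test_single_supporting_group_gives_none(self):
        res = consensus_effects(
            {"dsrna": {(-60, -40): 0.3}, "retro": {(-30, -10): 0.2}}, "CU"
        )
        assert all(c.effect is None for c in res)


class TestGCContent:
    def test_extreme_sequences(self):
        assert gc_content("GCGC") == 1.0
        assert gc_content("AUAU") == 0.0

    def test_identical_groups_large_p(self):
        seqs = ["ACGU", "GGCC", "AUGC"]
        *_, p = gc_content_compare(seqs, list(seqs))
        assert p > 0.9

    def test_disjoint_gc_ranges_small_p(self):
        low = ["AUAUAUAUAU"] * 10
        high = ["GCGCGCGCGC"] * 10
        gc_a, gc_b, p = gc_content_compare(low, high)
        # exact rank-sum: all 10 vs 10 separated
        assert p < 1e-3
        assert gc_a.max() < gc_b.min()


class TestEndToEndEffects:
    def test_planted_signal_direction_recovered(self, rng):
        # activity rises with column 0, falls with column 1
        n = 300
        X = rng.poisson(1.5, size=(n, 8)).astype(np.int32)
        y = X[:, 0] - 1.0 * X[:, 1] + rng.normal(0, 0.2, n)
        descs = [desc(k) for k in ("A", "C", "G", "U", "AA", "AC", "AG", "AU")]
        matrix = FeatureMatrix([f"s{i}" for i in range(n)], descs, X)
        active = y > np.quantile(y, 0.8)
        plan = stratified_folds(active, 3, seed=0)
        folds = double_loop_cv(
            matrix, y, active,
            HyperparameterGrid(m=(10,), r=(0.1,), f=(1.0,)),
            plan, pre_cfg=PreselectionConfig(min_prevalence=0.0),
            n_inner=3, n_trees=60, seed=5,
        )
        effects = feature_effects(folds, matrix, threshold=0.1)
        by_feature = {e.feature: e for e in effects}
        assert by_feature[desc("A")].direction == POSITIVE
        assert by_feature[desc("C")].direction == NEGATIVE
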