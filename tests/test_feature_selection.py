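import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from gvtax.feature_selection import (
    ImportanceRanking,
    default_forest,
    impurity_importance,
    permutation_importance_ranking,
    prevalence_screen,
    rfe_curve,
    select_final_features,
    spearman_cluster,
)
from gvtax.io_features import FeatureMatrix

from conftest import toy_matrix


def _fit_forest(matrix, y, seed=0, n_estimators=100):
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    model.fit(matrix.to_frame(), y)
    return model


# ---------------------------------------------------------------------------
# prevalence_screen
# ---------------------------------------------------------------------------

class TestPrevalenceScreen:
    def _two_order_matrix(self):
        # order A: g0-g3, order B: g4-g7.  V1 in 1/4 of A, 0/4 of B.
        # V2 in every genome.  V3 in 2/4 of A and 1/4 of B.
        values = np.array(
            [
                [1, 1, 1],
                [0, 1, 1],
                [0, 1, 0],
                [0, 1, 0],
                [0, 1, 0],
                [0, 1, 1],
                [0, 1, 0],
                [0, 1, 0],
            ]
        )
        matrix = toy_matrix(values, gvog_names=["V1", "V2", "V3"])
        orders = {f"g{i}": ("A" if i < 4 else "B") for i in range(8)}
        return matrix, orders

    def test_any_vs_every_order_mode(self):
        matrix, orders = self._two_order_matrix()
        assert prevalence_screen(matrix, orders, 0.25, "any-order") == [
            "gc_content", "V1", "V2", "V3",
        ]
        assert prevalence_screen(matrix, orders, 0.25, "every-order") == [
            "gc_content", "V2", "V3",
        ]

    def test_ubiquitous_gvog_kept_under_both_modes(self):
        matrix, orders = self._two_order_matrix()
        for mode in ("any-order", "every-order"):
            assert "V2" in prevalence_screen(matrix, orders, 0.9, mode)

    def test_zero_threshold_keeps_everything(self):
        matrix, orders = self._two_order_matrix()
        kept = prevalence_screen(matrix, orders, 0.0)
        assert kept == ["gc_content", "V1", "V2", "V3"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        matrix = toy_matrix(rng.integers(0, 2, size=(30, 20)))
        orders = {f"g{i}": f"O{i % 3}" for i in range(30)}
        previous = None
        for thr in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            kept = set(prevalence_screen(matrix, orders, thr))
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_unlabelled_genome_is_an_error(self):
        matrix, orders = self._two_order_matrix()
        del orders["g3"]
        with pytest.raises(ValueError, match="g3"):
            prevalence_screen(matrix, orders)


# ---------------------------------------------------------------------------
# spearman_cluster
# ---------------------------------------------------------------------------

class TestSpearmanCluster:
    def test_identical_columns_share_a_cluster(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 2, size=50)
        matrix = toy_matrix(np.column_stack([col, col]), gvog_names=["Va", "Vb"])
        cs = spearman_cluster(matrix, distance_threshold=0.01)
        cluster_of = {f: i for i, c in enumerate(cs.clusters) for f in c}
        assert cluster_of["Va"] == cluster_of["Vb"]

    def test_independent_columns_split_at_half_threshold(self):
        rng = np.random.default_rng(1)
        values = rng.integers(0, 2, size=(200, 2))
        matrix = toy_matrix(values, gvog_names=["Va", "Vb"])
        cs = spearman_cluster(matrix, distance_threshold=0.5)
        cluster_of = {f: i for i, c in enumerate(cs.clusters) for f in c}
        assert cluster_of["Va"] != cluster_of["Vb"]

    def test_zero_threshold_gives_singletons(self):
        rng = np.random.default_rng(2)
        matrix = toy_matrix(rng.integers(0, 2, size=(30, 5)))
        cs = spearman_cluster(matrix, distance_threshold=0.0)
        assert all(len(c) == 1 for c in cs.clusters)
        assert len(cs.clusters) == len(matrix.feature_names)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        raw = rng.normal(size=(80, 4))
        m1 = FeatureMatrix([f"g{i}" for i in range(80)], list("abcd"), raw)
        transformed = raw.copy()
        transformed[:, 1] = np.exp(raw[:, 1])  # strictly monotone
        m2 = FeatureMatrix([f"g{i}" for i in range(80)], list("abcd"), transformed)
        c1 = spearman_cluster(m1, 0.7)
        c2 = spearman_cluster(m2, 0.7)
        assert c1.clusters == c2.clusters

    def test_needs_two_features(self):
        m = FeatureMatrix(["g0"], ["only"], [[0.5]])
        with pytest.raises(ValueError, match="at least 2"):
            spearman_cluster(m)

    def test_representative_follows_supplied_ranking(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 2, size=50)
        matrix = toy_matrix(np.column_stack([col, col]), gvog_names=["Va", "Vb"])
        ranking = ImportanceRanking("impurity", {"Va": (0.1, 0), "Vb": (0.9, 0), "gc_content": (0.0, 0)})
        cs = spearman_cluster(matrix, 0.01, ranking=ranking)
        pair_cluster = next(c for c in cs.clusters if "Va" in c)
        rep = cs.representatives[cs.clusters.index(pair_cluster)]
        assert rep == "Vb"


# ---------------------------------------------------------------------------
# rfe_curve
# ---------------------------------------------------------------------------

def _signal_plus_noise(n=200, informative=10, noise=90, seed=6):
    """Two classes; `informative` features track the class (0.9/0.1), the rest
    are fair coins."""
    rng = np.random.default_rng(seed)
    y = np.array(["A", "B"] * (n // 2))
    p_inf = np.where((y == "A")[:, None], 0.9, 0.1)
    inf = rng.random((n, informative)) < p_inf
    noise_block = rng.integers(0, 2, size=(n, noise))
    matrix = toy_matrix(np.column_stack([inf, noise_block]))
    return matrix, y


class TestRfeCurve:
    def test_full_size_equals_plain_cv(self):
        matrix, y = _signal_plus_noise(n=100, informative=5, noise=15)
        total = len(matrix.feature_names)
        curve = rfe_curve(matrix, y, [total], cv_folds=5, seed=0)
        cv = StratifiedKFold(5, shuffle=True, random_state=0)
        expected = cross_val_score(
            default_forest(0), matrix.to_frame(), y, cv=cv, scoring="accuracy"
        )
        assert curve[0][1] == pytest.approx(expected.mean())

    def test_known_signal_support_plateaus_early(self):
        matrix, y = _signal_plus_noise()
        total = len(matrix.feature_names)
        curve = rfe_curve(matrix, y, [10, total], cv_folds=5, seed=0)
        acc_small, acc_full = curve[0][1], curve[1][1]
        assert abs(acc_small - acc_full) <= 0.02
        # non-decreasing beyond the signal size, within fold noise
        assert acc_full >= acc_small - (curve[0][2] + curve[1][2])

    @pytest.mark.parametrize("sizes", [[0, 5], [5, 3], [5, 5000]])
    def test_invalid_sizes_rejected(self, sizes):
        matrix, y = _signal_plus_noise(n=40, informative=4, noise=6)
        with pytest.raises(ValueError):
            rfe_curve(matrix, y, sizes, cv_folds=4)


# ---------------------------------------------------------------------------
# importances
# ---------------------------------------------------------------------------

class TestPermutationImportance:
    def test_constant_column_has_zero_importance(self):
        rng = np.random.default_rng(7)
        y = np.array(["A", "B"] * 40)
        signal = np.where(y == "A", 1, 0) ^ (rng.random(80) < 0.05)
        values = np.column_stack([signal, np.ones(80)])
        matrix = toy_matrix(values, gvog_names=["Vsig", "Vconst"])
        model = _fit_forest(matrix, y)
        ranking = permutation_importance_ranking(model, matrix, y, seed=0)
        assert ranking.importances["Vconst"][0] == 0.0

    def test_single_informative_feature_ranks_first(self):
        rng = np.random.default_rng(8)
        y = np.array(["A", "B"] * 50)
        signal = np.where(y == "A", 1, 0) ^ (rng.random(100) < 0.05)
        noise = rng.integers(0, 2, size=(100, 8))
        matrix = toy_matrix(np.column_stack([signal, noise]))
        names = matrix.feature_names
        model = _fit_forest(matrix, y)
        ranking = permutation_importance_ranking(model, matrix, y, seed=0)
        assert ranking.ranked()[0] == names[1]  # the signal column

    def test_label_independent_feature_converges_to_zero(self):
        rng = np.random.default_rng(9)
        y = np.array(["A", "B"] * 60)
        signal = np.where(y == "A", 1, 0) ^ (rng.random(120) < 0.05)
        noise = rng.integers(0, 2, size=120)
        matrix = toy_matrix(np.column_stack([signal, noise]), gvog_names=["Vsig", "Vnoise"])
        model = _fit_forest(matrix, y)
        ranking = permutation_importance_ranking(model, matrix, y, n_repeats=50, seed=0)
        assert abs(ranking.importances["Vnoise"][0]) < 0.02

    def test_duplicated_feature_masks_importance_until_clustered(self):
        # The stated motivation for collinearity clustering: permuting one of
        # two perfect copies barely moves accuracy; retraining on cluster
        # representatives restores the feature's visible importance.
        rng = np.random.default_rng(10)
        y = np.array(["A", "B"] * 100)
        signal = (np.where(y == "A", 1, 0) ^ (rng.random(200) < 0.05)).astype(float)
        noise = rng.integers(0, 2, size=(200, 3)).astype(float)
        dup = np.column_stack([signal, signal.copy(), noise])
        matrix = toy_matrix(dup, gvog_names=["Vsig1", "Vsig2", "Vn1", "Vn2", "Vn3"])
        forest_kw = dict(n_estimators=200, max_features=1, random_state=0, n_jobs=1)
        model = RandomForestClassifier(**forest_kw).fit(matrix.to_frame(), y)
        masked = permutation_importance_ranking(model, matrix, y, seed=0)

        clusters = spearman_cluster(matrix, distance_threshold=0.5)
        reps = clusters.representatives
        assert sum(r in ("Vsig1", "Vsig2") for r in reps) == 1
        reduced = matrix.subset_features(reps)
        model2 = RandomForestClassifier(**forest_kw).fit(reduced.to_frame(), y)
        restored = permutation_importance_ranking(model2, reduced, y, seed=0)
        rep_sig = next(r for r in reps if r.startswith("Vsig"))
        full = restored.importances[rep_sig][0]
        assert full > 0.4
        # each duplicated copy shows well under the representative's importance
        assert masked.importances["Vsig1"][0] < 0.6 * full
        assert masked.importances["Vsig2"][0] < 0.6 * full

    def test_feature_mismatch_is_an_error(self):
        rng = np.random.default_rng(11)
        y = np.array(["A", "B"] * 20)
        matrix = toy_matrix(rng.integers(0, 2, size=(40, 3)))
        model = _fit_forest(matrix, y)
        other = toy_matrix(rng.integers(0, 2, size=(40, 3)), gvog_names=["X", "Y", "Z"])
        with pytest.raises(ValueError, match="mismatch"):
            permutation_importance_ranking(model, other, y)


class TestImpurityImportance:
    def _fitted(self, seed=12):
        rng = np.random.default_rng(seed)
        y = np.array(["A", "B"] * 50)
        signal = np.where(y == "A", 1, 0)  # perfectly separating
        noise = rng.integers(0, 2, size=(100, 9))
        matrix = toy_matrix(np.column_stack([signal, noise]))
        return matrix, y, _fit_forest(matrix, y)

    def test_importances_sum_to_one(self):
        matrix, y, model = self._fitted()
        ranking = impurity_importance(model, matrix.feature_names)
        total = sum(m for m, _ in ranking.importances.values())
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_perfect_separator_dominates(self):
        matrix, y, model = self._fitted()
        ranking = impurity_importance(model, matrix.feature_names)
        assert ranking.importances[matrix.feature_names[1]][0] > 0.5

    def test_noise_features_near_uniform_share(self):
        rng = np.random.default_rng(13)
        y = np.array(["A", "B"] * 50)
        matrix = toy_matrix(rng.integers(0, 2, size=(100, 19)))
        model = _fit_forest(matrix, y)
        ranking = impurity_importance(model, matrix.feature_names)
        uniform = 1 / len(matrix.feature_names)
        gvog_means = [
            m for f, (m, _) in ranking.importances.items() if f != "gc_content"
        ]
        assert np.mean(gvog_means) < 2 * uniform

    def test_unfitted_model_is_an_error(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            impurity_importance(RandomForestClassifier())


class TestSelectFinalFeatures:
    def test_k_equal_to_all_is_identity_set(self):
        ranking = ImportanceRanking("impurity", {"a": (0.3, 0), "b": (0.2, 0), "c": (0.5, 0)})
        assert set(select_final_features(ranking, 3)) == {"a", "b", "c"}

    def test_lexicographic_tie_break(self):
        ranking = ImportanceRanking("impurity", {"a": (0.3, 0), "b": (0.3, 0), "c": (0.1, 0)})
        assert select_final_features(ranking, 2) == ["a", "b"]

    def test_gc_content_always_included(self):
        ranking = ImportanceRanking(
            "impurity",
            {"gc_content": (0.0, 0), "a": (0.5, 0), "b": (0.4, 0), "c": (0.3, 0)},
        )
        selected = select_final_features(ranking, 2)
        assert selected == ["gc_content", "a"]

    def test_invalid_k(self):
        ranking = ImportanceRanking("impurity", {"a": (0.3, 0)})
        with pytest.raises(ValueError):
            select_final_features(ranking, 0)
        with pytest.raises(ValueError):
            select_final_features(ranking, 2)
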