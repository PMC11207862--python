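import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from rhizotype import (
    HarnessConfig,
    feature_importance,
    roc_auc,
    run_ensemble,
    summarize_ensemble,
    top_n_intersection,
)
from rhizotype.ensemble import FAMILIES, ImportanceRanking


def _separable(n=44, n_a=31, n_feat=6, gap=3.0, seed=0):
    """Bounded noise with a hard margin: every feature separates perfectly."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, n_feat))
    y = np.array(["A"] * n_a + ["B"] * (n - n_a))
    X[y == "B", :] += gap
    return X, y


class TestRocAuc:
    def test_perfect_ordering(self):
        auc, points = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert points[0].tolist() == [0.0, 0.0]
        assert points[-1].tolist() == [1.0, 1.0]

    def test_half_concordant(self):
        auc, _ = roc_auc([0.9, 0.1, 0.8, 0.2], [1, 1, 0, 0])
        assert auc == 0.5

    def test_all_ties(self):
        auc, _ = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == 0.5

    def test_matches_sklearn_on_random_scores(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=40)
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max():
                continue
            ours, _ = roc_auc(scores, labels)
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestHarness:
    def test_separable_data_is_perfect_for_every_family(self):
        X, y = _separable()
        cfg = HarnessConfig.fast(master_seed=0, n_iterations=5)
        res = run_ensemble(X, y, cfg)
        for fam in FAMILIES:
            assert res.families[fam].auc == 1.0
            assert res.families[fam].accuracy == 1.0

    def test_pooled_confusion_totals(self):
        X, y = _separable()
        cfg = HarnessConfig.fast(master_seed=1, n_iterations=4)
        res = run_ensemble(X, y, cfg)
        for fam in FAMILIES:
            assert res.families[fam].confusion.sum() == 4 * res.test_size
        assert res.test_size == 9  # 20% of 44

    def test_determinism(self):
        X, y = _separable(seed=2)
        cfg = HarnessConfig.fast(master_seed=5, n_iterations=2)
        r1 = run_ensemble(X, y, cfg)
        r2 = run_ensemble(X, y, cfg)
        for fam in FAMILIES:
            np.testing.assert_array_equal(
                r1.families[fam].pooled_scores, r2.families[fam].pooled_scores
            )
            np.testing.assert_array_equal(
                r1.families[fam].confusion, r2.families[fam].confusion
            )

    def test_accuracy_consistent_with_confusion(self):
        X, y = _separable(gap=0.0, seed=3)
        cfg = HarnessConfig.fast(master_seed=0, n_iterations=3)
        res = run_ensemble(X, y, cfg)
        for fam in FAMILIES:
            conf = res.families[fam].confusion
            assert res.families[fam].accuracy == pytest.approx(
                np.trace(conf) / conf.sum()
            )

    def test_small_class_rejected(self):
        X, y = _separable(n=10, n_a=7)
        with pytest.raises(ValueError):
            run_ensemble(X, y, HarnessConfig.fast(n_iterations=1))


class TestImportance:
    def test_informative_feature_ranks_first_in_both_families(self):
        rng = np.random.default_rng(0)
        n = 60
        y = np.array(["A"] * 30 + ["B"] * 30)
        informative = np.where(y == "B", 1.0, -1.0) + rng.normal(0, 0.3, n)
        X = np.column_stack([informative, rng.normal(size=(n, 20))])
        names = [f"f{j}" for j in range(21)]
        for family in ("rf", "xgb"):
            rank = feature_importance(X, y, family, seed=0, feature_names=names)
            assert rank.ranking[0] == "f0"

    def test_constant_feature_zero_importance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        X[:, 2] = 7.0
        y = np.array([0] * 20 + [1] * 20)
        X[y == 1, 0] += 3
        for family in ("rf", "xgb"):
            rank = feature_importance(X, y, family, seed=0)
            assert rank.scores["x2"] == 0.0

    def test_ranking_is_permutation_with_nonnegative_scores(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 7))
        y = np.array([0] * 15 + [1] * 15)
        rank = feature_importance(X, y, "rf", seed=3)
        assert sorted(rank.ranking) == sorted(rank.scores)
        assert all(v >= 0 for v in rank.scores.values())


class TestIntersection:
    def _ranking(self, names):
        return ImportanceRanking("rf", {n: 1.0 for n in names}, list(names))

    def test_identical_rankings(self):
        names = [f"f{i}" for i in range(40)]
        a, b = self._ranking(names), self._ranking(names)
        assert len(top_n_intersection(a, b, 30)) == 30

    def test_disjoint_prefixes_empty(self):
        names = [f"f{i}" for i in range(20)]
        a = self._ranking(names)
        b = self._ranking(names[10:] + names[:10])
        assert top_n_intersection(a, b, 10) == []

    def test_sorted_by_rank_sum(self):
        names = ["a", "b", "c", "d"]
        a = self._ranking(["a", "b", "c", "d"])
        b = self._ranking(["b", "a", "c", "d"])
        out = top_n_intersection(a, b, 3)
        assert out == ["a", "b", "c"] or out == ["b", "a", "c"]
        # rank sums: a=1, b=1, c=4 -> c last
        assert out[-1] == "c"

    def test_oversized_n_rejected(self):
        a = self._ranking(["x", "y"])
        with pytest.raises(ValueError):
            top_n_intersection(a, a, 3)


class TestSummarize:
    def test_single_family(self):
        out = summarize_ensemble([0.875], [0.9])
        assert out["mean_auc"] == 0.88
        assert out["mean_accuracy_pct"] == 90.0
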