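import numpy as np
import pytest

from rhizotype import OPLSDA, fit_oplsda, permutation_test, screen_key_taxa, splot


def _construction_data(n=40, n_noise=10, noise_sd=0.05, seed=0):
    """One informative variable equal to the class code plus tiny noise."""
    rng = np.random.default_rng(seed)
    y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    coded = np.where(y == "B", 1.0, -1.0)
    informative = coded + rng.normal(0, noise_sd, n)
    noise = rng.normal(size=(n, n_noise))
    X = np.column_stack([informative, noise])
    return X, y


class TestFit:
    def test_construction_oracle(self):
        X, y = _construction_data()
        model = OPLSDA(n_ortho="auto").fit(X, y)
        assert model.r2y_ > 0.95
        assert np.nanargmax(model.vip_) == 0

    def test_single_perfect_variable_vip_one(self):
        X, y = _construction_data(n_noise=0)
        model = OPLSDA(n_ortho=0).fit(X, y)
        np.testing.assert_allclose(model.vip_, [1.0], atol=1e-12)

    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 40))
        y = np.array([0] * 15 + [1] * 15)
        model = OPLSDA(n_ortho=1).fit(X, y)
        assert np.nanmean(model.vip_**2) == pytest.approx(1.0, abs=1e-8)

    def test_predictive_score_orthogonal_to_ortho_scores(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 20))
        X[:, 0] += np.r_[np.zeros(15), np.ones(15)] * 2
        y = np.array([0] * 15 + [1] * 15)
        model = OPLSDA(n_ortho=2).fit(X, y)
        for t_o in model.ortho_scores_:
            assert abs(np.corrcoef(model.scores_, t_o)[0, 1]) < 1e-8

    def test_r2y_at_least_q2(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            X = rng.normal(size=(24, 15))
            y = np.array([0] * 12 + [1] * 12)
            X[:, 0] += y * rng.uniform(0, 3)
            model = OPLSDA(n_ortho="auto").fit(X, y)
            assert model.r2y_ >= model.q2_ - 1e-12

    def test_null_q2_is_low(self):
        X, y = _construction_data(seed=7)
        rng = np.random.default_rng(7)
        q2s = []
        for _ in range(20):
            q2s.append(OPLSDA(n_ortho=0).fit(X, rng.permutation(y)).q2_)
        assert np.mean(q2s) < 0.0
        assert max(q2s) < 0.2

    def test_zero_variance_dropped_with_warning(self):
        X, y = _construction_data()
        X[:, 3] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_oplsda(X, y, n_ortho=0)
        assert np.isnan(model.vip_[3])
        assert np.nanmean(model.vip_**2) == pytest.approx(1.0, abs=1e-8)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            OPLSDA().fit(X, np.zeros(10))

    def test_predict_and_transform(self):
        X, y = _construction_data()
        model = OPLSDA(n_ortho=0).fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0
        assert model.transform(X).shape == (X.shape[0],)

    def test_auto_degrades_to_plain_plsda(self):
        # a single predictive variable leaves no orthogonal variation to strip
        X, y = _construction_data(n_noise=0, seed=11)
        model = OPLSDA(n_ortho="auto").fit(X, y)
        assert model.n_ortho_ == 0


class TestPermutationTest:
    def test_separable_data_attains_minimum_p(self):
        X, y = _construction_data()
        res = permutation_test(X, y, n_ortho=0, n_perm=200, seed=0)
        assert res.p_q2 == pytest.approx(1 / 201)
        assert res.p_q2 < 0.005
        assert res.p_r2y == pytest.approx(1 / 201)
        assert res.permuted_q2.shape == (200,)

    def test_add_one_formula_at_20_permutations(self):
        X, y = _construction_data()
        with pytest.warns(UserWarning):
            res = permutation_test(X, y, n_ortho=0, n_perm=19, seed=0)
        X, y = _construction_data()
        res = permutation_test(X, y, n_ortho=0, n_perm=20, seed=0)
        assert res.p_q2 == pytest.approx(1 / 21)


class TestSPlot:
    def test_informative_variable_reliable(self):
        X, y = _construction_data()
        model = OPLSDA(n_ortho=0).fit(X, y)
        rows = splot(model, X, feature_names=[f"v{j}" for j in range(X.shape[1])])
        by_name = {r.feature: r for r in rows}
        assert abs(by_name["v0"].pcorr1) > 0.9

    def test_noise_variable_unreliable(self):
        X, y = _construction_data(n=200, seed=2)
        model = OPLSDA(n_ortho=0).fit(X, y)
        rows = splot(model, X)
        noise_rows = [r for r in rows if r.feature != "x0"]
        # sampling bound: the vast majority of pure-noise variables show
        # negligible reliability against the predictive score
        assert np.mean([abs(r.pcorr1) < 0.3 for r in noise_rows]) >= 0.9
        assert np.median([abs(r.pcorr1) for r in noise_rows]) < 0.25

    def test_pcorr_bounded_and_sign_consistent(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(25, 12))
        y = np.array([0] * 13 + [1] * 12)
        model = OPLSDA(n_ortho=0).fit(X, y)
        for r in splot(model, X):
            assert abs(r.pcorr1) <= 1 + 1e-12
            if abs(r.p1) > 1e-12:
                assert np.sign(r.p1) == np.sign(r.pcorr1)

    def test_zero_variance_flagged(self):
        X, y = _construction_data()
        X[:, 5] = 2.0
        with pytest.warns(UserWarning):
            model = fit_oplsda(X, y, n_ortho=0)
        rows = splot(model, X)
        flagged = [r for r in rows if r.excluded]
        assert len(flagged) == 1


class TestScreen:
    def test_threshold_screen(self):
        X, y = _construction_data()
        model = OPLSDA(n_ortho=0).fit(X, y)
        model.vip_ = np.array([2.0, 0.5, 0.1])
        model.retained_ = np.ones(3, dtype=bool)
        assert screen_key_taxa(model, ["a", "b", "c"]) == ["a"]
        assert screen_key_taxa(model, ["a", "b", "c"], threshold=0.0) == ["a", "b", "c"]

    def test_recovers_planted_taxa(self, default_features):
        features, groups, truth = default_features
        model = OPLSDA(n_ortho="auto").fit(features.to_numpy(), groups.to_numpy())
        key = set(screen_key_taxa(model, features.columns))
        planted = set(truth.characteristic_taxa)
        assert len(planted & key) >= 20
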