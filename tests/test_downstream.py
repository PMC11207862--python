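import numpy as np
import pandas as pd
import pytest

from rhizotype import PLSPathModel, correlation_network, pls_sem, rda


class TestRda:
    def test_self_explanation_is_total(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(30, 4))
        res = rda(Y, Y)
        assert res.proportion_constrained == pytest.approx(1.0, abs=1e-8)

    def test_independent_constraints_explain_little(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(500, 5))
        X = rng.normal(size=(500, 3))
        res = rda(Y, X)
        assert res.proportion_constrained < 0.05

    def test_axis_count_bounded_by_rank(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(25, 6))
        X = rng.normal(size=(25, 2))
        res = rda(Y, X)
        assert res.constrained_eigenvalues.size <= 2
        assert np.all(np.diff(res.constrained_eigenvalues) <= 1e-12)
        assert np.all(res.constrained_eigenvalues >= 0)

    def test_rotation_invariance_of_proportion(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(40, 5))
        X = rng.normal(size=(40, 3))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        p1 = rda(Y, X).proportion_constrained
        p2 = rda(Y, X @ Q).proportion_constrained
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_collinear_constraints_handled(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(20, 3))
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x])
        res = rda(Y, X)
        assert res.constrained_eigenvalues.size <= 1 + 1e-9


class TestCorrelationNetwork:
    def test_perfect_edge(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        df = pd.DataFrame({"x": x, "y": x, "z": rng.normal(size=20)})
        net = correlation_network(df, r_min=0.9, p_max=0.05)
        edges = {(e.node_a, e.node_b): e for e in net.edges}
        assert ("x", "y") in edges
        assert edges[("x", "y")].r == pytest.approx(1.0)
        assert edges[("x", "y")].sign == 1

    def test_negative_edge_sign(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "y": -x + rng.normal(0, 1e-6, 30)})
        net = correlation_network(df, r_min=0.9)
        assert net.edges[0].sign == -1
        assert net.edges[0].r < -0.999

    def test_null_data_yields_no_edges(self):
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(200, 10)))
            df.columns = [f"v{j}" for j in range(10)]
            total += len(correlation_network(df, r_min=0.5).edges)
        assert total <= 1

    def test_r_matches_direct_oracle(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        df["b"] = df["a"] * 0.7 + rng.normal(0, 0.3, 25)
        net = correlation_network(df, r_min=0.0, p_max=1.0)
        for e in net.edges:
            direct = np.corrcoef(df[e.node_a], df[e.node_b])[0, 1]
            assert e.r == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_variable_excluded(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(size=10), "flat": np.ones(10),
                           "b": rng.normal(size=10)})
        net = correlation_network(df, r_min=0.0, p_max=1.0)
        assert "flat" not in net.nodes


class TestPlsPathModel:
    def test_noise_free_chain_has_unit_paths(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=50)
        data = pd.DataFrame({"i1": z, "i2": z.copy(), "i3": z.copy()})
        res = pls_sem(
            data,
            blocks={"L1": ["i1"], "L2": ["i2"], "L3": ["i3"]},
            inner_paths={"L2": ["L1"], "L3": ["L2"]},
            n_boot=100,
            seed=0,
        )
        assert res.path_coefficients[("L1", "L2")] == pytest.approx(1.0, abs=1e-6)
        assert res.path_coefficients[("L2", "L3")] == pytest.approx(1.0, abs=1e-6)

    def test_single_indicator_latent_is_standardized_indicator(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({
            "a": rng.normal(size=40),
        })
        data["b"] = 0.6 * data["a"] + rng.normal(0, 0.5, 40)
        res = pls_sem(data, {"LA": ["a"], "LB": ["b"]}, {"LB": ["LA"]},
                      n_boot=100, seed=1)
        za = (data["a"] - data["a"].mean()) / data["a"].std(ddof=0)
        np.testing.assert_allclose(res.latent_scores["LA"], za, atol=1e-10)
        # path equals the standardized OLS slope between indicators
        beta = np.corrcoef(data["a"], data["b"])[0, 1]
        assert res.path_coefficients[("LA", "LB")] == pytest.approx(beta, abs=1e-10)

    def test_latent_scores_standardized(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(size=(30, 6)),
                            columns=[f"x{j}" for j in range(6)])
        data["x1"] += data["x0"]
        res = pls_sem(
            data,
            {"L1": ["x0", "x1"], "L2": ["x2", "x3"], "L3": ["x4", "x5"]},
            {"L2": ["L1"], "L3": ["L2"]},
            n_boot=100,
            seed=2,
        )
        for lv in res.latent_scores:
            assert res.latent_scores[lv].mean() == pytest.approx(0.0, abs=1e-10)
            assert res.latent_scores[lv].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_cyclic_paths_rejected(self):
        data = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0) ** 2})
        with pytest.raises(ValueError, match="cyclic"):
            PLSPathModel(
                blocks={"L1": ["a"], "L2": ["b"]},
                inner_paths={"L1": ["L2"], "L2": ["L1"]},
            ).fit(data)

    def test_null_path_p_values_calibrated(self):
        rejections = 0
        n_sim = 100
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame({"a": rng.normal(size=40),
                                 "b": rng.normal(size=40)})
            res = pls_sem(data, {"LA": ["a"], "LB": ["b"]}, {"LB": ["LA"]},
                          n_boot=200, seed=seed)
            if res.p_values[("LA", "LB")] <= 0.05:
                rejections += 1
        assert rejections / n_sim <= 0.08
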