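"""Nodewise lasso estimation, EBIC selection, aggregation, predictability."""

import numpy as np
import pytest

from exponet.mgm import (ConvergenceError, DatasetError, EstimationConfig,
                         MixedDataset, aggregate_edges, ebic, estimate_network,
                         lambda_grid, nodewise_fit, predictability,
                         select_lambda)
from exponet.synthetic import TrueGraph, sample_mgm


def _continuous_dataset(X: np.ndarray, names=None) -> MixedDataset:
    names = names or [f"v{j}" for j in range(X.shape[1])]
    return MixedDataset(names, ["continuous"] * X.shape[1], X)


def _orthonormal_design(n: int, p: int, seed: int) -> np.ndarray:
    """Columns with exact zero mean, unit variance and zero cross-correlation."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, p + 1))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    Q = Q[:, :p]
    Q -= Q.mean(axis=0)
    return Q / Q.std(axis=0)


class TestDataset:
    def test_binary_column_validation(self):
        with pytest.raises(DatasetError, match="0/1"):
            MixedDataset(["a", "b"], ["binary", "binary"],
                         np.array([[0, 2.0], [1, 0]]))

    def test_missing_values_rejected(self):
        with pytest.raises(DatasetError, match="missing"):
            MixedDataset(["a", "b"], ["continuous", "continuous"],
                         np.array([[0, np.nan], [1, 0]]))

    def test_unknown_node_lookup(self):
        ds = _continuous_dataset(np.random.default_rng(0).normal(size=(50, 3)))
        with pytest.raises(DatasetError, match="nope"):
            ds.index_of("nope")


class TestNodewiseLasso:
    def test_soft_threshold_closed_form_on_orthonormal_design(self):
        # with X'X/n = I the lasso solution is sign(r)(|r| - lambda)+ where
        # r is the marginal covariance of each predictor with y
        n, lam = 2000, 0.08
        Q = _orthonormal_design(n, 3, seed=1)
        beta_true = np.array([0.5, -0.15, 0.02])
        rng = np.random.default_rng(2)
        y = Q @ beta_true + rng.normal(0, 0.3, n)
        X = np.column_stack([y, Q])
        ds = _continuous_dataset(X, ["y", "x1", "x2", "x3"])
        y_std = (y - y.mean()) / y.std()
        r = Q.T @ y_std / n
        expected = np.sign(r) * np.maximum(np.abs(r) - lam, 0)
        fit = nodewise_fit(ds, "y", lam)
        np.testing.assert_allclose(
            fit.coef[["x1", "x2", "x3"]].to_numpy(), expected, atol=1e-6)

    def test_lambda_zero_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(500, 4))
        ds = _continuous_dataset(X)
        fit = nodewise_fit(ds, "v0", 0.0)
        # independent oracle: ordinary least squares via the normal equations
        Xs = (X - X.mean(0)) / X.std(0)
        A = np.column_stack([np.ones(500), Xs[:, 1:]])
        beta = np.linalg.solve(A.T @ A, A.T @ Xs[:, 0])
        np.testing.assert_allclose(fit.coef.to_numpy(), beta[1:], atol=1e-5)

    def test_full_shrinkage_above_lambda_max(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(300, 5))
        X[:, 0] = 0.6 * X[:, 1] + 0.4 * rng.normal(size=300)
        ds = _continuous_dataset(X)
        lam_max = lambda_grid(ds, "v0")[0]
        fit = nodewise_fit(ds, "v0", lam_max * 1.0001)
        assert fit.df == 0

    def test_binary_node_l1_shrinkage(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(800, 2))
        prob = 1 / (1 + np.exp(-(1.0 * x[:, 0])))
        y = (rng.random(800) < prob).astype(float)
        ds = MixedDataset(["y", "x1", "x2"],
                          ["binary", "continuous", "continuous"],
                          np.column_stack([y, x]))
        small = nodewise_fit(ds, "y", 0.01)
        assert small.coef["x1"] > 0.5
        big = nodewise_fit(ds, "y", 1.0)
        assert big.df == 0

    def test_negative_lambda_rejected(self):
        ds = _continuous_dataset(np.random.default_rng(0).normal(size=(50, 2)))
        with pytest.raises(ValueError, match="lambda"):
            nodewise_fit(ds, "v0", -0.1)


class TestEBICSelection:
    def test_gamma_zero_reduces_to_bic(self):
        ll, df, n = -120.0, 3, 500
        assert ebic(ll, df, n, 10, 0.0) == pytest.approx(
            -2 * ll + df * np.log(n))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pure_noise_selects_empty_model(self, seed):
        rng = np.random.default_rng(seed)
        ds = _continuous_dataset(rng.normal(size=(500, 6)))
        lam = select_lambda(ds, "v0", gamma=0.25)
        assert nodewise_fit(ds, "v0", lam).df == 0

    def test_selected_lambda_minimizes_ebic_over_grid(self):
        # exhaustive grid evaluation as the oracle
        rng = np.random.default_rng(7)
        X = rng.normal(size=(400, 4))
        X[:, 0] = 0.5 * X[:, 1] + rng.normal(0, 1, 400)
        ds = _continuous_dataset(X)
        grid = lambda_grid(ds, "v0", n_lambda=25)
        chosen = select_lambda(ds, "v0", gamma=0.25, lambda_grid_values=grid)
        scores = {lam: ebic(f.loglik, f.df, f.n, 3, 0.25)
                  for lam in grid
                  for f in [nodewise_fit(ds, "v0", float(lam))]}
        assert scores[chosen] == pytest.approx(min(scores.values()), abs=1e-6)

    def test_strong_predictor_is_selected(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(500, 3))
        x[:, 0] = 0.5 * x[:, 1] + np.sqrt(1 - 0.25) * rng.normal(size=500)
        ds = _continuous_dataset(x)
        lam = select_lambda(ds, "v0", gamma=0.25)
        assert nodewise_fit(ds, "v0", lam).coef["v1"] != 0

    def test_empty_grid_rejected(self):
        ds = _continuous_dataset(np.random.default_rng(0).normal(size=(50, 2)))
        with pytest.raises(ValueError, match="grid"):
            select_lambda(ds, "v0", lambda_grid_values=np.array([]))


class TestAggregation:
    def test_mean_of_absolutes_and_sign(self):
        coefs = {"a": {"b": 0.2}, "b": {"a": 0.3}}
        net = aggregate_edges(coefs, rule="AND")
        assert net.weights[0, 1] == pytest.approx(0.25)
        assert net.signs[0, 1] == 1

    def test_and_rule_zeroes_one_sided_edges(self):
        coefs = {"a": {"b": 0.0}, "b": {"a": 0.3}}
        assert aggregate_edges(coefs, rule="AND").weights[0, 1] == 0
        assert aggregate_edges(coefs, rule="OR").weights[0, 1] == pytest.approx(0.15)

    def test_sign_conflict_is_undefined(self):
        coefs = {"a": {"b": -0.2}, "b": {"a": 0.3}}
        net = aggregate_edges(coefs, rule="AND")
        assert net.weights[0, 1] == pytest.approx(0.25)
        assert np.isnan(net.signs[0, 1])

    def test_all_zero_coefficients_give_empty_network(self):
        coefs = {k: {j: 0.0 for j in "abc" if j != k} for k in "abc"}
        net = aggregate_edges(coefs)
        assert np.count_nonzero(net.weights) == 0
        assert net.edge_list().empty

    def test_and_edges_subset_of_or_edges(self):
        rng = np.random.default_rng(9)
        names = list("abcde")
        coefs = {k: {j: float(rng.choice([0, rng.normal()]))
                     for j in names if j != k} for k in names}
        and_net = aggregate_edges(coefs, rule="AND")
        or_net = aggregate_edges(coefs, rule="OR")
        assert np.all((and_net.weights != 0) <= (or_net.weights != 0))

    def test_missing_fit_rejected(self):
        with pytest.raises(ValueError, match="lacks"):
            aggregate_edges({"a": {}, "b": {"a": 0.1}})


class TestPredictability:
    def test_no_neighbours_scores_zero_and_copy_scores_one(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=1000)
        z = rng.normal(size=1000)
        ds = _continuous_dataset(np.column_stack([x, x.copy(), z]),
                                 ["x", "x_copy", "z"])
        fits = {name: nodewise_fit(ds, name, 0.05) for name in ds.names}
        pred = predictability(ds, fits)
        assert pred["x"] == pytest.approx(1.0, abs=1e-9)
        assert pred["z"] == 0.0

    def test_half_signal_half_noise_gives_half(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=10_000)
        y = x + rng.normal(size=10_000)  # equal signal and noise variance
        z = rng.normal(size=10_000)
        ds = _continuous_dataset(np.column_stack([y, x, z]), ["y", "x", "z"])
        net = estimate_network(ds)
        assert net.predictability["y"] == pytest.approx(0.5, abs=0.02)

    def test_binary_predictability_is_normalized_accuracy(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=3000)
        y = (x + 0.3 * rng.normal(size=3000) > 0).astype(float)
        ds = MixedDataset(["y", "x"], ["binary", "continuous"],
                          np.column_stack([y, x]))
        net = estimate_network(ds)
        assert 0.5 < net.predictability["y"] <= 1.0


class TestFullEstimation:
    def test_scale_equivariance_of_standardized_network(self):
        g = TrueGraph([("x", "continuous"), ("y", "continuous"),
                       ("z", "continuous")],
                      np.array([[0, 0.4, 0], [0.4, 0, 0.3], [0, 0.3, 0]]))
        ds = sample_mgm(g, 1500, burn_in=100, thin=5, seed=13)
        scaled = ds.values.copy()
        scaled[:, 1] *= 7.3
        ds2 = MixedDataset(list(ds.names), list(ds.kinds), scaled)
        n1 = estimate_network(ds)
        n2 = estimate_network(ds2)
        np.testing.assert_allclose(n1.weights, n2.weights, atol=1e-8)

    def test_single_seed_recovery_sanity(self):
        from exponet.synthetic import make_recovery_graph

        g = make_recovery_graph()
        ds = sample_mgm(g, 2000, burn_in=200, thin=5, seed=14)
        net = estimate_network(ds)
        true = {frozenset((a, b)) for a, b, _ in g.edges()}
        est = {frozenset((net.node_names[i], net.node_names[j]))
               for i in range(11) for j in range(i + 1, 11)
               if net.weights[i, j] != 0}
        assert len(est & true) >= 8
        assert len(est - true) <= 4

    def test_null_calibration_mean_edge_count(self):
        # fully independent mixed data: EBIC keeps the network nearly empty
        counts = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = np.column_stack([
                rng.normal(size=(1100, 6)),
                (rng.random((1100, 5)) < 0.5).astype(float),
            ])
            ds = MixedDataset([f"v{i}" for i in range(11)],
                              ["continuous"] * 6 + ["binary"] * 5, X)
            net = estimate_network(ds)
            counts.append(np.count_nonzero(net.weights[np.triu_indices(11, 1)]))
        assert np.mean(counts) <= 2.0

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(15)
        ds = _continuous_dataset(rng.normal(size=(300, 4)))
        net = estimate_network(ds)
        np.testing.assert_allclose(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)
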