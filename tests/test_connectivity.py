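import numpy as np
import pytest
from scipy import optimize

from vnsnet import connectivity, synthetic
from vnsnet.montage import edge_pairs
from vnsnet.preprocessing import EpochMatrix


def _epoch(rng, n=60, p=19):
    return rng.standard_normal((n, p))


class TestKernelWeights:
    @pytest.mark.parametrize("t", [1, 7, 30, 60])
    @pytest.mark.parametrize("h", [0.5, 3.91, 25.0])
    def test_weights_normalized(self, t, h):
        kw = connectivity.kernel_weights(t, 60, h)
        assert kw.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (kw.weights >= 0).all()

    def test_interior_center_is_symmetric(self):
        kw = connectivity.kernel_weights(30, 60, 3.0)
        for k in range(1, 29):
            assert kw.weights[29 - k] == pytest.approx(kw.weights[29 + k], rel=1e-12)

    def test_infinite_bandwidth_limit_is_uniform(self, rng):
        kw = connectivity.kernel_weights(17, 60, 1e6)
        np.testing.assert_allclose(kw.weights, np.full(60, 1 / 60), atol=1e-9)
        x = _epoch(rng)
        tvc = connectivity.time_varying_covariance(x, h=1e6, centering="none")
        static = x.T @ x / 60
        for t in range(60):
            np.testing.assert_allclose(tvc.matrices[t], static, atol=1e-9)

    def test_invalid_bandwidth_or_center(self):
        with pytest.raises(ValueError):
            connectivity.kernel_weights(5, 60, 0.0)
        with pytest.raises(ValueError):
            connectivity.kernel_weights(0, 60, 1.0)


class TestTimeVaryingCovariance:
    def test_constant_rows_give_rank_one_outer_product(self):
        v = np.arange(1.0, 20.0)
        x = np.tile(v, (60, 1))
        tvc = connectivity.time_varying_covariance(x, centering="none")
        for t in range(60):
            np.testing.assert_allclose(tvc.matrices[t], np.outer(v, v), atol=1e-9)

    def test_epoch_mean_centering_zeroes_constant_data(self):
        x = np.tile(np.arange(1.0, 20.0), (60, 1))
        tvc = connectivity.time_varying_covariance(x, centering="epoch_mean")
        np.testing.assert_allclose(tvc.matrices, 0.0, atol=1e-12)

    @pytest.mark.parametrize("centering", ["none", "epoch_mean", "kernel_mean"])
    def test_matches_brute_force_formula(self, rng, centering):
        """Sigma_t = sum_i w_it x_i x_i^T / sum_i w_it evaluated by explicit
        loops must agree with the vectorized implementation to 1e-12."""
        x = _epoch(rng, p=5)
        h = 3.91
        tvc = connectivity.time_varying_covariance(x, h=h, centering=centering)
        xc = x - x.mean(axis=0) if centering == "epoch_mean" else x
        for t in [1, 13, 60]:
            raw = np.array([np.exp(-0.5 * ((i - t) / h) ** 2) for i in range(1, 61)])
            if centering == "kernel_mean":
                mu = sum(raw[i] * xc[i] for i in range(60)) / raw.sum()
                rows = xc - mu
            else:
                rows = xc
            num = np.zeros((5, 5))
            for i in range(60):
                num += raw[i] * np.outer(rows[i], rows[i])
            np.testing.assert_allclose(tvc.matrices[t - 1], num / raw.sum(), atol=1e-12)

    def test_matrices_are_psd(self, rng):
        tvc = connectivity.time_varying_covariance(_epoch(rng))
        for t in range(60):
            assert np.linalg.eigvalsh(tvc.matrices[t])[0] > -1e-10

    def test_non_finite_input_rejected(self):
        x = np.zeros((60, 19))
        x[3, 4] = np.nan
        with pytest.raises(ValueError):
            connectivity.time_varying_covariance(x)


class TestEpochMeanCovariance:
    def test_identical_matrices_average_to_themselves(self, rng):
        m = np.eye(4) * 2.0
        tvc = connectivity.TimeVaryingCovariance(np.tile(m, (60, 1, 1)), "none")
        np.testing.assert_allclose(connectivity.epoch_mean_covariance(tvc), m)

    def test_matches_brute_force_mean(self, rng):
        tvc = connectivity.time_varying_covariance(_epoch(rng, p=4))
        oracle = sum(tvc.matrices[t] for t in range(60)) / 60
        np.testing.assert_allclose(
            connectivity.epoch_mean_covariance(tvc), oracle, atol=1e-12
        )
        assert np.linalg.eigvalsh(connectivity.epoch_mean_covariance(tvc))[0] > -1e-10


def _nelder_mead_glasso(S, lam):
    """Independent reference: directly minimize the penalized negative
    log-likelihood -logdet(T) + tr(S T) + lam*||T||_1,offdiag over symmetric
    3x3 matrices with a derivative-free simplex search."""
    iu = np.triu_indices(3)

    def unpack(v):
        T = np.zeros((3, 3))
        T[iu] = v
        return T + np.triu(T, 1).T

    def objective(v):
        T = unpack(v)
        vals = np.linalg.eigvalsh(T)
        if vals[0] <= 1e-8:
            return 1e8 - 1e6 * vals[0]
        off = np.abs(T).sum() - np.abs(np.diag(T)).sum()
        return -np.log(np.linalg.det(T)) + np.sum(S * T) + lam * off

    v0 = np.linalg.inv(S)[iu]
    res = optimize.minimize(
        objective, v0, method="Nelder-Mead",
        options={"maxiter": 20000, "xatol": 1e-9, "fatol": 1e-12},
    )
    return unpack(res.x)


class TestGlassoPrecision:
    def test_zero_penalty_returns_matrix_inverse(self, rng):
        x = rng.standard_normal((200, 6))
        S = x.T @ x / 200
        est = connectivity.glasso_precision(S, 0.0)
        np.testing.assert_allclose(est.theta, np.linalg.inv(S), atol=1e-6)
        assert est.converged

    def test_huge_penalty_gives_diagonal_estimate(self, rng):
        x = rng.standard_normal((200, 6))
        S = np.cov(x.T)
        lam = np.abs(S - np.diag(np.diag(S))).max() * 1.5
        est = connectivity.glasso_precision(S, lam)
        off = est.theta - np.diag(np.diag(est.theta))
        np.testing.assert_allclose(off, 0.0, atol=1e-8)

    def test_agrees_with_independent_simplex_solver(self):
        theta_true = np.array([[1.5, -0.4, 0.0], [-0.4, 1.5, -0.4], [0.0, -0.4, 1.5]])
        rng = np.random.default_rng(77)
        x = synthetic.simulate_epoch_series(theta_true, 4000, seed=11)
        S = x.T @ x / len(x)
        est = connectivity.glasso_precision(S, 0.05)
        ref = _nelder_mead_glasso(S, 0.05)
        np.testing.assert_allclose(est.theta, ref, atol=1e-4)

    def test_singular_covariance_at_zero_penalty_errors(self):
        S = np.ones((4, 4))
        with pytest.raises(ValueError, match="lambda"):
            connectivity.glasso_precision(S, 0.0)


class TestPartialCorrelations:
    def test_diagonal_precision_has_no_partial_correlation(self):
        rho = connectivity.partial_correlations(np.diag([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(rho, np.zeros(3))

    def test_two_by_two_closed_form(self):
        rho = connectivity.partial_correlations(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert rho[0] == pytest.approx(0.5)

    def test_matches_regression_residual_definition(self, rng):
        """rho_ij at lam=0 equals the correlation of residuals after
        regressing channels i and j on all remaining channels."""
        prec = np.array(
            [
                [2.0, -0.6, 0.0, -0.3],
                [-0.6, 2.0, -0.5, 0.0],
                [0.0, -0.5, 2.0, -0.4],
                [-0.3, 0.0, -0.4, 2.0],
            ]
        )
        x = synthetic.simulate_epoch_series(prec, 2000, seed=5)
        S = x.T @ x / len(x)
        rho = connectivity.partial_correlations(connectivity.glasso_precision(S, 0.0))
        pairs = edge_pairs(4)
        for k, (i, j) in enumerate(pairs):
            others = [c for c in range(4) if c not in (i, j)]
            Z = x[:, others]
            beta_i = np.linalg.lstsq(Z, x[:, i], rcond=None)[0]
            beta_j = np.linalg.lstsq(Z, x[:, j], rcond=None)[0]
            ri = x[:, i] - Z @ beta_i
            rj = x[:, j] - Z @ beta_j
            # uncentered correlation: the second-moment matrix is uncentered
            oracle = ri @ rj / np.sqrt((ri @ ri) * (rj @ rj))
            assert rho[k] == pytest.approx(oracle, abs=1e-6)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            connectivity.partial_correlations(np.array([[1.0, 0.0], [0.0, -1.0]]))


class TestPipelineProperties:
    def test_feature_table_shape_and_columns(self, rng):
        epochs = [
            EpochMatrix(_epoch(rng), f"P{k % 2}", "responder") for k in range(4)
        ]
        table = connectivity.connectivity_pipeline(epochs, lam=0.05)
        assert table.shape == (4, 3 + 171)
        assert "C3-C4" in table.columns
        assert list(table["patient_id"]) == ["P0", "P1", "P0", "P1"]

    def test_two_channel_toy_gives_single_edge(self, rng):
        epochs = [EpochMatrix(_epoch(rng, p=2), "P0", "responder")]
        table = connectivity.connectivity_pipeline(epochs, lam=0.0)
        assert connectivity.feature_matrix(table).shape == (1, 1)

    def test_channel_permutation_equivariance(self, rng):
        """Relabeling channels permutes the rho vector consistently."""
        x = _epoch(rng, p=6)
        perm = rng.permutation(6)
        rho = connectivity.epoch_features(x, lam=0.0)
        rho_p = connectivity.epoch_features(x[:, perm], lam=0.0)
        pairs = edge_pairs(6)
        index = {pair: k for k, pair in enumerate(pairs)}
        # column a of the permuted data is original channel perm[a]
        for k, (a, b) in enumerate(pairs):
            oi, oj = sorted((perm[a], perm[b]))
            assert rho_p[k] == pytest.approx(rho[index[(oi, oj)]], abs=1e-8)

    def test_channel_scaling_invariance_at_zero_penalty(self, rng):
        x = _epoch(rng, p=5)
        scaled = x.copy()
        scaled[:, 2] *= 7.5
        rho = connectivity.epoch_features(x, lam=0.0)
        rho_s = connectivity.epoch_features(scaled, lam=0.0)
        np.testing.assert_allclose(rho, rho_s, atol=1e-6)

    def test_estimator_consistency_toward_ground_truth(self, default_network):
        """Mean estimated rho over repeated epochs approaches the
        generating network's partial correlations."""
        _, prec, _ = default_network
        truth = synthetic.ground_truth_partial_correlations(prec)
        iu = np.triu_indices(19, 1)
        estimates = [
            connectivity.epoch_features(
                synthetic.simulate_epoch_series(prec, 60, seed=k), lam=0.01
            )
            for k in range(300)
        ]
        err = np.abs(np.mean(estimates, axis=0) - truth[iu]).max()
        assert err < 0.15


class TestEbicPenaltySelection:
    def test_large_sample_sparse_truth_prefers_moderate_penalty(self):
        theta_true = np.array([[1.5, -0.4, 0.0], [-0.4, 1.5, -0.4], [0.0, -0.4, 1.5]])
        x = synthetic.simulate_epoch_series(theta_true, 3000, seed=21)
        S = x.T @ x / len(x)
        lam = connectivity.select_lambda_ebic(S, len(x))
        # criterion must keep the true edges: estimate at the chosen
        # penalty recovers the chain support
        theta = connectivity.glasso_precision(S, lam).theta
        assert abs(theta[0, 1]) > 1e-6 and abs(theta[1, 2]) > 1e-6
        assert lam <= 0.1  # at n=3000 heavy shrinkage would be penalized

    def test_returns_value_from_grid(self, rng):
        x = rng.standard_normal((200, 5))
        S = np.cov(x.T)
        grid = [0.05, 0.2, 0.8]
        assert connectivity.select_lambda_ebic(S, 200, grid=grid) in grid
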