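"""Estimator contracts: closed forms, composition oracles, null bounds."""

import numpy as np
import pytest

from ddcov import (
    LinearSimConfig,
    ResponseFunction,
    SpikeTrains,
    TimeSeries,
    cov_estimator,
    cspk,
    ddc_leaky_from_arrays,
    ddc_linear,
    ddc_linear_from_arrays,
    ddc_nonlinear,
    delta_c,
    delta_p,
    get_estimator,
    interior,
    numerical_derivative,
    precision_estimator,
    read_estimate,
    regularized_precision,
    relu_threshold_scan,
    simulate_linear,
    time_average_outer,
    write_estimate,
    zscore,
)


class TestCovariance:
    def test_independent_nodes_near_zero(self, rng):
        T = 50000
        ts = TimeSeries(values=rng.standard_normal((2, T)), dt=0.01)
        C = cov_estimator(ts).matrix
        assert abs(C[0, 1]) < 3.0 / np.sqrt(T)
        assert np.allclose(np.diag(C), 1.0)

    def test_duplicated_node(self, rng):
        x = rng.standard_normal(1000)
        ts = TimeSeries(values=np.vstack([x, x]), dt=0.01)
        assert cov_estimator(ts).matrix[0, 1] == pytest.approx(1.0)

    def test_confounder_false_positive(self, confounder_series):
        # the two driven-but-unconnected nodes correlate via the common source
        C = cov_estimator(confounder_series).matrix
        assert abs(C[1, 2]) > 0.05
        assert np.allclose(C, C.T)


class TestPrecision:
    def test_identity_cov(self, rng):
        T = 200000
        ts = TimeSeries(values=rng.standard_normal((3, T)), dt=0.01)
        P = precision_estimator(ts).matrix
        assert np.allclose(P, np.eye(3), atol=0.05)

    def test_2x2_closed_form(self, rng):
        rho = 0.6
        L = np.linalg.cholesky(np.array([[1, rho], [rho, 1.0]]))
        X = L @ rng.standard_normal((2, 100000))
        ts = TimeSeries(values=X, dt=0.01)
        C = cov_estimator(ts).matrix
        r = C[0, 1]
        expected = np.array([[1, -r], [-r, 1.0]]) / (1 - r ** 2)
        assert np.allclose(precision_estimator(ts).matrix, expected, atol=1e-8)

    def test_multiply_back(self, stable_w):
        ts = simulate_linear(LinearSimConfig(W=stable_w, duration=50.0, seed=3))
        C = cov_estimator(ts).matrix
        P = precision_estimator(ts).matrix
        assert np.allclose(P @ C, np.eye(5), atol=1e-8)

    def test_singular_recommends_pseudoinverse(self, rng):
        x = rng.standard_normal(500)
        ts = TimeSeries(values=np.vstack([x, x + 1e-14]), dt=0.01)
        with pytest.raises(np.linalg.LinAlgError, match="pseudoinverse"):
            precision_estimator(ts)
        P = precision_estimator(ts, pseudoinverse=True).matrix
        assert np.all(np.isfinite(P))


class TestRegularizedPrecision:
    def test_lambda_zero_reduces_to_precision(self, confounder_series):
        P = precision_estimator(confounder_series).matrix
        for penalty in ("L1", "L2"):
            R = regularized_precision(confounder_series, penalty, 0.0).matrix
            assert np.allclose(R, P, atol=1e-6)

    def test_negative_lambda_rejected(self, confounder_series):
        with pytest.raises(ValueError, match="nonnegative"):
            regularized_precision(confounder_series, "L1", -1.0)

    def test_l1_shrinks_fully(self, confounder_series):
        R = regularized_precision(confounder_series, "L1", 5.0).matrix
        off = R[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-8)

    def test_l1_sparsity_monotone(self, stable_w):
        ts = simulate_linear(LinearSimConfig(W=stable_w, duration=100.0, seed=5))
        counts = []
        for lam in (0.01, 0.05, 0.1, 0.3, 1.0):
            R = regularized_precision(ts, "L1", lam).matrix
            counts.append(int(np.sum(np.abs(R[~np.eye(5, dtype=bool)]) > 1e-3)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_l2_optimality_condition(self, stable_w):
        ts = simulate_linear(LinearSimConfig(W=stable_w, duration=100.0, seed=5))
        lam = 0.5
        C = cov_estimator(ts).matrix
        R = regularized_precision(ts, "L2", lam).matrix
        assert np.allclose(np.diag(R), 1.0, atol=1e-12)
        # undo the unit-diagonal rescaling, then (C + lam I) M = I must hold
        M = np.linalg.inv(C + lam * np.eye(5))
        d = np.sqrt(np.diag(M))
        assert np.allclose(R * np.outer(d, d), M, atol=1e-6)


class TestDifferentialCovariance:
    def test_constant_input_zero(self):
        ts = TimeSeries(values=np.full((2, 100), 3.0), dt=0.1)
        assert np.all(delta_c(ts, standardize=False).matrix == 0)

    def test_composition_oracle(self, rng):
        ts = TimeSeries(values=rng.standard_normal((3, 500)), dt=0.05)
        expected = time_average_outer(numerical_derivative(ts), interior(ts))
        assert np.allclose(delta_c(ts, standardize=False).matrix, expected,
                           atol=1e-12)

    def test_decay_identity(self, rng):
        # for dx/dt = -x with the analytic derivative, <dx/dt, x> = -<x, x>
        x = rng.standard_normal((1, 1000))
        dc = time_average_outer(-x, x)
        assert dc[0, 0] == pytest.approx(-np.mean(x ** 2))

    def test_delta_p_two_nodes_equals_delta_c(self, rng):
        ts = TimeSeries(values=rng.standard_normal((2, 2000)), dt=0.01)
        assert np.allclose(delta_p(ts).matrix, delta_c(ts).matrix, atol=1e-12)

    def test_delta_p_brute_force_oracle(self, rng):
        ts = TimeSeries(values=rng.standard_normal((4, 3000)), dt=0.01)
        dp = delta_p(ts).matrix
        z = zscore(ts)
        dc = delta_c(z, standardize=False).matrix
        C = cov_estimator(z, standardize=False).matrix
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert dp[i, j] == pytest.approx(dc[i, j])
                    continue
                K = [k for k in range(4) if k not in (i, j)]
                expected = dc[i, j] - C[j, K] @ np.linalg.inv(
                    C[np.ix_(K, K)]) @ dc[i, K]
                assert dp[i, j] == pytest.approx(expected, abs=1e-10)

    def test_delta_p_null_bound(self, rng):
        T = 100000
        ts = TimeSeries(values=rng.standard_normal((3, T)), dt=0.01)
        dp = delta_p(ts).matrix
        off = dp[~np.eye(3, dtype=bool)]
        # derivative scaling: sd of <dx/dt, x> entries is ~1/(dt*sqrt(2T))
        assert np.max(np.abs(off)) < 5.0 / (np.sqrt(T) * 2 * ts.dt)


class TestLinearDDC:
    def test_exact_recovery_with_analytic_derivative(self, rng):
        for _ in range(3):
            W = 0.4 * rng.standard_normal((4, 4)) - np.eye(4)
            x0 = rng.standard_normal(4)
            n = 2000
            X = np.empty((4, n))
            x = x0
            for k in range(n):
                X[:, k] = x
                x = x + 0.01 * (W @ x)
            est = ddc_linear_from_arrays(W @ X, X)
            assert np.allclose(est, W, atol=1e-10)

    def test_equals_row_wise_ols(self, rng):
        dx = rng.standard_normal((3, 400))
        x = rng.standard_normal((3, 400))
        est = ddc_linear_from_arrays(dx, x)
        ols, *_ = np.linalg.lstsq(x.T, dx.T, rcond=None)
        assert np.allclose(est, ols.T, atol=1e-10)

    def test_leaky_closed_form(self, rng):
        # tau dx/dt = -x + W x is the linear system (W - I)/tau
        tau = 0.1
        W = np.array([[0.0, 0.0, 0.0], [-0.5, 0.0, 0.0], [-0.5, 0.0, 0.0]])
        A = (W - np.eye(3)) / tau
        cfg = LinearSimConfig(W=A, duration=500.0, seed=11, dt=0.005)
        ts = simulate_linear(cfg)
        est = ddc_linear(ts, standardize=False).matrix
        assert np.allclose(est, A, atol=0.25 * np.abs(A).max())

    def test_directed_asymmetry_on_motif(self, confounder_series, confounder):
        M = ddc_linear(confounder_series).matrix
        for i, j in zip(*np.nonzero(np.tril(confounder.W, -1))):
            assert abs(M[i, j]) > abs(M[j, i])

    def test_singular_needs_flag(self, rng):
        x = rng.standard_normal(500)
        ts = TimeSeries(values=np.vstack([x, x]), dt=0.01)
        with pytest.raises(np.linalg.LinAlgError):
            ddc_linear(ts, standardize=False)
        assert np.all(np.isfinite(
            ddc_linear(ts, standardize=False, pseudoinverse=True).matrix))


class TestNonlinearDDC:
    def test_identity_equals_linear(self, confounder_series):
        lin = ddc_linear(confounder_series).matrix
        non = ddc_nonlinear(confounder_series, ResponseFunction("identity")).matrix
        assert np.allclose(lin, non, atol=1e-10)

    def test_inactive_relu_equals_linear(self, confounder_series):
        z = zscore(confounder_series)
        theta = float(z.values.min()) - 1.0
        non = ddc_nonlinear(confounder_series,
                            ResponseFunction("relu", theta=theta)).matrix
        assert np.allclose(non, ddc_linear(confounder_series).matrix, atol=1e-10)

    def test_leaky_consistency_from_arrays(self, rng):
        # tau dx/dt = -x + W R(x) with the analytic derivative gives DD = W
        W = np.array([[-1.0, 0.0, 0.0], [-0.5, -1.0, 0.0], [0.3, -0.5, -1.0]])
        tau = 0.2

        def R(x):
            return np.tanh(x)

        n, dt = 4000, 0.001
        X = np.empty((3, n))
        x = rng.standard_normal(3)
        for k in range(n):
            X[:, k] = x
            x = x + dt * ((-x + W @ R(x)) / tau) + 0.05 * np.sqrt(dt) * \
                rng.standard_normal(3)
        dX = (-X + W @ R(X)) / tau
        est = ddc_leaky_from_arrays(dX, X, R(X), tau, center_response=False)
        assert np.allclose(est, W, atol=1e-8)

    def test_leaky_tau_zero_limit(self, rng):
        X = rng.standard_normal((3, 1000))
        dX = rng.standard_normal((3, 1000))
        est = ddc_leaky_from_arrays(dX, X, X, tau=1e-12, center_response=False)
        assert np.allclose(est, np.eye(3), atol=1e-8)

    def test_tau_must_be_positive(self, rng):
        X = rng.standard_normal((3, 100))
        with pytest.raises(ValueError, match="tau"):
            ddc_leaky_from_arrays(X, X, X, tau=0.0)


class TestThresholdScan:
    def test_single_theta_grid(self, confounder_series, confounder):
        theta, est = relu_threshold_scan(confounder_series, confounder, n_grid=1)
        z = zscore(confounder_series)
        assert theta == pytest.approx(np.percentile(z.values, 5.0))
        assert est.params["theta"] == pytest.approx(theta)

    def test_linear_data_selects_near_linear_model(self, confounder_series,
                                                   confounder):
        from ddcov import normalized_error

        theta, est = relu_threshold_scan(confounder_series, confounder)
        err_scan = normalized_error(est.matrix, confounder.W)
        err_lin = normalized_error(ddc_linear(confounder_series).matrix,
                                   confounder.W)
        assert err_scan <= err_lin + 0.05

    def test_default_grid_near_fine_grid(self, confounder_series, confounder):
        from ddcov import normalized_error

        _, est_default = relu_threshold_scan(confounder_series, confounder,
                                             n_grid=19)
        _, est_fine = relu_threshold_scan(confounder_series, confounder,
                                          n_grid=181)
        e_default = normalized_error(est_default.matrix, confounder.W)
        e_fine = normalized_error(est_fine.matrix, confounder.W)
        grid_step = 0.05  # error resolution of one 5-percentile step
        assert e_default <= e_fine + grid_step

    def test_truth_required(self, confounder_series):
        with pytest.raises(ValueError, match="truth"):
            relu_threshold_scan(confounder_series, None)


def _poisson_train(rate, duration, rng):
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


class TestCspk:
    def test_low_rate_zeroed(self, rng):
        st = SpikeTrains(spike_times=(np.array([10.0]),
                                      _poisson_train(5.0, 20.0, rng),
                                      _poisson_train(5.0, 20.0, rng)),
                         duration=20.0)
        M = cspk(st).matrix
        assert np.all(M[0, :] == 0) and np.all(M[:, 0] == 0)

    def test_independent_trains_below_shuffle_null(self, rng):
        duration = 100.0
        st = SpikeTrains(spike_times=(_poisson_train(5.0, duration, rng),
                                      _poisson_train(5.0, duration, rng)),
                         duration=duration)
        obs = cspk(st).matrix[0, 1]
        null = []
        for _ in range(20):
            shuffled = SpikeTrains(
                spike_times=(_poisson_train(5.0, duration, rng),
                             _poisson_train(5.0, duration, rng)),
                duration=duration)
            null.append(cspk(shuffled).matrix[0, 1])
        assert abs(obs) < 3.0 * np.std(null) + 1e-12

    def test_delayed_copy_detected(self, rng):
        duration = 60.0
        src = _poisson_train(8.0, duration - 0.1, rng)
        delayed = src + 0.02  # j is a 20 ms delayed copy of i
        third = _poisson_train(8.0, duration, rng)
        st = SpikeTrains(spike_times=(src, delayed, third), duration=duration)
        M = cspk(st).matrix
        off = np.abs(M[~np.eye(3, dtype=bool)])
        # influence i -> j shows up at entry (target j=1, source i=0)
        assert abs(M[1, 0]) == pytest.approx(off.max())

    def test_window_validation(self):
        st = SpikeTrains(spike_times=(np.array([0.5]),), duration=1.0)
        with pytest.raises(ValueError, match="tau_window"):
            cspk(st, tau_window=0.0)


class TestRegistryAndIO:
    def test_unknown_name_lists_valid(self, confounder_series):
        with pytest.raises(ValueError, match="DDC_L"):
            get_estimator("bogus")

    def test_relu_without_theta(self, confounder_series):
        with pytest.raises(ValueError, match="theta"):
            get_estimator("DDC_ReLU")(confounder_series)

    def test_estimate_round_trip(self, tmp_path, confounder_series):
        est = ddc_linear(confounder_series)
        path = tmp_path / "est.csv"
        write_estimate(est, path)
        back = read_estimate(path)
        assert np.allclose(back.matrix, est.matrix, atol=1e-15)
        assert back.estimator == "DDC_L"
        assert back.node_ids == est.node_ids
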