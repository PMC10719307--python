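import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mallostasis import (
    AnalyticState,
    ModelParameters,
    NaturalBasis,
    diagonalize,
    equilibrium,
    from_natural,
    mean_solution,
    memory_drift,
    predict_step,
    recovery_fraction,
    steady_state_lag,
    steady_state_mean,
    steady_state_variance,
    to_natural,
    variance_solution,
)

RNG = np.random.default_rng(42)


def _params(W, Lambda, Sigma, covs=("const", "age")):
    m = np.atleast_2d(W).shape[0]
    return ModelParameters(
        W=W, Lambda=Lambda, Sigma=Sigma,
        biomarker_names=[f"b{j}" for j in range(m)],
        covariate_names=list(covs),
    )


class TestEquilibrium:
    def test_age_independent_when_no_drift(self):
        p = _params(-0.1 * np.eye(1), [[2.0, 0.0]], np.zeros((1, 1)))
        assert equilibrium(p, [], 0.0) == pytest.approx(equilibrium(p, [], 99.0))

    def test_scalar_arithmetic(self):
        p = _params([[-0.1]], [[2.0, 0.5]], [[0.0]])
        assert equilibrium(p, [], 4.0)[0] == pytest.approx(4.0)

    def test_matches_matrix_oracle(self):
        m, c = 4, 3
        Lam = RNG.standard_normal((m, c + 2))
        p = _params(-np.eye(m), Lam, np.eye(m), covs=["const", "u", "v", "w", "age"])
        x = RNG.standard_normal(c)
        t = 7.3
        expected = Lam @ np.concatenate([[1.0], x, [t]])
        assert np.allclose(equilibrium(p, x, t), expected)

    def test_dimension_mismatch_is_error(self):
        p = _params([[-0.1]], [[2.0, 0.5]], [[0.0]])
        with pytest.raises(ValueError):
            equilibrium(p, [1.0, 2.0], 0.0)


class TestPredictStep:
    def test_equilibrium_is_fixed_point(self):
        p = _params(-0.3 * np.eye(2), RNG.standard_normal((2, 2)), np.eye(2))
        mu = equilibrium(p, [], 5.0)
        assert np.allclose(predict_step(p, mu, [], 5.0, 2.0), mu)

    def test_zero_network_returns_input(self):
        p = _params(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)))
        y = np.array([1.0, -2.0])
        assert np.allclose(predict_step(p, y, [], 0.0, 3.0), y)

    def test_hand_matrix_arithmetic(self):
        W = np.array([[-0.5, 0.0], [0.0, -0.25]])
        p = _params(W, np.zeros((2, 2)), np.zeros((2, 2)))
        y = np.array([1.0, 1.0])  # mu = 0 so deviation is (1, 1)
        out = predict_step(p, y, [], 0.0, 1.0)
        assert np.allclose(out, [0.5, 0.75])

    def test_euler_refinement_converges_to_ode(self):
        # iterated predict_step approaches the continuous mean solution at order dt
        lam, mu0, z0, T = -0.4, 1.0, 3.0, 5.0
        p = _params([[lam]], [[mu0, 0.0]], [[0.0]])
        state = AnalyticState(lam=lam, mu0=mu0, mu_age=0.0, z0_mean=z0, z0_var=0.0, sigma2=0.0)
        errs = []
        for n_steps in (50, 100, 200):
            dt = T / n_steps
            y = np.array([z0])
            for k in range(n_steps):
                y = predict_step(p, y, [], k * dt, dt)
            errs.append(abs(y[0] - mean_solution(state, T)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[1] / errs[2] == pytest.approx(2.0, rel=0.2)  # order 1


class TestNaturalTransform:
    def test_identity_basis(self):
        b = NaturalBasis(P=np.eye(3), eigenvalues=np.zeros(3), is_orthogonal=True)
        y = RNG.standard_normal(3)
        assert np.allclose(to_natural(b, y), y)

    def test_parseval_under_orthogonal_rotation(self):
        A = RNG.standard_normal((4, 4))
        Q, _ = np.linalg.qr(A)
        b = NaturalBasis(P=Q, eigenvalues=np.zeros(4), is_orthogonal=True)
        y = RNG.standard_normal((200, 4))
        z = to_natural(b, y)
        sum_y = (y**2).sum(axis=1).mean()
        sum_z = (z**2).sum(axis=1).mean()
        assert sum_y == pytest.approx(sum_z, abs=1e-8)

    def test_round_trip_general_invertible(self):
        P = RNG.standard_normal((5, 5)) + 5 * np.eye(5)
        b = NaturalBasis(P=P, eigenvalues=np.zeros(5))
        y = RNG.standard_normal((10, 5))
        assert np.allclose(from_natural(b, to_natural(b, y)), y, atol=1e-10)

    def test_singular_p_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            NaturalBasis(P=np.zeros((2, 2)), eigenvalues=np.zeros(2))


class TestDiagonalize:
    def test_diagonal_network_eigenvalues(self):
        W = np.diag([-0.9, -0.1])
        p = _params(W, np.zeros((2, 2)), np.eye(2))
        basis, tp = diagonalize(p)
        # least stable first: lambda = -0.1 leads
        assert np.allclose(basis.eigenvalues, [-0.1, -0.9])
        assert np.allclose(tp.W, np.diag([-0.1, -0.9]))

    def test_symmetric_network_vs_eigh_oracle(self):
        A = RNG.standard_normal((3, 3))
        W = -(A @ A.T) / 3 - 0.05 * np.eye(3)
        p = _params(W, RNG.standard_normal((3, 2)), np.eye(3))
        basis, tp = diagonalize(p)
        off = tp.W - np.diag(np.diag(tp.W))
        assert np.abs(off).max() < 1e-8
        oracle = np.sort(np.linalg.eigvalsh(W))[::-1]
        assert np.allclose(basis.eigenvalues, oracle)
        # transformed loadings follow P^-1
        assert np.allclose(tp.Lambda, basis.P_inv @ p.Lambda)

    def test_complex_eigenvalues_refused(self):
        W = np.array([[0.0, -1.0], [1.0, 0.0]])  # rotation: eigenvalues +/- i
        p = _params(W, np.zeros((2, 2)), np.eye(2))
        with pytest.raises(ValueError, match="PCA"):
            diagonalize(p)


class TestScalarAnalytics:
    state = AnalyticState(lam=-0.3, mu0=1.0, mu_age=0.05, z0_mean=2.0, z0_var=1.0, sigma2=0.5)

    def test_initial_condition(self):
        assert mean_solution(self.state, 0.0) == pytest.approx(2.0)

    def test_long_time_reaches_steady_state(self):
        t = 90.0  # |lam| t = 27 >> 1
        assert mean_solution(self.state, t) == pytest.approx(
            steady_state_mean(self.state, t), abs=1e-8
        )

    def test_mean_matches_rk_oracle(self):
        st = self.state

        def ode(t, z):
            return st.lam * (z - (st.mu0 + st.mu_age * t))

        sol = solve_ivp(ode, (0, 5), [st.z0_mean], rtol=1e-10, atol=1e-12)
        assert mean_solution(st, 5.0) == pytest.approx(sol.y[0, -1], abs=1e-6)

    def test_steady_state_lag_value(self):
        st = AnalyticState(lam=-0.025, mu0=0.0, mu_age=-0.01, z0_mean=0.0, z0_var=0.0, sigma2=0.0)
        assert steady_state_lag(st) == pytest.approx(0.4)
        # long-time integration converges to mu(t) + lag
        t = 400.0
        assert mean_solution(st, t) - st.mu(t) == pytest.approx(0.4, abs=1e-4)

    def test_positive_drift_gives_negative_lag(self):
        st = AnalyticState(lam=-0.025, mu0=0.0, mu_age=0.02, z0_mean=0.0, z0_var=0.0, sigma2=0.0)
        assert steady_state_lag(st) < 0

    def test_no_drift_steady_state_is_mu(self):
        st = AnalyticState(lam=-0.5, mu0=3.0, mu_age=0.0, z0_mean=0.0, z0_var=0.0, sigma2=0.0)
        assert steady_state_lag(st) == 0.0
        assert steady_state_mean(st, 10.0) == pytest.approx(3.0)

    def test_unstable_lambda_has_no_steady_state(self):
        st = AnalyticState(lam=0.1, mu0=0.0, mu_age=0.0, z0_mean=1.0, z0_var=0.0, sigma2=0.0)
        with pytest.raises(ValueError):
            steady_state_mean(st, 1.0)
        with pytest.raises(ValueError):
            steady_state_variance(st)

    def test_marginal_lambda_preserves_initial_conditions(self):
        st = AnalyticState(lam=0.0, mu0=1.0, mu_age=0.1, z0_mean=5.0, z0_var=0.0, sigma2=0.0)
        assert mean_solution(st, 100.0) == pytest.approx(5.0)

    def test_unstable_deviation_grows_exponentially(self):
        st = AnalyticState(lam=0.2, mu0=0.0, mu_age=0.0, z0_mean=1.0, z0_var=0.0, sigma2=0.0)
        assert mean_solution(st, 10.0) == pytest.approx(np.exp(2.0))


class TestMemoryDrift:
    def test_at_reference_time(self):
        st = AnalyticState(lam=-0.1, mu0=0.0, mu_age=0.02, z0_mean=0.0, z0_var=0.0, sigma2=0.0)
        mem, drift = memory_drift(st, 3.0, 3.0, observed_dev_at_t0=1.5)
        assert mem == pytest.approx(1.5)
        assert drift == pytest.approx(0.0)

    def test_long_time_limits(self):
        st = AnalyticState(lam=-0.1, mu0=0.0, mu_age=0.02, z0_mean=0.0, z0_var=0.0, sigma2=0.0)
        mem, drift = memory_drift(st, 1000.0, 0.0, observed_dev_at_t0=1.0)
        assert mem == pytest.approx(0.0, abs=1e-20)
        assert drift == pytest.approx(st.mu_age / st.lam)

    def test_scalar_arithmetic_oracle(self):
        lam, mu_age, dev0, dt = -0.1, 0.02, 1.0, 10.0
        st = AnalyticState(lam=lam, mu0=0.0, mu_age=mu_age, z0_mean=0.0, z0_var=0.0, sigma2=0.0)
        mem, drift = memory_drift(st, dt, 0.0, dev0)
        assert mem == pytest.approx(dev0 * np.exp(-1.0))
        assert drift == pytest.approx((mu_age / lam) * (1 - np.exp(-1.0)))
        # sum equals the deviation predicted by the mean solution started at dev0
        st2 = AnalyticState(lam=lam, mu0=0.0, mu_age=mu_age, z0_mean=dev0, z0_var=0.0, sigma2=0.0)
        dev_t = mean_solution(st2, dt) - st2.mu(dt)
        assert mem + drift == pytest.approx(dev_t)


class TestVariance:
    def test_noiseless_decay(self):
        st = AnalyticState(lam=-0.3, mu0=0.0, mu_age=0.0, z0_mean=0.0, z0_var=2.0, sigma2=0.0)
        assert variance_solution(st, 4.0) == pytest.approx(2.0 * np.exp(-2.4))

    def test_long_time_equilibrates(self):
        st = AnalyticState(lam=-0.2, mu0=0.0, mu_age=0.0, z0_mean=0.0, z0_var=1.0, sigma2=0.5)
        assert variance_solution(st, 200.0) == pytest.approx(0.5 / 0.4)
        assert steady_state_variance(st) == pytest.approx(1.25)

    def test_matches_ode_oracle(self):
        st = AnalyticState(lam=-0.2, mu0=0.0, mu_age=0.0, z0_mean=0.0, z0_var=1.0, sigma2=0.5)

        def ode(t, v):
            return 2 * st.lam * v + st.sigma2

        sol = solve_ivp(ode, (0, 3), [st.z0_var], rtol=1e-10, atol=1e-12)
        assert variance_solution(st, 3.0) == pytest.approx(sol.y[0, -1], abs=1e-6)


class TestRecoveryFraction:
    @pytest.mark.parametrize(
        "rate,elapsed,expected",
        [
            (0.025, 40.0, 1 - np.exp(-1)),  # 63% after one timescale
            (0.025, 0.0, 0.0),
            (0.025, 120.0, 1 - np.exp(-3)),  # 95% after three timescales
        ],
    )
    def test_values(self, rate, elapsed, expected):
        assert recovery_fraction(rate, elapsed) == pytest.approx(expected)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            recovery_fraction(0.0, 1.0)


def test_parameter_file_round_trip(tmp_path):
    W = RNG.standard_normal((3, 3))
    W = -(W @ W.T)
    p = ModelParameters(
        W=W,
        Lambda=RNG.standard_normal((3, 3)),
        Sigma=np.eye(3) * 0.3,
        biomarker_names=["a", "b", "c"],
        covariate_names=["const", "sex", "age"],
    )
    path = tmp_path / "params.txt"
    p.to_text(path)
    q = ModelParameters.from_text(path)
    assert np.array_equal(p.W, q.W)
    assert np.array_equal(p.Lambda, q.Lambda)
    assert np.array_equal(p.Sigma, q.Sigma)
    assert q.covariate_names == p.covariate_names
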