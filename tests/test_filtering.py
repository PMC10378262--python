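"""Generalised coordinates, Lagrangian/action, free-energy stack, filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varsel import (FreeEnergyReport, GeneralisedPath, GenerativeModel,
                    VariationalDensity, action, action_from_lagrangians,
                    active_inference_step, free_energy,
                    generalised_fluctuation_covariance, lagrangian,
                    least_action_path, make_particular_flow, shift,
                    taylor_embed, variational_density)
from varsel.langevin import PartitionSpec

LOG2PI = math.log(2.0 * math.pi)


def random_model(rng, k=None, m=None):
    k = k or rng.integers(1, 4)
    m = m or rng.integers(1, 4)
    A0 = rng.normal(size=(k, k))
    P0 = A0 @ A0.T + k * np.eye(k)
    As = rng.normal(size=(m, m))
    Ps = As @ As.T + m * np.eye(m)
    return GenerativeModel(prior_mean=rng.normal(size=k), prior_precision=P0,
                           likelihood=rng.normal(size=(m, k)),
                           noise_precision=Ps)


class TestShift:
    def test_definition(self):
        p = GeneralisedPath([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(shift(p).values, [[3.0, 4.0], [0.0, 0.0]])

    def test_nilpotence(self):
        p = GeneralisedPath(np.arange(12.0).reshape(4, 3) + 1)
        out = p
        for _ in range(p.order + 1):
            out = shift(out)
        assert np.all(out.values == 0)

    @given(st.floats(-100, 100), st.integers(1, 4))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_commutes_with_scalar_multiplication(self, c, order):
        vals = np.linspace(1, 2 * (order + 1), 2 * (order + 1)).reshape(-1, 2)
        p = GeneralisedPath(vals)
        np.testing.assert_allclose(shift(GeneralisedPath(c * vals)).values,
                                   c * shift(p).values)


class TestLagrangian:
    @pytest.fixture
    def scalar_flow(self):
        part = PartitionSpec([], [], [], [0])
        return make_particular_flow(part, [[1.0]], [[0.0]], [[1.0]])

    def test_on_path_of_least_action(self, scalar_flow):
        # residual vanishes on the (trivial) least-action path; the value is
        # half the flow divergence: 1/2 (ln 1 + 0 + (-1)) = -0.5
        p = GeneralisedPath([[0.0], [0.0]])
        assert lagrangian(scalar_flow, p) == pytest.approx(-0.5)

    def test_doubling_residual_quadruples_quadratic_term(self, scalar_flow):
        base = lagrangian(scalar_flow, GeneralisedPath([[0.0], [0.0]]))
        p1 = GeneralisedPath([[1.0], [-1.0]])     # residual at top order only
        p2 = GeneralisedPath([[2.0], [-2.0]])
        q1 = lagrangian(scalar_flow, p1) - base
        q2 = lagrangian(scalar_flow, p2) - base
        assert q2 == pytest.approx(4.0 * q1)

    def test_matches_gaussian_density_oracle(self, rng):
        # independently coded: 1/2 [ln|Gk| + r'(2 Gk)^{-1} r + tr J] with
        # Gk the Kronecker generalised covariance assembled explicitly
        part = PartitionSpec([], [], [], [0, 1])
        A = rng.normal(size=(2, 2))
        Pi = A @ A.T + 2 * np.eye(2)
        Gamma = np.diag(rng.uniform(0.5, 2.0, 2))
        flow = make_particular_flow(part, Pi, np.zeros((2, 2)), Gamma)
        vals = rng.normal(size=(3, 2))
        p = GeneralisedPath(vals)
        sigma = 0.7
        got = lagrangian(flow, p, roughness=sigma)

        S = generalised_fluctuation_covariance(2, sigma)
        Gk = np.kron(S, Gamma)
        J = flow.jacobian
        f = vals @ J.T
        r = np.zeros_like(vals)
        r[:-1] = vals[1:] - f[:-1]
        r[-1] = -f[-1]
        rv = r.ravel()
        expected = 0.5 * (np.linalg.slogdet(Gk)[1]
                          + rv @ np.linalg.solve(2.0 * Gk, rv)
                          + np.trace(J))
        assert got == pytest.approx(expected, rel=1e-10)

    def test_divergence_switch(self, scalar_flow):
        p = GeneralisedPath([[0.0], [0.0]])
        assert lagrangian(scalar_flow, p, include_divergence=False) == \
            pytest.approx(0.0)


class TestAction:
    def test_empty_path_is_zero(self, scalar_ou_flow):
        assert action(scalar_ou_flow, [], 0.1) == 0.0

    def test_constant_lagrangian_times_duration(self, scalar_ou_flow):
        # the zero path has constant L = -0.5; over T = 10: A = -5
        paths = [GeneralisedPath([[0.0], [0.0]]) for _ in range(101)]
        assert action(scalar_ou_flow, paths, 0.1) == pytest.approx(-5.0)

    def test_trace_integral_helper(self):
        assert action_from_lagrangians(np.array([]), 0.1) == 0.0
        assert action_from_lagrangians(np.full(11, 2.0), 0.5) == \
            pytest.approx(10.0)


class TestGeneralisedFluctuations:
    def test_order_one_structure(self):
        S = generalised_fluctuation_covariance(1, 0.5)
        np.testing.assert_allclose(S, [[1.0, 0.0], [0.0, 4.0]])

    @pytest.mark.parametrize("order,sigma", [(1, 0.3), (2, 0.5), (3, 1.0)])
    def test_positive_definite(self, order, sigma):
        S = generalised_fluctuation_covariance(order, sigma)
        assert np.linalg.eigvalsh(S).min() > 0


class TestTaylorEmbed:
    def test_polynomial_derivatives_recovered_exactly(self):
        dt = 0.1
        t = dt * np.arange(9)
        t0 = t[4]
        y = 2.0 + 3.0 * (t - t0) - 0.5 * (t - t0) ** 2
        p = taylor_embed(y, order=2, dt=dt)
        np.testing.assert_allclose(p.values.ravel(), [2.0, 3.0, -1.0],
                                   atol=1e-10)


def rts_smoother(y, A, c, Qv, G, R, m0, P0):
    """Independent oracle: forward Kalman filter + RTS backward pass."""
    T = len(y)
    mf, Pf, mp, Pp = [], [], [], []
    m, P = np.asarray(m0, float), np.asarray(P0, float)
    for t in range(T):
        if t > 0:
            m = A @ m + c
            P = A @ P @ A.T + Qv
        mp.append(m.copy())
        Pp.append(P.copy())
        S = G @ P @ G.T + R
        K = P @ G.T @ np.linalg.inv(S)
        m = m + K @ (np.atleast_1d(y[t]) - G @ m)
        P = P - K @ G @ P
        mf.append(m.copy())
        Pf.append(P.copy())
    ms = [None] * T
    ms[-1] = mf[-1]
    for t in range(T - 2, -1, -1):
        Jt = Pf[t] @ A.T @ np.linalg.inv(Pp[t + 1])
        ms[t] = mf[t] + Jt @ (ms[t + 1] - mp[t + 1])
    return np.array(ms)


class TestLeastActionPath:
    @pytest.fixture
    def dynamic_model(self):
        return GenerativeModel(prior_mean=[0.0], prior_precision=[[1.0]],
                               likelihood=[[1.0]], noise_precision=[[4.0]],
                               drift=[[-1.0]], fluct_amplitude=[[0.5]])

    def test_noise_free_data_recovers_deterministic_solution(self):
        # tight observation of a clean exponential decay: the least-action
        # path reproduces the ODE solution within discretisation error
        model = GenerativeModel(prior_mean=[1.0], prior_precision=[[1.0]],
                                likelihood=[[1.0]],
                                noise_precision=[[1e6]],
                                drift=[[-1.0]], fluct_amplitude=[[0.5]])
        dt = 0.01
        t = dt * np.arange(200)
        s = np.exp(-t)
        res = least_action_path(model, s, dt)
        assert np.abs(res.mean_path[:, 0] - s).max() < 5 * dt

    def test_terminal_gradient_norm_below_tolerance(self, dynamic_model, rng):
        s = rng.normal(size=100)
        res = least_action_path(dynamic_model, s, 0.1)
        assert res.gradient_norm < 1e-6

    def test_matches_kalman_smoother_oracle(self, dynamic_model, rng):
        dt = 0.1
        n = 300
        phi = 1.0 - dt
        eta = np.zeros(n)
        for t in range(1, n):
            eta[t] = phi * eta[t - 1] + rng.normal(0, np.sqrt(2 * 0.5 * dt))
        s = eta + rng.normal(0, 0.5, n)
        res = least_action_path(dynamic_model, s, dt)
        oracle = rts_smoother(
            s, A=np.array([[phi]]), c=np.zeros(1),
            Qv=np.array([[2 * 0.5 * dt]]), G=np.array([[1.0]]),
            R=np.array([[0.25]]), m0=np.zeros(1), P0=np.array([[1.0]]))
        rms = np.sqrt(np.mean((res.mean_path[:, 0] - oracle[:, 0]) ** 2))
        scale = np.sqrt(np.mean(oracle[:, 0] ** 2))
        assert rms / scale < 0.02


class TestVariationalDensity:
    def test_conjugate_update(self, conjugate_model):
        q = variational_density(conjugate_model, [2.0])
        assert q.mean[0] == pytest.approx(1.0)
        assert q.cov[0, 0] == pytest.approx(0.5)

    def test_infinite_sensory_noise_returns_prior(self):
        model = GenerativeModel(prior_mean=[0.3], prior_precision=[[2.0]],
                                likelihood=[[1.0]],
                                noise_precision=[[1e-12]])
        q = variational_density(model, [100.0])
        assert q.mean[0] == pytest.approx(0.3, abs=1e-9)
        assert q.cov[0, 0] == pytest.approx(0.5, abs=1e-9)

    def test_matches_grid_integration_oracle(self, rng):
        model = random_model(rng, k=2, m=2)
        s = rng.normal(size=2)
        q = variational_density(model, s)
        # brute-force Bayes on a grid
        g = np.linspace(-6, 6, 301)
        X, Y = np.meshgrid(g, g, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel()], axis=1)
        d0 = pts - model.prior_mean
        log_prior = -0.5 * np.einsum("ni,ij,nj->n", d0,
                                     model.prior_precision, d0)
        resid = s - pts @ model.likelihood.T
        log_lik = -0.5 * np.einsum("ni,ij,nj->n", resid,
                                   model.noise_precision, resid)
        w = np.exp(log_prior + log_lik - (log_prior + log_lik).max())
        w /= w.sum()
        mean = w @ pts
        np.testing.assert_allclose(q.mean, mean, atol=2e-3)


class TestFreeEnergy:
    def test_exact_posterior_attains_log_evidence(self, conjugate_model):
        q = variational_density(conjugate_model, [2.0])
        rep = free_energy(conjugate_model, q, [2.0])
        assert rep.divergence == pytest.approx(0.0, abs=1e-12)
        assert rep.F == pytest.approx(-rep.log_evidence)
        assert rep.F == pytest.approx(0.5 * np.log(4 * np.pi) + 1.0)

    def test_perturbing_the_mean_strictly_increases_f(self, conjugate_model):
        q = variational_density(conjugate_model, [2.0])
        rep0 = free_energy(conjugate_model, q, [2.0])
        for eps in (0.1, 0.5, 2.0):
            qp = VariationalDensity(q.mean + eps, q.cov)
            assert free_energy(conjugate_model, qp, [2.0]).F > rep0.F

    def test_complexity_zero_when_variational_equals_prior(self, conjugate_model):
        q = VariationalDensity(conjugate_model.prior_mean,
                               np.linalg.inv(conjugate_model.prior_precision))
        rep = free_energy(conjugate_model, q, [2.0])
        assert rep.complexity == pytest.approx(0.0, abs=1e-12)

    def test_decomposition_identities_on_random_models(self, rng):
        for _ in range(20):
            model = random_model(rng)
            s = rng.normal(size=model.m)
            mean = rng.normal(size=model.k)
            A = rng.normal(size=(model.k, model.k))
            cov = A @ A.T + model.k * np.eye(model.k)
            rep = free_energy(model, VariationalDensity(mean, cov), s)
            # validate() enforces all three identities at 1e-8 and ELBO
            assert rep.F >= -rep.log_evidence - 1e-10

    def test_report_validation_catches_inconsistency(self):
        bad = FreeEnergyReport(F=1.0, energy=5.0, entropy=1.0, complexity=2.0,
                               accuracy=1.0, divergence=0.5, log_evidence=-0.5)
        with pytest.raises(AssertionError):
            bad.validate()


class TestActiveInferenceStep:
    def test_step_is_pure_shift_at_the_minimum(self, conjugate_model):
        s = np.array([2.0])
        q = variational_density(conjugate_model, s)
        mu, a, _ = active_inference_step(conjugate_model, q.mean, [0.0], s,
                                         dt=0.1, action_sensitivity=[[0.0]])
        np.testing.assert_allclose(mu, q.mean, atol=1e-12)

    def test_f_non_increasing_for_static_input(self, conjugate_model):
        mu = np.array([-3.0])
        s = np.array([2.0])
        prev = np.inf
        for _ in range(50):
            mu, _, rep = active_inference_step(conjugate_model, mu, [0.0], s,
                                               dt=0.05,
                                               action_sensitivity=[[0.0]])
            assert rep.F <= prev + 1e-12
            prev = rep.F

    def test_closed_loop_thermostat_reaches_prior_mean(self):
        from varsel import ThermostatEnvironment, fixtures
        fx = fixtures("thermostat")
        env_cfg = {k: v for k, v in fx.config["environment"].items()
                   if k != "kind"}
        env = ThermostatEnvironment(**env_cfg)
        res = env.evaluate(fx.config["theta"], fx.config["lifetime"], seed=0)
        target = fx.ground_truth["fixed_point_sensed"]
        assert res.extras["eta"][-1] == pytest.approx(target, abs=1e-6)
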