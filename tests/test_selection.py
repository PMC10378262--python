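"""Variational fitness, Langevin selection, and Bayesian model reduction."""

import numpy as np
import pytest
from scipy import stats

from varsel import (FilteringEnvironment, Genotype, QuadraticStubEnvironment,
                    SelectionConfig, VariationalDensity, bmr_delta_evidence,
                    evolve, fitness_gradient, free_energy, reduced_posterior,
                    sample_population, structure_select, variational_density,
                    variational_fitness)


@pytest.fixture
def stub_env():
    return QuadraticStubEnvironment(theta_star=[1.5])


@pytest.fixture
def filt_env():
    return FilteringEnvironment(m_env=1.0, a_env=1.0, gamma_env=0.5,
                                obs_noise_var=0.5, prior_var=1.0, dt=0.1)


class TestVariationalFitness:
    def test_zero_length_lifetime_has_zero_action(self, stub_env, filt_env):
        for env in (stub_env, filt_env):
            rec = variational_fitness(Genotype([0.7]), env, 0.0, seed=1)
            assert rec.A == 0.0

    def test_action_is_trace_integral(self, filt_env):
        rec = variational_fitness(Genotype([0.3]), filt_env, 20.0, seed=4)
        # validate() asserts the bookkeeping identity at 1e-10; re-derive here
        w = np.full(rec.F_trace.size, rec.dt)
        w[0] = w[-1] = rec.dt / 2
        assert rec.A == pytest.approx(float(w @ rec.F_trace), rel=1e-12)

    def test_matched_prior_beats_mismatched_prior(self, filt_env):
        # genotype whose prior equals the niche NESS mean accumulates more
        # evidence (lower action), averaged over paired seeds
        diffs = [
            variational_fitness(Genotype([3.0]), filt_env, 50.0, seed=s).A
            - variational_fitness(Genotype([1.0]), filt_env, 50.0, seed=s).A
            for s in range(20)]
        assert np.mean(diffs) > 0
        assert np.mean(diffs) > 2 * np.std(diffs) / np.sqrt(20)

    def test_determinism(self, filt_env):
        a1 = variational_fitness(Genotype([0.2]), filt_env, 30.0, seed=9).A
        a2 = variational_fitness(Genotype([0.2]), filt_env, 30.0, seed=9).A
        assert a1 == a2

    def test_stepwise_free_energy_matches_module_closed_form(self, filt_env):
        # dual route: the vectorised per-step F equals the free-energy stack
        # evaluated with the exact posterior at sampled steps
        rec = variational_fitness(Genotype([0.4]), filt_env, 10.0, seed=2)
        res = filt_env.evaluate([0.4], 10.0, 2)
        model = filt_env.agent_model([0.4])
        for t in (0, 17, 50, 99):
            s = res.extras["s"][t]
            q = variational_density(model, [s])
            rep = free_energy(model, q, [s])
            assert rec.F_trace[t] == pytest.approx(rep.F, rel=1e-10)


class TestFitnessGradient:
    def test_quadratic_stub_gradient_is_linear(self, stub_env):
        for theta in (-2.0, 0.0, 1.0, 4.0):
            g = fitness_gradient(Genotype([theta]), stub_env, 1.0, seed=0)
            assert g[0] == pytest.approx(theta - 1.5, abs=1e-6)

    def test_gradient_vanishes_at_the_optimum(self, stub_env):
        g = fitness_gradient(Genotype([1.5]), stub_env, 1.0, seed=0)
        assert abs(g[0]) < 1e-9

    def test_matches_closed_form_evidence_derivative(self, filt_env):
        # CRN finite differences against the analytic derivative of the
        # accumulated negative log evidence, same sensory realisation
        for theta, seed in [(0.0, 1), (1.0, 2), (-2.5, 3)]:
            g = fitness_gradient(Genotype([theta]), filt_env, 50.0,
                                 seed=seed, h=1e-4)
            oracle = filt_env.closed_form_gradient([theta], 50.0, seed)
            assert g[0] == pytest.approx(oracle, rel=1e-5)

    def test_unknown_estimator_rejected(self, stub_env):
        with pytest.raises(ValueError, match="estimator"):
            fitness_gradient(Genotype([0.0]), stub_env, 1.0,
                             estimator="adjoint")


class TestEvolve:
    def test_static_population_without_noise_or_gradient(self, stub_env):
        cfg = SelectionConfig(population_size=3, generations=10,
                              gamma_slow=0.0, dt_slow=1.0, lifetime=1.0,
                              seed=0)
        pop = [Genotype([1.5], gid=i) for i in range(3)]   # all at theta*
        res = evolve(pop, cfg, stub_env)
        np.testing.assert_allclose(res.thetas[-1], res.thetas[0], atol=1e-8)

    def test_same_seed_reproduces_history(self, stub_env):
        cfg = SelectionConfig(population_size=5, generations=20,
                              gamma_slow=0.1, dt_slow=0.5, lifetime=1.0,
                              seed=11)
        runs = [evolve(sample_population(5, [0.0], 1.0, 11), cfg, stub_env)
                for _ in range(2)]
        assert np.array_equal(runs[0].thetas, runs[1].thetas)
        assert np.array_equal(runs[0].actions, runs[1].actions)

    def test_population_mean_converges_to_optimum(self, stub_env):
        cfg = SelectionConfig(population_size=20, generations=200,
                              gamma_slow=0.2, dt_slow=0.5, lifetime=1.0,
                              seed=5)
        res = evolve(sample_population(20, [0.0], 1.0, 5), cfg, stub_env)
        final = res.final_population.ravel()
        se = final.std(ddof=1) / np.sqrt(final.size)
        assert abs(final.mean() - 1.5) < 3 * se

    def test_drift_variance_scales_with_gamma(self):
        # flat landscape (zero gradient): between-generation variance of the
        # pure drift term grows linearly in Gamma_slow
        env = QuadraticStubEnvironment(theta_star=[0.0], weights=[0.0])
        incr_var = {}
        for gamma in (0.05, 0.2):
            cfg = SelectionConfig(population_size=50, generations=40,
                                  gamma_slow=gamma, dt_slow=1.0,
                                  lifetime=1.0, seed=3)
            res = evolve(sample_population(50, [0.0], 0.0, 3), cfg, env)
            incr = np.diff(res.thetas[:, :, 0], axis=0)
            incr_var[gamma] = incr.var()
        ratio = incr_var[0.2] / incr_var[0.05]
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_lineage_frame_shape_and_parents(self, stub_env):
        cfg = SelectionConfig(population_size=4, generations=5,
                              gamma_slow=0.1, dt_slow=0.5, lifetime=1.0,
                              seed=1)
        res = evolve(sample_population(4, [0.0], 1.0, 1), cfg, stub_env)
        df = res.lineage_frame()
        assert len(df) == 6 * 4
        assert set(df.columns) >= {"generation", "gid", "parent", "theta_0", "A"}
        assert (df.loc[df.generation == 0, "parent"] == -1).all()

    def test_stationary_density_is_gibbs(self, stub_env):
        # long-run histogram ~ exp(-A) = N(theta*, 1): the operational
        # content of selection as Bayesian model selection (small run; the
        # full-size version lives in the acceptance suite)
        cfg = SelectionConfig(population_size=20, generations=3000,
                              gamma_slow=1.0, dt_slow=0.05, lifetime=1.0,
                              seed=8)
        res = evolve(sample_population(20, [1.5], 1.0, 8), cfg, stub_env)
        samples = res.thetas[500::60, :, 0].ravel()
        ks = stats.kstest(samples, "norm", args=(1.5, 1.0))
        assert ks.pvalue > 0.01


class TestBMR:
    def test_equal_priors_give_zero(self, rng):
        A = rng.normal(size=(2, 2))
        prior = VariationalDensity(rng.normal(size=2), A @ A.T + 2 * np.eye(2))
        B = rng.normal(size=(2, 2))
        post = VariationalDensity(rng.normal(size=2), B @ B.T + 2 * np.eye(2))
        assert bmr_delta_evidence(post, prior, prior) == pytest.approx(0.0,
                                                                       abs=1e-12)

    def test_matches_conjugate_two_model_oracle(self, rng):
        # y = theta + noise; evidence differences computed two independent
        # ways: BMR from the full posterior vs direct Gaussian marginals
        for _ in range(50):
            k = int(rng.integers(1, 4))
            m0 = rng.normal(size=k)
            mr = rng.normal(size=k)
            S0 = np.diag(rng.uniform(0.3, 2.0, k))
            Sr = np.diag(rng.uniform(0.02, 1.0, k))
            R = np.diag(rng.uniform(0.2, 1.5, k))
            y = rng.normal(size=k)
            P = np.linalg.inv(S0) + np.linalg.inv(R)
            S = np.linalg.inv(P)
            m = S @ (np.linalg.solve(S0, m0) + np.linalg.solve(R, y))
            delta = bmr_delta_evidence(
                VariationalDensity(m, S), VariationalDensity(m0, S0),
                VariationalDensity(mr, Sr))
            direct = (stats.multivariate_normal.logpdf(y, mr, Sr + R)
                      - stats.multivariate_normal.logpdf(y, m0, S0 + R))
            assert delta == pytest.approx(direct, abs=1e-6)

    def test_removing_a_needed_parameter_is_rejected(self):
        # posterior concentrated away from zero: pinning the parameter at
        # zero (precision -> infinity) must lower the evidence
        post = VariationalDensity([2.0], [[0.01]])
        prior = VariationalDensity([0.0], [[1.0]])
        removed = VariationalDensity([0.0], [[1e-8]])
        assert bmr_delta_evidence(post, prior, removed) < 0

    def test_reduced_posterior_matches_direct_conditioning(self, rng):
        prior = VariationalDensity([0.0], [[1.0]])
        post = VariationalDensity([0.8], [[0.2]])
        tighter = VariationalDensity([0.0], [[0.25]])
        rp = reduced_posterior(post, prior, tighter)
        # precision algebra: Pp = 1/0.2 + 4 - 1 = 8, mean = (0.8/0.2)/8
        assert rp.cov[0, 0] == pytest.approx(1 / 8)
        assert rp.mean[0] == pytest.approx(0.5)


class TestStructureSelect:
    def _regression_posterior(self, X, y, noise_var, prior_var):
        k = X.shape[1]
        P = np.eye(k) / prior_var + X.T @ X / noise_var
        S = np.linalg.inv(P)
        m = S @ (X.T @ y) / noise_var
        return (VariationalDensity(m, S),
                VariationalDensity(np.zeros(k), prior_var * np.eye(k)))

    def test_no_improving_candidate_leaves_model_unchanged(self, rng):
        # both regressors truly contribute: no removal is favoured
        n = 400
        X = rng.normal(size=(n, 2))
        y = X @ np.array([1.0, -0.8]) + rng.normal(0, 0.5, n)
        post, prior = self._regression_posterior(X, y, 0.25, 1.0)
        cands = {f"drop_{j}": _pin_candidate(j) for j in range(2)}
        sel = structure_select(prior, post, cands)
        assert sel.accepted == ()
        assert sel.total_delta == 0.0
        np.testing.assert_array_equal(sel.posterior.mean, post.mean)

    def test_planted_irrelevant_component_is_pruned(self, rng):
        # true coefficient of regressor 1 is zero; with plenty of data its
        # removal increases evidence while regressor 0 is retained
        n = 800
        X = rng.normal(size=(n, 2))
        y = X @ np.array([1.2, 0.0]) + rng.normal(0, 0.5, n)
        post, prior = self._regression_posterior(X, y, 0.25, 1.0)
        cands = {f"drop_{j}": _pin_candidate(j) for j in range(2)}
        sel = structure_select(prior, post, cands)
        assert sel.accepted == ("drop_1",)

    def test_greedy_deltas_sum_to_total_on_orthogonal_components(self, rng):
        # diagonal (orthogonal) posterior: the greedy path's deltas add up
        # to the joint reduction's evidence change
        k = 4
        prior = VariationalDensity(np.zeros(k), np.eye(k))
        post = VariationalDensity(np.array([0.05, 1.9, -0.02, 0.1]),
                                  np.diag([0.05, 0.05, 0.05, 0.05]))
        cands = {f"drop_{j}": _pin_candidate(j) for j in range(k)}
        sel = structure_select(prior, post, cands)
        joint_reduced = VariationalDensity(
            np.where([j in (0, 2, 3) for j in range(k)], 0.0, prior.mean),
            np.diag([1e-8 if j in (0, 2, 3) else 1.0 for j in range(k)]))
        joint_delta = bmr_delta_evidence(post, prior, joint_reduced)
        assert sel.accepted == ("drop_0", "drop_2", "drop_3")
        assert sel.total_delta == pytest.approx(joint_delta, abs=1e-6)
        assert sum(e["delta_evidence"] for e in sel.decision_log
                   if e["accepted"]) == pytest.approx(sel.total_delta)


def _pin_candidate(j):
    def _reduce(prior):
        var = np.diag(prior.cov).copy()
        var[j] = 1e-8
        mean = prior.mean.copy()
        mean[j] = 0.0
        return VariationalDensity(mean, np.diag(var))
    return _reduce
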