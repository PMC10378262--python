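"""The slow scale: variational fitness, Langevin selection, model reduction.

An agent's *genotype* — flow parameters plus initial states — defines the
generative model its phenotype uses during a lifetime of active inference.
The path integral of variational free energy over that lifetime (the
*action*) scores how well the phenotype kept to the path of least action,
and is read as negative adaptive fitness: the accumulated negative log
evidence for the genotype's model of its niche.

Selection is then stochastic gradient Langevin dynamics on the action,

    theta <- theta + (Q_slow - Gamma_slow) grad A(theta) dt + omega,
    var(omega) = 2 Gamma_slow dt,

whose stationary density is proportional to exp(-A(theta)): long-run
evolution samples the Gibbs density of negative fitness, which is what
makes natural selection a form of Bayesian model selection.  Discrete
structure choices (keep or remove a component) are handled separately by
Gaussian Bayesian model reduction: the evidence of a model with a modified
prior is computed directly from the full model's posterior, without
refitting.

The module runs a four-step protocol per generation: sample genotypes,
filter each phenotype through its lifetime, integrate free energy into an
action, and update genotypes by the slow Langevin flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .filtering import (GenerativeModel, VariationalDensity,
                        action_from_lagrangians, active_inference_step)

_LOG2PI = float(np.log(2.0 * np.pi))


def _subseed(base: int, *keys: int) -> int:
    """Deterministic child seed below 2**31."""
    state = np.random.SeedSequence([int(base)] + [int(k) for k in keys])
    return int(state.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# genotypes and fitness records


@dataclass
class Genotype:
    """Parameters and initial states defining a kind; the unit of selection."""

    theta: np.ndarray
    x0: np.ndarray | None = None
    structure_mask: np.ndarray | None = None
    gid: int = 0

    def __post_init__(self):
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("genotype parameters must be finite")
        if self.x0 is not None:
            self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        if self.structure_mask is not None:
            self.structure_mask = np.asarray(self.structure_mask, dtype=bool)


@dataclass
class FitnessRecord:
    """Action (negative fitness) of one phenotypic lifetime."""

    gid: int
    generation: int
    A: float
    F_trace: np.ndarray = field(repr=False)
    lifetime: float = 0.0
    dt: float = 0.0
    seed: int = 0
    diagnostic: str = ""

    def validate(self, tol: float = 1e-10) -> "FitnessRecord":
        if np.isfinite(self.A):
            expected = action_from_lagrangians(self.F_trace, self.dt)
            if abs(expected - self.A) > tol * max(1.0, abs(self.A)):
                raise AssertionError(
                    f"A = {self.A!r} disagrees with its trace integral {expected!r}")
        return self


# ---------------------------------------------------------------------------
# environments (fitness functionals)


class Environment(Protocol):
    """Anything that can score a genotype's lifetime."""

    def evaluate(self, theta: np.ndarray, T: float, seed: int) -> "LifetimeResult":
        ...


@dataclass
class LifetimeResult:
    A: float
    F_trace: np.ndarray
    dt: float
    extras: dict = field(default_factory=dict)


@dataclass
class QuadraticStubEnvironment:
    """Analytic fitness landscape A(theta) = 1/2 (theta - theta*)' W (theta - theta*).

    A deterministic stub with a known optimum and a known Gibbs density
    exp(-A): the oracle for every stationary-distribution claim about the
    slow dynamics.
    """

    theta_star: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.theta_star = np.atleast_1d(np.asarray(self.theta_star, dtype=float))
        if self.weights is None:
            self.weights = np.ones_like(self.theta_star)
        else:
            self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))

    def action_value(self, theta: np.ndarray) -> float:
        d = np.atleast_1d(theta) - self.theta_star
        return 0.5 * float(np.sum(self.weights * d * d))

    def evaluate(self, theta, T: float = 1.0, seed: int = 0) -> LifetimeResult:
        if T <= 0:
            return LifetimeResult(A=0.0, F_trace=np.empty(0), dt=1.0)
        A = self.action_value(theta)
        # constant-Lagrangian trace whose trapezoidal integral recovers A
        return LifetimeResult(A=A, F_trace=np.array([A / T, A / T]), dt=T)


@dataclass
class FilteringEnvironment:
    """A linear-Gaussian niche scored by accumulated log evidence.

    The external state is a scalar Ornstein-Uhlenbeck process relaxing to
    ``m_env`` at rate ``a_env`` with fluctuation amplitude ``gamma_env``;
    sensation adds white noise of variance ``obs_noise_var`` per sample.
    The phenotype's generative model takes theta[0] as its prior mean over
    the external state with prior variance ``prior_var``; per-step inference
    is the exact conjugate update, so the instantaneous free energy equals
    the negative log evidence -ln N(s_t; theta, prior_var + obs_noise_var)
    and the action has a closed-form theta-gradient (used as a test oracle).

    Fitness is minimised when the prior mean matches the niche mean: a
    genotype whose prior equals the environment's NESS is the fittest kind.
    """

    m_env: float = 0.0
    a_env: float = 1.0
    gamma_env: float = 0.5
    obs_noise_var: float = 0.5
    prior_var: float = 1.0
    dt: float = 0.1

    def _sensory_path(self, n: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        phi = 1.0 - self.a_env * self.dt
        w = rng.normal(0.0, np.sqrt(2.0 * self.gamma_env * self.dt), n)
        drive = w + self.a_env * self.dt * self.m_env
        eta = lfilter([1.0], [1.0, -phi], drive, zi=[phi * self.m_env])[0]
        return eta + rng.normal(0.0, np.sqrt(self.obs_noise_var), n)

    def evaluate(self, theta, T: float, seed: int) -> LifetimeResult:
        theta0 = float(np.atleast_1d(theta)[0])
        n = int(round(T / self.dt))
        if n < 1:
            return LifetimeResult(A=0.0, F_trace=np.empty(0), dt=self.dt)
        s = self._sensory_path(n, seed)
        ev_var = self.prior_var + self.obs_noise_var
        F = 0.5 * (_LOG2PI + np.log(ev_var)) + (s - theta0) ** 2 / (2.0 * ev_var)
        A = action_from_lagrangians(F, self.dt)
        return LifetimeResult(A=A, F_trace=F, dt=self.dt, extras={"s": s})

    def closed_form_gradient(self, theta, T: float, seed: int) -> float:
        """d A / d theta for the same sensory realisation (test oracle)."""
        theta0 = float(np.atleast_1d(theta)[0])
        n = int(round(T / self.dt))
        s = self._sensory_path(n, seed)
        ev_var = self.prior_var + self.obs_noise_var
        g = (theta0 - s) / ev_var
        w = np.full(n, self.dt)
        w[0] = w[-1] = self.dt / 2.0
        return float(np.sum(w * g))

    def agent_model(self, theta) -> GenerativeModel:
        """The generative model the genotype encodes (for step-wise checks)."""
        theta0 = float(np.atleast_1d(theta)[0])
        return GenerativeModel(
            prior_mean=[theta0], prior_precision=[[1.0 / self.prior_var]],
            likelihood=[[1.0]], noise_precision=[[1.0 / self.obs_noise_var]])


@dataclass
class ThermostatEnvironment:
    """Closed-loop fixture: the agent's action drives the sensed variable.

    Environment:  eta' = -k_env (eta - eta_amb) + coupling * a  (+ noise),
    sensation s = eta + noise.  The agent holds a prior that the external
    state sits at theta[0]; active inference moves ``a`` until the sensed
    value matches the prior mean — the coupled linear system's fixed point
    has s = mu = theta (homeostasis at the genetically specified set point).
    """

    k_env: float = 1.0
    eta_amb: float = 0.0
    coupling: float = 1.0
    env_noise: float = 0.0
    obs_noise: float = 0.0
    prior_prec: float = 1.0
    obs_prec: float = 4.0
    kappa: float = 1.0
    dt: float = 0.01

    def evaluate(self, theta, T: float, seed: int) -> LifetimeResult:
        theta0 = float(np.atleast_1d(theta)[0])
        n = int(round(T / self.dt))
        if n < 1:
            return LifetimeResult(A=0.0, F_trace=np.empty(0), dt=self.dt)
        model = GenerativeModel(
            prior_mean=[theta0], prior_precision=[[self.prior_prec]],
            likelihood=[[1.0]], noise_precision=[[self.obs_prec]])
        rng = np.random.default_rng(seed)
        eta = self.eta_amb
        mu = np.array([theta0])
        a = np.array([0.0])
        F = np.empty(n)
        etas = np.empty(n)
        sens = self.coupling * np.ones((1, 1))   # reflex sensitivity ds/da
        for t in range(n):
            s = eta + (rng.normal(0.0, np.sqrt(self.obs_noise))
                       if self.obs_noise > 0 else 0.0)
            mu, a, report = active_inference_step(
                model, mu, a, np.array([s]), self.dt, kappa=self.kappa,
                action_sensitivity=sens)
            drift = -self.k_env * (eta - self.eta_amb) + self.coupling * a[0]
            eta = eta + self.dt * drift + (
                rng.normal(0.0, np.sqrt(2.0 * self.env_noise * self.dt))
                if self.env_noise > 0 else 0.0)
            F[t] = report.F
            etas[t] = eta
        A = action_from_lagrangians(F, self.dt)
        return LifetimeResult(A=A, F_trace=F, dt=self.dt,
                              extras={"eta": etas, "mu": float(mu[0]),
                                      "a": float(a[0])})


# ---------------------------------------------------------------------------
# variational fitness and its gradient


def variational_fitness(genotype: Genotype, environment: Environment,
                        T: float, seed: int, *,
                        generation: int = 0) -> FitnessRecord:
    """Score one lifetime: run the phenotype, integrate F, return the action.

    Simulation failures (numerical divergence) are not fatal: the lifetime
    is scored as infinite action with a diagnostic — the phenotype strayed
    from the path.
    """
    try:
        res = environment.evaluate(genotype.theta, T, seed)
        return FitnessRecord(gid=genotype.gid, generation=generation,
                             A=res.A, F_trace=res.F_trace, lifetime=T,
                             dt=res.dt, seed=seed).validate()
    except (FloatingPointError, OverflowError, RuntimeError) as e:
        return FitnessRecord(gid=genotype.gid, generation=generation,
                             A=np.inf, F_trace=np.empty(0), lifetime=T,
                             dt=0.0, seed=seed, diagnostic=str(e))


def fitness_gradient(genotype: Genotype, environment: Environment, T: float,
                     *, estimator: str = "crn-fd", h: float = 1e-3,
                     seed: int = 0) -> np.ndarray:
    """Estimate grad_theta A by central finite differences.

    ``crn-fd`` (default) evaluates theta +/- h with common random numbers —
    the same fast-scale seed on both sides — cancelling the shared
    stochasticity of the lifetime; ``fd`` draws fresh seeds per side.
    The step is relative: h_i = h * max(1, |theta_i|).
    """
    if estimator not in ("crn-fd", "fd"):
        raise ValueError(f"unknown estimator {estimator!r}")
    theta = genotype.theta
    grad = np.empty_like(theta)
    for i in range(theta.size):
        hi = h * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += hi
        tm[i] -= hi
        if estimator == "crn-fd":
            sp = sm = seed
        else:
            sp, sm = _subseed(seed, i, 0), _subseed(seed, i, 1)
        Ap = environment.evaluate(tp, T, sp).A
        Am = environment.evaluate(tm, T, sm).A
        grad[i] = (Ap - Am) / (2.0 * hi)
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError(f"non-finite fitness gradient {grad}")
    return grad


# ---------------------------------------------------------------------------
# the evolve driver (the slow Langevin flow)


@dataclass
class SelectionConfig:
    """Slow-scale dynamics: M genotypes for a number of generations.

    Each generation applies theta <- theta + (Q_slow - Gamma_slow) grad A
    * dt_slow + noise with variance 2 Gamma_slow dt_slow.  Gamma_slow must
    be PSD and Q_slow antisymmetric (zero by default: the solenoidal term
    at the slow scale is optional).
    """

    population_size: int = 20
    generations: int = 100
    gamma_slow: np.ndarray = 0.01
    q_slow: np.ndarray | None = None
    dt_slow: float = 1.0
    lifetime: float = 10.0
    grad_h: float = 1e-3
    estimator: str = "crn-fd"
    seed: int = 0
    divergence_bound: float = 1e6

    def __post_init__(self):
        self.gamma_slow = np.atleast_2d(np.asarray(self.gamma_slow, dtype=float))
        if not np.allclose(self.gamma_slow, self.gamma_slow.T) or \
                np.linalg.eigvalsh(self.gamma_slow).min() < -1e-12:
            raise ValueError("gamma_slow must be symmetric PSD")
        if self.q_slow is not None:
            self.q_slow = np.atleast_2d(np.asarray(self.q_slow, dtype=float))
            if not np.allclose(self.q_slow, -self.q_slow.T):
                raise ValueError("q_slow must be antisymmetric")


@dataclass
class EvolveResult:
    """Generation-indexed genotype history and actions."""

    thetas: np.ndarray          # (generations + 1, M, p)
    actions: np.ndarray         # (generations, M) action before each update
    config: SelectionConfig

    @property
    def final_population(self) -> np.ndarray:
        return self.thetas[-1]

    def lineage_frame(self) -> pd.DataFrame:
        """Tidy lineage: generation, genotype id, parent id, theta, action."""
        G1, M, p = self.thetas.shape
        rows = []
        for g in range(G1):
            for i in range(M):
                row = {"generation": g, "gid": i,
                       "parent": i if g > 0 else -1}
                for c in range(p):
                    row[f"theta_{c}"] = self.thetas[g, i, c]
                row["A"] = self.actions[g - 1, i] if g > 0 else np.nan
                rows.append(row)
        return pd.DataFrame(rows)


def sample_population(M: int, prior_mean, prior_sd, seed: int) -> list[Genotype]:
    """Protocol step 1: sample genotypes from the initial density."""
    rng = np.random.default_rng(seed)
    mean = np.atleast_1d(np.asarray(prior_mean, dtype=float))
    sd = np.broadcast_to(np.asarray(prior_sd, dtype=float), mean.shape)
    return [Genotype(theta=rng.normal(mean, sd), gid=i) for i in range(M)]


def evolve(population: Sequence[Genotype], config: SelectionConfig,
           environment: Environment) -> EvolveResult:
    """Stochastic gradient Langevin selection over generations.

    Per generation and genotype: estimate grad A over a lifetime, apply the
    slow Helmholtz update with injected drift noise, and record the lineage.
    The same config seed reproduces the entire history bitwise.
    """
    M = len(population)
    if M != config.population_size:
        raise ValueError(f"population has {M} genotypes, config says "
                         f"{config.population_size}")
    p = population[0].theta.size
    Gm = np.broadcast_to(config.gamma_slow, (p, p))
    Qm = (np.zeros((p, p)) if config.q_slow is None
          else np.broadcast_to(config.q_slow, (p, p)))
    QG = Qm - Gm
    evals, evecs = np.linalg.eigh(Gm)
    noise_root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    noise_scale = np.sqrt(2.0 * config.dt_slow)
    rng = np.random.default_rng(_subseed(config.seed, 0xE0))

    thetas = np.empty((config.generations + 1, M, p))
    actions = np.empty((config.generations, M))
    thetas[0] = np.stack([g.theta for g in population])

    cur = [Genotype(theta=g.theta.copy(), gid=i)
           for i, g in enumerate(population)]
    for gen in range(config.generations):
        noise = rng.standard_normal((M, p)) @ (noise_scale * noise_root).T
        for i, g in enumerate(cur):
            seed_gi = _subseed(config.seed, gen, i)
            rec = variational_fitness(g, environment, config.lifetime,
                                      seed_gi, generation=gen)
            actions[gen, i] = rec.A
            if not np.isfinite(rec.A):
                # strayed from the path: resample around the population mean
                g.theta = thetas[gen].mean(axis=0).copy()
                continue
            grad = fitness_gradient(g, environment, config.lifetime,
                                    estimator=config.estimator,
                                    h=config.grad_h, seed=seed_gi)
            g.theta = g.theta + config.dt_slow * (QG @ grad) + noise[i]
            if np.abs(g.theta).max() > config.divergence_bound:
                raise FloatingPointError(
                    f"genotype {i} diverged at generation {gen}: {g.theta}")
        thetas[gen + 1] = np.stack([g.theta for g in cur])
    return EvolveResult(thetas=thetas, actions=actions, config=config)


# ---------------------------------------------------------------------------
# Bayesian model reduction


def bmr_delta_evidence(full_posterior: VariationalDensity,
                       full_prior: VariationalDensity,
                       reduced_prior: VariationalDensity) -> float:
    """Change in log evidence when the full prior is replaced by a reduced one.

    For Gaussians the reduced evidence follows from the full posterior
    alone:  with precisions P (posterior), P0 (prior), Pr (reduced prior),
    the reduced posterior has precision Pp = P + Pr - P0 and

      dF = 1/2 [ ln|Pr| - ln|P0| + ln|P| - ln|Pp| ]
         + 1/2 [ b' Pp^{-1} b - (m'Pm + mr'Pr mr - m0'P0 m0) ],
      b = P m + Pr mr - P0 m0.

    Positive values favour the reduction.  Equal priors give exactly zero.
    """
    m, m0, mr = full_posterior.mean, full_prior.mean, reduced_prior.mean
    if not (m.shape == m0.shape == mr.shape):
        raise ValueError("posterior and prior dimensions disagree")
    P = np.linalg.inv(full_posterior.cov)
    P0 = np.linalg.inv(full_prior.cov)
    Pr = np.linalg.inv(reduced_prior.cov)
    Pp = P + Pr - P0
    sign, logdet_Pp = np.linalg.slogdet(Pp)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            "reduced posterior precision is not positive definite")
    b = P @ m + Pr @ mr - P0 @ m0
    quad = float(b @ np.linalg.solve(Pp, b)
                 - m @ P @ m - mr @ Pr @ mr + m0 @ P0 @ m0)
    logdets = (np.linalg.slogdet(Pr)[1] - np.linalg.slogdet(P0)[1]
               + np.linalg.slogdet(P)[1] - logdet_Pp)
    return 0.5 * (logdets + quad)


def reduced_posterior(full_posterior: VariationalDensity,
                      full_prior: VariationalDensity,
                      reduced_prior: VariationalDensity) -> VariationalDensity:
    """Posterior under the reduced prior, from the full posterior alone."""
    P = np.linalg.inv(full_posterior.cov)
    P0 = np.linalg.inv(full_prior.cov)
    Pr = np.linalg.inv(reduced_prior.cov)
    Pp = P + Pr - P0
    cov = np.linalg.inv(Pp)
    mean = cov @ (P @ full_posterior.mean + Pr @ reduced_prior.mean
                  - P0 @ full_prior.mean)
    return VariationalDensity(mean, 0.5 * (cov + cov.T))


@dataclass
class StructureSelection:
    """Outcome of greedy structure selection."""

    prior: VariationalDensity
    posterior: VariationalDensity
    accepted: tuple[str, ...]
    decision_log: list[dict]
    total_delta: float


def structure_select(full_prior: VariationalDensity,
                     posterior: VariationalDensity,
                     candidates: dict[str, "VariationalDensity | object"]
                     ) -> StructureSelection:
    """Greedy Bayesian model reduction over enumerable candidates.

    Candidates are tried one at a time (in insertion order); a reduction is
    applied whenever it increases model evidence, updating the running prior
    and posterior.  Every decision is logged with its evidence change.

    A candidate is either an absolute reduced prior
    (:class:`VariationalDensity`) or a callable mapping the *current* prior
    to a reduced prior; callables compose cleanly under the greedy chain
    (earlier accepted reductions stay in force).
    """
    prior = full_prior
    post = posterior
    accepted: list[str] = []
    log: list[dict] = []
    total = 0.0
    for name, cand in candidates.items():
        red_prior = cand(prior) if callable(cand) else cand
        delta = bmr_delta_evidence(post, prior, red_prior)
        take = delta > 0.0
        log.append({"candidate": name, "delta_evidence": float(delta),
                    "accepted": bool(take)})
        if take:
            post = reduced_posterior(post, prior, red_prior)
            prior = red_prior
            accepted.append(name)
            total += delta
    return StructureSelection(prior=prior, posterior=post,
                              accepted=tuple(accepted), decision_log=log,
                              total_delta=total)
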