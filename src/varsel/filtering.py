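"""Generalised coordinates, least-action paths, and the free-energy stack.

This is the fast (phenotypic) scale.  A trajectory is represented locally by
*generalised coordinates of motion* — the state together with its velocity,
acceleration, ... up to a truncation order — on which a shift operator D
maps each order to the next.  The surprisal of a generalised state is the
*Lagrangian*; its path integral is the *action*, the negative log
probability of a path.  Paths of least action satisfy the stationarity
condition ``grad L = 0`` and are recovered here, for linear-Gaussian
models, by solving that condition exactly — the fixed point towards which
a gradient descent on the Lagrangian, in a moving frame of reference,
would converge.

The same machinery is then re-expressed as approximate Bayesian inference:
a Gaussian *variational density* over external states, and a variational
free energy F with its three classical decompositions

    F = energy - entropy = complexity - accuracy = divergence - log evidence,

so that F upper-bounds negative log evidence (the ELBO bound), with
equality exactly when the variational density equals the posterior.  For
the linear-Gaussian models used throughout, every term has a closed form
and the decompositions are computed independently rather than by
rearrangement, making the identities genuine cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .langevin import DimensionMismatch, HelmholtzFlow, PartitionSpec

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# generalised coordinates


@dataclass
class GeneralisedPath:
    """A state in generalised coordinates: values[k] is the k-th derivative.

    ``values`` has shape (order + 1, d).  The shift operator D moves each
    order up by one and zeroes the top order (truncation).
    """

    values: np.ndarray
    partition: PartitionSpec | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 2:
            raise ValueError("generalised order must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("generalised states contain non-finite entries")

    @property
    def order(self) -> int:
        return self.values.shape[0] - 1

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def state(self) -> np.ndarray:
        return self.values[0]


def shift(path: GeneralisedPath) -> GeneralisedPath:
    """Apply D: order-k block of the output is the order-(k+1) input block."""
    out = np.zeros_like(path.values)
    out[:-1] = path.values[1:]
    return GeneralisedPath(out, path.partition)


def generalised_fluctuation_covariance(order: int, roughness: float) -> np.ndarray:
    """Temporal covariance of generalised fluctuations with unit amplitude.

    Fluctuations are taken smooth with Gaussian autocorrelation
    ``rho(h) = exp(-h^2 / (2 sigma^2))`` where ``sigma`` is the roughness
    parameter (same time units as the trajectory).  Entry (i, j) is
    ``cov(w^(i), w^(j)) = (-1)^j rho^(i+j)(0)``; odd-order entries vanish.
    """
    if roughness <= 0:
        raise ValueError("roughness must be positive")
    n = order + 1
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            k2 = i + j
            if k2 % 2:
                continue
            k = k2 // 2
            dfact = 1.0
            for m in range(1, k2, 2):  # (k2 - 1)!!
                dfact *= m
            S[i, j] = (-1.0) ** j * (-1.0) ** k * dfact / roughness ** k2
    return S


def taylor_embed(samples: np.ndarray, order: int, dt: float,
                 index: int | None = None) -> GeneralisedPath:
    """Embed discrete samples into generalised coordinates at one time point.

    Fits a Taylor polynomial of degree ``order`` through the 2*order + 1
    samples centred on ``index`` (default: the middle sample) and reads off
    the derivatives.  This is the standard linear map between a local window
    of a sampled signal and generalised coordinates of motion.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 1:
        samples = samples.T
    T = samples.shape[0]
    w = 2 * order + 1
    if T < w:
        raise ValueError(f"need at least {w} samples for order {order}")
    if index is None:
        index = T // 2
    lo = int(np.clip(index - order, 0, T - w))
    window = samples[lo: lo + w]
    offsets = (np.arange(lo, lo + w) - index) * dt
    # Vandermonde in the Taylor basis: sample = sum_k x^(k) t^k / k!
    B = np.column_stack([offsets ** k / float(math.factorial(k))
                         for k in range(order + 1)])
    coeffs, *_ = np.linalg.lstsq(B, window, rcond=None)
    return GeneralisedPath(coeffs)


# ---------------------------------------------------------------------------
# Lagrangian and action


def _generalised_residual(flow: HelmholtzFlow, path: GeneralisedPath) -> np.ndarray:
    """Residual r = D x - f(x) applied order-by-order (linear flow)."""
    J = flow.jacobian
    f_vals = path.values @ J.T
    r = np.zeros_like(path.values)
    r[:-1] = path.values[1:] - f_vals[:-1]
    r[-1] = -f_vals[-1]
    return r


def lagrangian(flow: HelmholtzFlow, path: GeneralisedPath, *,
               roughness: float | None = None,
               include_divergence: bool = True) -> float:
    """Surprisal of a generalised state.

    L = 1/2 [ ln|G| + r' (2 G)^{-1} r + div f ],   r = D x - f(x),

    where G is the covariance of generalised fluctuations: the flow's Gamma
    replicated across orders, temporally correlated according to
    ``roughness`` when given (white across orders otherwise).  The
    divergence correction ``div f = tr J`` reflects the change of measure
    from fluctuations to states; ``include_divergence=False`` drops it.
    """
    if not flow.is_quadratic:
        raise NotImplementedError("Lagrangian implemented for linear flows")
    Gamma = flow.Gamma
    sign, logdet_g = np.linalg.slogdet(Gamma)
    if sign <= 0:
        raise np.linalg.LinAlgError("Gamma is singular")
    n1 = path.order + 1
    r = _generalised_residual(flow, path)
    if roughness is None:
        S = np.eye(n1)
        logdet_S = 0.0
    else:
        S = generalised_fluctuation_covariance(path.order, roughness)
        sS, logdet_S = np.linalg.slogdet(S)
        if sS <= 0:
            raise np.linalg.LinAlgError("generalised temporal covariance singular")
    # quadratic form r' (2 S x Gamma)^{-1} r with r laid out orders x states
    A = np.linalg.solve(S, r)          # (n1, d)
    B = np.linalg.solve(Gamma, r.T)    # (d, n1)
    quad = 0.5 * float(np.sum(A * B.T))
    logdet = n1 * logdet_g + path.d * logdet_S
    div = float(np.trace(flow.jacobian)) if include_divergence else 0.0
    return 0.5 * (logdet + quad + div)


def action(flow: HelmholtzFlow, paths: Sequence[GeneralisedPath], dt: float,
           **kwargs) -> float:
    """Path integral of the Lagrangian: trapezoidal rule over a sequence."""
    if len(paths) == 0:
        return 0.0
    L = np.array([lagrangian(flow, p, **kwargs) for p in paths])
    if L.size == 1:
        return 0.0
    return float(np.trapezoid(L, dx=dt))


def action_from_lagrangians(L: np.ndarray, dt: float) -> float:
    """Trapezoidal integral of a precomputed Lagrangian (or F) trace."""
    L = np.asarray(L, dtype=float)
    if L.size < 2:
        return 0.0
    return float(np.trapezoid(L, dx=dt))


# ---------------------------------------------------------------------------
# generative models


def _as_matrix(x, name: str) -> np.ndarray:
    M = np.atleast_2d(np.asarray(x, dtype=float))
    if M.shape[0] != M.shape[1]:
        raise DimensionMismatch(f"{name} must be square, got {M.shape}")
    return M


def _check_spd(M: np.ndarray, name: str) -> None:
    if not np.allclose(M, M.T):
        raise ValueError(f"{name} is not symmetric")
    if np.linalg.eigvalsh(M).min() <= 0:
        raise ValueError(f"{name} is not positive definite")


@dataclass
class GenerativeModel:
    """A linear-Gaussian generative model encoded by an extended genotype.

    The genotype packs the parameters theta — prior over external states,
    likelihood mapping, sensory noise precision, fluctuation roughness —
    together with initial states x0 (which include the initial external
    states: the epigenetic part of the specification).

    Externals:   eta ~ N(prior_mean, prior_precision^{-1}); optionally with
                 linear dynamics  d eta = drift (eta - prior_mean) dt + w,
                 var(w) = 2 * fluct_amplitude * dt.
    Sensation:   s = likelihood @ eta + v,  precision(v) = noise_precision.
    """

    prior_mean: np.ndarray
    prior_precision: np.ndarray
    likelihood: np.ndarray
    noise_precision: np.ndarray
    drift: np.ndarray | None = None
    fluct_amplitude: np.ndarray | None = None
    roughness: float = 0.5
    order: int = 3
    x0: np.ndarray | None = None

    def __post_init__(self):
        self.prior_mean = np.atleast_1d(np.asarray(self.prior_mean, dtype=float))
        self.prior_precision = _as_matrix(self.prior_precision, "prior_precision")
        self.likelihood = np.atleast_2d(np.asarray(self.likelihood, dtype=float))
        self.noise_precision = _as_matrix(self.noise_precision, "noise_precision")
        k = self.prior_mean.shape[0]
        if self.prior_precision.shape != (k, k):
            raise DimensionMismatch("prior_precision does not match prior_mean")
        if self.likelihood.shape[1] != k:
            raise DimensionMismatch("likelihood mapping does not match externals")
        m = self.likelihood.shape[0]
        if self.noise_precision.shape != (m, m):
            raise DimensionMismatch("noise_precision does not match likelihood rows")
        _check_spd(self.prior_precision, "prior_precision")
        _check_spd(self.noise_precision, "noise_precision")
        if self.drift is not None:
            self.drift = _as_matrix(self.drift, "drift")
            if self.drift.shape != (k, k):
                raise DimensionMismatch("drift does not match externals")
            self.fluct_amplitude = _as_matrix(self.fluct_amplitude, "fluct_amplitude")
        if self.x0 is None:
            self.x0 = self.prior_mean.copy()
        else:
            self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
            if self.x0.shape[0] != k:
                raise DimensionMismatch("x0 must include every external state")

    @property
    def k(self) -> int:
        return self.prior_mean.shape[0]

    @property
    def m(self) -> int:
        return self.likelihood.shape[0]


@dataclass
class VariationalDensity:
    """Gaussian belief over (generalised) external states."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = _as_matrix(self.cov, "cov")
        if self.cov.shape[0] != self.mean.shape[0]:
            raise DimensionMismatch("mean and cov disagree")
        _check_spd(self.cov, "cov")


@dataclass
class FreeEnergyReport:
    """F with its three decompositions, all in nats.

    F = energy - entropy = complexity - accuracy = divergence - log_evidence,
    each side computed independently; ``validate`` enforces the identities
    and the ELBO bound (divergence >= 0, so F >= -log_evidence).
    """

    F: float
    energy: float
    entropy: float
    complexity: float
    accuracy: float
    divergence: float
    log_evidence: float

    def validate(self, tol: float = 1e-8) -> "FreeEnergyReport":
        checks = {
            "energy - entropy": self.energy - self.entropy,
            "complexity - accuracy": self.complexity - self.accuracy,
            "divergence - log_evidence": self.divergence - self.log_evidence,
        }
        for name, val in checks.items():
            if abs(val - self.F) > tol * max(1.0, abs(self.F)):
                raise AssertionError(
                    f"decomposition {name} = {val:.12g} disagrees with "
                    f"F = {self.F:.12g}")
        if self.divergence < -tol:
            raise AssertionError(f"divergence {self.divergence:.3e} < 0")
        return self


def _gauss_kl(m1, S1, m0, S0) -> float:
    """KL( N(m1, S1) || N(m0, S0) )."""
    k = m1.shape[0]
    S0_inv_S1 = np.linalg.solve(S0, S1)
    dm = m1 - m0
    quad = float(dm @ np.linalg.solve(S0, dm))
    sign, logdet = np.linalg.slogdet(S0_inv_S1)
    return 0.5 * (np.trace(S0_inv_S1) + quad - k - logdet)


def _gauss_logpdf(x, m, S) -> float:
    k = m.shape[0]
    dm = x - m
    sign, logdet = np.linalg.slogdet(S)
    return -0.5 * (k * _LOG2PI + logdet + float(dm @ np.linalg.solve(S, dm)))


def variational_density(model: GenerativeModel, s: np.ndarray) -> VariationalDensity:
    """Exact Gaussian posterior over external states given sensory data.

    Conjugate update: posterior precision P = P0 + G' Ps G, posterior mean
    P^{-1} (P0 m0 + G' Ps s).  With infinite sensory noise (zero precision)
    the posterior reduces to the prior.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if s.shape[0] != model.m:
        raise DimensionMismatch("sensory data does not match likelihood rows")
    G, Ps, P0 = model.likelihood, model.noise_precision, model.prior_precision
    P = P0 + G.T @ Ps @ G
    try:
        cov = np.linalg.inv(P)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("posterior precision is singular") from e
    mean = cov @ (P0 @ model.prior_mean + G.T @ Ps @ s)
    return VariationalDensity(mean, 0.5 * (cov + cov.T))


def free_energy(model: GenerativeModel, q: VariationalDensity,
                s: np.ndarray) -> FreeEnergyReport:
    """Variational free energy of belief q given sensory data s.

    Every decomposition term is computed from its own closed form:
      energy      = E_q[-ln p(eta, s)]
      entropy     = -E_q[ln q]                    (Gaussian entropy)
      complexity  = KL(q || prior)
      accuracy    = E_q[ln p(s | eta)]
      divergence  = KL(q || posterior)
      log_evidence= ln p(s)                        (Gaussian marginal)
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if s.shape[0] != model.m:
        raise DimensionMismatch("sensory data does not match likelihood rows")
    if q.mean.shape[0] != model.k:
        raise DimensionMismatch("variational density does not match externals")
    G, Ps, P0, m0 = (model.likelihood, model.noise_precision,
                     model.prior_precision, model.prior_mean)
    m, S = q.mean, q.cov
    k, mdim = model.k, model.m

    R = np.linalg.inv(Ps)            # sensory noise covariance
    S0 = np.linalg.inv(P0)           # prior covariance

    # E_q[ln p(s | eta)]
    resid = s - G @ m
    accuracy = -0.5 * (mdim * _LOG2PI - np.linalg.slogdet(Ps)[1]
                       + float(resid @ Ps @ resid)
                       + float(np.trace(Ps @ G @ S @ G.T)))
    # E_q[-ln p(eta)]
    dm = m - m0
    cross_energy = 0.5 * (k * _LOG2PI - np.linalg.slogdet(P0)[1]
                          + float(dm @ P0 @ dm) + float(np.trace(P0 @ S)))
    energy = -accuracy + cross_energy
    entropy = 0.5 * (k * (_LOG2PI + 1.0) + np.linalg.slogdet(S)[1])
    complexity = _gauss_kl(m, S, m0, S0)

    post = variational_density(model, s)
    divergence = _gauss_kl(m, S, post.mean, post.cov)
    log_evidence = _gauss_logpdf(s, G @ m0, R + G @ S0 @ G.T)

    return FreeEnergyReport(
        F=energy - entropy,
        energy=energy, entropy=entropy,
        complexity=complexity, accuracy=accuracy,
        divergence=divergence, log_evidence=log_evidence,
    ).validate()


# ---------------------------------------------------------------------------
# paths of least action / generalised filtering


@dataclass
class LeastActionResult:
    """Converged least-action path and its optimality diagnostics."""

    paths: list[GeneralisedPath] = field(repr=False)
    mean_path: np.ndarray = field(repr=False)   # (T, k) posterior-mode states
    gradient_norm: float = 0.0
    dt: float = 0.0


def _discrete_system(model: GenerativeModel, dt: float, T_steps: int):
    """Euler discretisation of the model's external dynamics."""
    k = model.k
    if model.drift is None:
        raise ValueError("least-action path needs a model with external dynamics")
    A = np.eye(k) + dt * model.drift
    Pw = np.linalg.inv(2.0 * model.fluct_amplitude * dt)
    c = -dt * (model.drift @ model.prior_mean)   # so that eta* = prior_mean
    return A, c, Pw


def least_action_path(model: GenerativeModel, sensory: np.ndarray, dt: float,
                      *, x0: np.ndarray | None = None,
                      tol: float = 1e-6) -> LeastActionResult:
    """Recover the path of least action given a sensory path.

    Minimises the discretised action — the path integral of the Lagrangian
    of the joint (external dynamics + sensory mapping) model — over the
    whole external trajectory.  The objective is a convex quadratic for
    linear-Gaussian models, so the stationarity condition grad L = 0 (the
    fixed point towards which the moving-frame gradient descent
    ``x' = Dx - kappa grad L`` converges) is solved exactly with one sparse
    Newton step; the terminal gradient norm is reported.

    For the same Euler discretisation, the recovered path equals the
    posterior mode — hence, in the Gaussian case, the posterior mean of a
    discrete Kalman smoother run on the same data.
    """
    sensory = np.atleast_1d(np.asarray(sensory, dtype=float))
    if sensory.ndim == 1:
        sensory = sensory[:, None]
    T = sensory.shape[0]
    if sensory.shape[1] != model.m:
        raise DimensionMismatch("sensory path does not match likelihood rows")
    k = model.k
    A, c, Pw = _discrete_system(model, dt, T)
    G, Ps = model.likelihood, model.noise_precision
    P0 = model.prior_precision
    m0 = model.prior_mean if x0 is None else np.asarray(x0, dtype=float)

    # negative log posterior of the path: 1/2 x' H x - b' x + const,
    # block-tridiagonal H assembled sparsely
    GtPsG = G.T @ Ps @ G
    AtPwA = A.T @ Pw @ A
    off = -(A.T @ Pw)
    diag_blocks = []
    b = np.zeros((T, k))
    for t in range(T):
        D = GtPsG.copy()
        if t == 0:
            D += P0
            b[0] += P0 @ m0
        if t > 0:
            D += Pw
            b[t] += Pw @ c
        if t < T - 1:
            D += AtPwA
            b[t] -= A.T @ (Pw @ c)
        b[t] += G.T @ Ps @ sensory[t]
        diag_blocks.append(D)

    H = sparse.lil_matrix((T * k, T * k))
    for t in range(T):
        H[t * k:(t + 1) * k, t * k:(t + 1) * k] = diag_blocks[t]
        if t < T - 1:
            H[(t + 1) * k:(t + 2) * k, t * k:(t + 1) * k] = off.T
            H[t * k:(t + 1) * k, (t + 1) * k:(t + 2) * k] = off
    H = H.tocsr()
    x = spsolve(H, b.ravel())
    grad = H @ x - b.ravel()
    gnorm = float(np.linalg.norm(grad))
    if gnorm > tol:
        raise RuntimeError(
            f"least-action solve did not converge: |grad| = {gnorm:.3e} > {tol:g}")

    mean_path = x.reshape(T, k)
    # express the result in generalised coordinates (state + velocity)
    vel = np.gradient(mean_path, dt, axis=0)
    paths = [GeneralisedPath(np.stack([mean_path[t], vel[t]])) for t in range(T)]
    return LeastActionResult(paths=paths, mean_path=mean_path,
                             gradient_norm=gnorm, dt=dt)


# ---------------------------------------------------------------------------
# active inference (closed loop)


def active_inference_step(model: GenerativeModel, mu: np.ndarray, a: np.ndarray,
                          s: np.ndarray, dt: float, *, kappa: float = 1.0,
                          action_sensitivity: np.ndarray | None = None,
                          belief_cov: np.ndarray | None = None):
    """One Euler step of autonomous dynamics alpha' = D alpha - grad F.

    Internal states (the belief mean ``mu``) perform perception — gradient
    descent on F with respect to the belief.  Active states ``a`` perform
    action — descent of F through the sensory channel, using the supplied
    reflex sensitivity ds/da (identity by default).  At a free-energy
    minimum both gradients vanish and the step reduces to the pure shift.

    Returns ``(mu_new, a_new, report)`` where ``report`` is the
    :class:`FreeEnergyReport` evaluated *before* the step.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    a = np.atleast_1d(np.asarray(a, dtype=float))
    s = np.atleast_1d(np.asarray(s, dtype=float))
    G, Ps, P0, m0 = (model.likelihood, model.noise_precision,
                     model.prior_precision, model.prior_mean)
    if belief_cov is None:
        belief_cov = np.linalg.inv(P0 + G.T @ Ps @ G)
    q = VariationalDensity(mu, belief_cov)
    report = free_energy(model, q, s)

    # dF/dmu: only energy depends on the mean (Laplace, fixed covariance)
    dF_dmu = P0 @ (mu - m0) - G.T @ Ps @ (s - G @ mu)
    # dF/da = (ds/da)' dF/ds, with dF/ds the sensory prediction error
    dF_ds = Ps @ (s - G @ mu)
    sens = (np.eye(len(a), model.m) if action_sensitivity is None
            else np.atleast_2d(np.asarray(action_sensitivity, dtype=float)))
    dF_da = sens @ dF_ds

    mu_new = mu - dt * kappa * dF_dmu
    a_new = a - dt * kappa * dF_da
    return mu_new, a_new, report
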