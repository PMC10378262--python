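"""Sparse-coupled Langevin dynamics with particular partitions.

A *particular partition* splits a state vector into external (eta), sensory
(s), active (a) and internal (mu) roles.  The sensory and active states form
the *blanket* b = (s, a); blanket plus internal states form the *particular*
states pi = (b, mu); active plus internal states are *autonomous* alpha =
(a, mu).  Coupling between roles is sparse: external states never drive
internal states directly, and vice versa — all influence is mediated by the
blanket.

The drift of every flow here is a Helmholtz decomposition

    f(x) = (Q - Gamma) grad I(x),

with ``I(x) = -ln p(x)`` the surprisal (self-information) of the
nonequilibrium steady-state (NESS) density ``p``, ``Gamma`` the (symmetric
PSD) amplitude of random fluctuations — the dissipative, gradient part — and
``Q`` an antisymmetric solenoidal operator that circulates probability on
the isocontours of ``I`` without changing the stationary density.

The tractable default is a quadratic potential ``I(x) = x' Pi x / 2`` with
SPD precision ``Pi``, for which the NESS density is Gaussian with covariance
``Pi^{-1}`` and every stationarity and conditional-independence claim is
analytically checkable.  A callable-potential variant supports nonlinear
demos without those guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np



class DimensionMismatch(ValueError):
    """Matrix or vector dimensions disagree with the declared state size."""


class PartitionViolation(ValueError):
    """Drift couples roles that a particular partition forbids."""


class NotAntisymmetric(ValueError):
    """Q fails Q = -Q' ."""


class NotPSD(ValueError):
    """A matrix required to be (semi)definite is not."""


class UnstableFlow(ValueError):
    """The drift Jacobian has an eigenvalue with non-negative real part."""


class DivergenceError(RuntimeError):
    """A simulated trajectory left the configured bounding sphere."""


_ROLES = ("eta", "s", "a", "mu")

#: role -> roles it may be driven by, the dependency pattern of the flow:
#: eta' = f(eta, s, a);  s' = f(eta, s, a);  a' = f(s, a, mu);  mu' = f(s, a, mu)
_ALLOWED_SOURCES = {
    "eta": ("eta", "s", "a"),
    "s": ("eta", "s", "a"),
    "a": ("s", "a", "mu"),
    "mu": ("s", "a", "mu"),
}


@dataclass(frozen=True)
class PartitionSpec:
    """Index sets assigning each of ``d`` states to a partition role.

    Derived sets (blanket ``b``, particular ``pi``, autonomous ``alpha``)
    are computed on demand so they can never be stored inconsistently.
    """

    eta_idx: tuple[int, ...]
    s_idx: tuple[int, ...]
    a_idx: tuple[int, ...]
    mu_idx: tuple[int, ...]

    def __init__(self, eta_idx: Sequence[int], s_idx: Sequence[int],
                 a_idx: Sequence[int], mu_idx: Sequence[int]):
        object.__setattr__(self, "eta_idx", tuple(int(i) for i in eta_idx))
        object.__setattr__(self, "s_idx", tuple(int(i) for i in s_idx))
        object.__setattr__(self, "a_idx", tuple(int(i) for i in a_idx))
        object.__setattr__(self, "mu_idx", tuple(int(i) for i in mu_idx))
        self._validate()

    def _validate(self) -> None:
        all_idx = self.eta_idx + self.s_idx + self.a_idx + self.mu_idx
        if len(set(all_idx)) != len(all_idx):
            raise PartitionViolation("role index sets are not pairwise disjoint")
        d = self.d
        if set(all_idx) != set(range(d)):
            raise PartitionViolation(
                f"role indices {sorted(set(all_idx))} do not cover 0..{d - 1}")
        if not self.pi_idx:
            raise PartitionViolation(
                "particular states pi = (s, a, mu) are empty: a thing must "
                "have particular states")

    @property
    def d(self) -> int:
        return len(self.eta_idx) + len(self.s_idx) + len(self.a_idx) + len(self.mu_idx)

    @property
    def b_idx(self) -> tuple[int, ...]:
        """Blanket states b = (s, a)."""
        return self.s_idx + self.a_idx

    @property
    def pi_idx(self) -> tuple[int, ...]:
        """Particular states pi = (s, a, mu)."""
        return self.s_idx + self.a_idx + self.mu_idx

    @property
    def alpha_idx(self) -> tuple[int, ...]:
        """Autonomous states alpha = (a, mu)."""
        return self.a_idx + self.mu_idx

    def role_of(self, i: int) -> str:
        for role in _ROLES:
            if i in getattr(self, f"{role}_idx"):
                return role
        raise IndexError(f"state {i} outside 0..{self.d - 1}")

    def column_names(self) -> list[str]:
        """Role-tagged state names in state order, e.g. eta_0, s_0, mu_1."""
        names = [""] * self.d
        for role in _ROLES:
            for k, i in enumerate(getattr(self, f"{role}_idx")):
                names[i] = f"{role}_{k}"
        return names

    def to_dict(self) -> dict:
        return {f"{r}_idx": list(getattr(self, f"{r}_idx")) for r in _ROLES}

    @classmethod
    def from_dict(cls, spec: dict) -> "PartitionSpec":
        return cls(*(spec[f"{r}_idx"] for r in _ROLES))


def _check_square(name: str, M: np.ndarray, d: int) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (d, d):
        raise DimensionMismatch(f"{name} has shape {M.shape}, expected ({d}, {d})")
    if not np.all(np.isfinite(M)):
        raise ValueError(f"{name} contains non-finite entries")
    return M


@dataclass
class HelmholtzFlow:
    """A validated drift field ``f(x) = (Q - Gamma) grad I(x)``.

    With the quadratic default ``I(x) = x' Pi x / 2`` the drift is linear,
    ``f(x) = (Q - Gamma) Pi x``, and the NESS density is ``N(0, Pi^{-1})``.
    A general potential may be supplied as a callable together with its
    gradient; analytic NESS claims then no longer apply.
    """

    partition: PartitionSpec
    Pi: np.ndarray | None
    Q: np.ndarray
    Gamma: np.ndarray
    potential: Callable[[np.ndarray], float] | None = None
    grad_potential: Callable[[np.ndarray], np.ndarray] | None = None
    _J: np.ndarray | None = field(default=None, repr=False)

    @property
    def d(self) -> int:
        return self.partition.d

    @property
    def is_quadratic(self) -> bool:
        return self.grad_potential is None

    def grad_surprisal(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.is_quadratic:
            return self.Pi @ x
        return np.asarray(self.grad_potential(x), dtype=float)

    def surprisal(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if self.is_quadratic:
            return 0.5 * float(x @ self.Pi @ x)
        return float(self.potential(x))

    @property
    def jacobian(self) -> np.ndarray:
        """Drift Jacobian J = (Q - Gamma) Pi of the quadratic flow."""
        if not self.is_quadratic:
            raise ValueError("Jacobian only defined for the quadratic default")
        if self._J is None:
            self._J = (self.Q - self.Gamma) @ self.Pi
        return self._J

    def to_dict(self) -> dict:
        if not self.is_quadratic:
            raise ValueError("callable-potential flows are not serialisable")
        return {
            "partition": self.partition.to_dict(),
            "Pi": self.Pi.tolist(),
            "Q": self.Q.tolist(),
            "Gamma": self.Gamma.tolist(),
        }

    @classmethod
    def from_dict(cls, spec: dict) -> "HelmholtzFlow":
        return make_particular_flow(
            PartitionSpec.from_dict(spec["partition"]),
            np.asarray(spec["Pi"], dtype=float),
            np.asarray(spec["Q"], dtype=float),
            np.asarray(spec["Gamma"], dtype=float),
        )


@dataclass
class Trajectory:
    """A simulated path: strictly increasing times against a T x d state table."""

    times: np.ndarray
    states: np.ndarray
    seed: int | None
    dt: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[0] != self.times.shape[0]:
            raise DimensionMismatch("times and states disagree in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("states contain non-finite entries")

    @property
    def d(self) -> int:
        return self.states.shape[1]

    def __len__(self) -> int:
        return self.states.shape[0]

    def to_frame(self, partition: PartitionSpec | None = None):
        import pandas as pd

        cols = (partition.column_names() if partition is not None
                else [f"x_{i}" for i in range(self.d)])
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "time", self.times)
        return df


def make_particular_flow(partition: PartitionSpec, Pi: np.ndarray,
                         Q: np.ndarray, Gamma: np.ndarray,
                         *, atol: float = 1e-12) -> HelmholtzFlow:
    """Build and validate a quadratic-potential particular flow.

    Checks: Pi SPD, Q antisymmetric, Gamma symmetric PSD, and that the drift
    Jacobian J = (Q - Gamma) Pi respects the sparse-coupling pattern of a
    particular partition (no eta<->mu coupling; sensory states are not
    driven by internal states, active states are not driven by external
    ones).
    """
    d = partition.d
    Pi = _check_square("Pi", Pi, d)
    Q = _check_square("Q", Q, d)
    Gamma = _check_square("Gamma", Gamma, d)

    if not np.allclose(Q, -Q.T, atol=atol):
        raise NotAntisymmetric("Q != -Q'")
    if not np.allclose(Gamma, Gamma.T, atol=atol):
        raise NotPSD("Gamma is not symmetric")
    gamma_eigs = np.linalg.eigvalsh(Gamma)
    if gamma_eigs.min() < -1e-10:
        raise NotPSD(f"Gamma has negative eigenvalue {gamma_eigs.min():.3e}")
    if not np.allclose(Pi, Pi.T, atol=atol):
        raise NotPSD("Pi is not symmetric")
    pi_eigs = np.linalg.eigvalsh(Pi)
    if pi_eigs.min() <= 0:
        raise NotPSD(f"Pi is not positive definite (min eigenvalue {pi_eigs.min():.3e})")

    J = (Q - Gamma) @ Pi
    for target, sources in _ALLOWED_SOURCES.items():
        rows = getattr(partition, f"{target}_idx")
        if not rows:
            continue
        for src in _ROLES:
            if src in sources:
                continue
            cols = getattr(partition, f"{src}_idx")
            if not cols:
                continue
            block = J[np.ix_(rows, cols)]
            if np.abs(block).max() > 1e-10:
                raise PartitionViolation(
                    f"drift Jacobian block J[{target}, {src}] is nonzero "
                    f"(max |entry| = {np.abs(block).max():.3e}); {target} states "
                    f"may only depend on {sources}")

    flow = HelmholtzFlow(partition=partition, Pi=Pi, Q=Q, Gamma=Gamma)
    flow._J = J
    return flow


def make_potential_flow(partition: PartitionSpec,
                        potential: Callable[[np.ndarray], float],
                        grad_potential: Callable[[np.ndarray], np.ndarray],
                        Q: np.ndarray, Gamma: np.ndarray) -> HelmholtzFlow:
    """General-potential escape hatch: no sparsity or NESS validation."""
    d = partition.d
    Q = _check_square("Q", Q, d)
    Gamma = _check_square("Gamma", Gamma, d)
    if not np.allclose(Q, -Q.T):
        raise NotAntisymmetric("Q != -Q'")
    return HelmholtzFlow(partition=partition, Pi=None, Q=Q, Gamma=Gamma,
                         potential=potential, grad_potential=grad_potential)


def drift(flow: HelmholtzFlow, x: np.ndarray, *,
          decompose: bool = False):
    """Evaluate f(x) = (Q - Gamma) grad I(x).

    With ``decompose=True`` returns ``(f, gradient_part, solenoidal_part)``
    where the gradient (dissipative) part is ``-Gamma grad I`` and the
    solenoidal part ``Q grad I`` is orthogonal to ``grad I``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (flow.d,):
        raise DimensionMismatch(f"x has shape {x.shape}, expected ({flow.d},)")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite entries")
    g = flow.grad_surprisal(x)
    if not decompose:
        return (flow.Q - flow.Gamma) @ g
    grad_part = -flow.Gamma @ g
    sol_part = flow.Q @ g
    return grad_part + sol_part, grad_part, sol_part


def integrate_sde(flow: HelmholtzFlow, x0: np.ndarray, dt: float, T: float,
                  seed: int, *, divergence_bound: float = 1e6,
                  noise: bool = True,
                  rng: np.random.Generator | None = None) -> Trajectory:
    """Euler--Maruyama integration of dx = f(x) dt + dW, var(dW) = 2 Gamma dt.

    The same seed yields a bitwise-identical trajectory.  Aborts with
    :class:`DivergenceError` when ``|x|`` exceeds ``divergence_bound``.
    ``noise=False`` integrates the deterministic drift alone (the
    zero-fluctuation limit in which paths collapse onto the path of least
    action) while Gamma still shapes the drift.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T < dt:
        raise ValueError("T must be at least dt")
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (flow.d,):
        raise DimensionMismatch(f"x0 has shape {x0.shape}, expected ({flow.d},)")

    n_steps = int(round(T / dt))
    if rng is None:
        rng = np.random.default_rng(seed)

    # noise with covariance 2 Gamma dt per step, via a symmetric PSD root
    evals, evecs = np.linalg.eigh(flow.Gamma)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    if not noise:
        root = np.zeros_like(root)
    scale = np.sqrt(2.0 * dt)

    states = np.empty((n_steps + 1, flow.d))
    states[0] = x0
    x = x0.copy()
    if flow.is_quadratic:
        # one fused linear step: x <- A x + noise
        A = np.eye(flow.d) + dt * flow.jacobian
        noise = rng.standard_normal((n_steps, flow.d)) @ (scale * root).T
        for k in range(n_steps):
            x = A @ x + noise[k]
            states[k + 1] = x
            if not (np.abs(x).max() < divergence_bound):
                raise DivergenceError(
                    f"|x| exceeded {divergence_bound:g} at step {k + 1} "
                    f"(t = {(k + 1) * dt:g}); flow may be unstable or dt too large")
    else:
        for k in range(n_steps):
            x = x + dt * drift(flow, x) + scale * (root @ rng.standard_normal(flow.d))
            states[k + 1] = x
            if not (np.abs(x).max() < divergence_bound):
                raise DivergenceError(
                    f"|x| exceeded {divergence_bound:g} at step {k + 1} "
                    f"(t = {(k + 1) * dt:g})")

    times = dt * np.arange(n_steps + 1)
    return Trajectory(times=times, states=states, seed=seed, dt=dt)


def stationary_covariance(flow: HelmholtzFlow, *, tol: float = 1e-10) -> np.ndarray:
    """Analytic NESS covariance Pi^{-1} of a stable quadratic flow.

    Raises :class:`UnstableFlow` unless every eigenvalue of J = (Q - Gamma) Pi
    has negative real part, and verifies the Lyapunov stationarity relation
    J S + S J' + 2 Gamma = 0.
    """
    if not flow.is_quadratic:
        raise ValueError("stationary covariance requires the quadratic default")
    J = flow.jacobian
    eigs = np.linalg.eigvals(J)
    if eigs.real.max() >= 0:
        raise UnstableFlow(
            f"drift Jacobian eigenvalue with real part {eigs.real.max():.3e} >= 0")
    Sigma = np.linalg.inv(flow.Pi)
    residual = J @ Sigma + Sigma @ J.T + 2.0 * flow.Gamma
    if np.abs(residual).max() > tol * max(1.0, np.abs(Sigma).max()):
        raise AssertionError(
            f"Lyapunov residual {np.abs(residual).max():.3e} exceeds tolerance")
    return Sigma


# ---------------------------------------------------------------------------
# blanket (conditional-independence) diagnostics


@dataclass
class IndependenceReport:
    """eta--mu dependence given the blanket, analytic and empirical."""

    analytic_cond_cov: np.ndarray | None  # Sigma[eta, mu | b], None if nonlinear
    max_abs_analytic: float | None
    partial_correlation: np.ndarray       # sample eta-mu partial corr given b
    max_abs_partial_corr: float
    p_value: float                        # permutation p-value of the max |pc|
    n_samples: int
    independent: bool                     # analytic verdict when available


def analytic_conditional_cross_cov(flow: HelmholtzFlow) -> np.ndarray:
    """Sigma[eta, mu | b] of the Gaussian NESS by Schur complement.

    Conditioning N(0, Pi^{-1}) on the blanket leaves the (eta, mu) block with
    precision Pi[(eta,mu), (eta,mu)]; the conditional cross-covariance
    vanishes exactly when Pi has no eta--mu block.
    """
    p = flow.partition
    Sigma = np.linalg.inv(flow.Pi)
    em = list(p.eta_idx) + list(p.mu_idx)
    b = list(p.b_idx)
    if not b:
        cond = Sigma[np.ix_(em, em)]
    else:
        S_em = Sigma[np.ix_(em, em)]
        S_eb = Sigma[np.ix_(em, b)]
        S_bb = Sigma[np.ix_(b, b)]
        cond = S_em - S_eb @ np.linalg.solve(S_bb, S_eb.T)
    ne = len(p.eta_idx)
    return cond[:ne, ne:]


def check_blanket_independence(traj: Trajectory, partition: PartitionSpec,
                               *, flow: HelmholtzFlow | None = None,
                               min_samples: int = 50,
                               n_permutations: int = 200,
                               seed: int = 0) -> IndependenceReport:
    """Test conditional independence of eta and mu paths given the blanket.

    Empirically: regress the blanket out of the sampled eta and mu states and
    report the residual (partial) correlation with a permutation p-value.
    When a quadratic ``flow`` is supplied, also report the analytic
    conditional cross-covariance of the Gaussian NESS.
    """
    p = partition
    if not p.eta_idx or not p.mu_idx:
        raise ValueError("partition must have both external and internal states")
    X = traj.states
    if X.shape[0] < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {X.shape[0]}")

    eta = X[:, list(p.eta_idx)]
    mu = X[:, list(p.mu_idx)]
    b = X[:, list(p.b_idx)] if p.b_idx else np.empty((X.shape[0], 0))

    # residualise on the blanket (with intercept)
    Z = np.column_stack([np.ones(X.shape[0]), b])
    beta_e, *_ = np.linalg.lstsq(Z, eta, rcond=None)
    beta_m, *_ = np.linalg.lstsq(Z, mu, rcond=None)
    re = eta - Z @ beta_e
    rm = mu - Z @ beta_m

    def _xcorr(u, v):
        su = u.std(axis=0, ddof=1)
        sv = v.std(axis=0, ddof=1)
        su[su == 0] = 1.0
        sv[sv == 0] = 1.0
        c = (u - u.mean(0)).T @ (v - v.mean(0)) / (u.shape[0] - 1)
        return c / np.outer(su, sv)

    pc = _xcorr(re, rm)
    observed = np.abs(pc).max()

    # permutation null: break any eta-mu dependence, preserve marginals.
    # Samples along a trajectory are autocorrelated, so permute contiguous
    # blocks rather than single rows.
    rng = np.random.default_rng(seed)
    n = re.shape[0]
    block = max(1, n // 50)
    n_blocks = n // block
    exceed = 0
    trimmed_re = re[: n_blocks * block]
    trimmed_rm = rm[: n_blocks * block]
    blocks_rm = trimmed_rm.reshape(n_blocks, block, -1)
    for _ in range(n_permutations):
        perm = rng.permutation(n_blocks)
        rm_perm = blocks_rm[perm].reshape(n_blocks * block, -1)
        if np.abs(_xcorr(trimmed_re, rm_perm)).max() >= observed:
            exceed += 1
    p_value = (exceed + 1) / (n_permutations + 1)

    analytic = None
    max_analytic = None
    independent = bool(p_value > 0.01)
    if flow is not None and flow.is_quadratic:
        analytic = analytic_conditional_cross_cov(flow)
        max_analytic = float(np.abs(analytic).max())
        independent = max_analytic < 1e-8

    return IndependenceReport(
        analytic_cond_cov=analytic,
        max_abs_analytic=max_analytic,
        partial_correlation=pc,
        max_abs_partial_corr=float(observed),
        p_value=float(p_value),
        n_samples=n,
        independent=independent,
    )


def circulation_statistic(traj: Trajectory, i: int = 0, j: int = 1) -> tuple[float, float]:
    """Mean area-sweep rate in the (i, j) plane, with its standard error.

    Estimates the probability current: E[x_i dx_j - x_j dx_i] / dt vanishes
    under detailed balance (Q = 0) and is nonzero under solenoidal flow.
    Time reversal flips its sign.
    """
    x = traj.states[:, i]
    y = traj.states[:, j]
    incr = x[:-1] * np.diff(y) - y[:-1] * np.diff(x)
    rate = incr / traj.dt
    return float(rate.mean()), float(rate.std(ddof=1) / np.sqrt(rate.size))
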