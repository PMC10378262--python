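"""Synaptic selection demo: a neuron learns where its synapses belong.

A single cell is immersed in a neuropil of ``n_pools`` presynaptic pools
that fire in timed waves: pool k emits a Gaussian bump of activity at phase
k/n_pools of each wave, so the pools define a hidden temporal sequence.
The cell's dendrite carries ``n_segments x synapses_per_segment`` synapse
slots, each wired to one pool; its generative model predicts an *ordered
travelling wave* along the dendrite — slot j expects a bump at phase
j/n_slots.  Only when synapses are deployed in the right order along the
dendrite can the cell predict its input.

Two nested timescales of free-energy minimisation:

* Within a lifetime, each synapse optimises its sensitivity — a
  log-precision gating its channel's contribution to free energy — by
  gradient descent on F.  Synapses routed to the matching pool end up with
  high precision; mismatched ones are turned down.

* Across generations, each synapse's evidence is audited by Gaussian
  Bayesian model reduction on a per-channel gain (prior N(0, 1): the
  channel may or may not carry signal).  If removing the synapse (gain
  pinned to zero) increases model evidence, its postsynaptic specialisation
  is relocated to another pool chosen uniformly at random.  Over
  generations this selects the connectivity that fits the environment, and
  the lifetime action (negative fitness) falls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filtering import VariationalDensity, action_from_lagrangians
from .selection import _subseed, structure_select

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class DemoConfig:
    """Study conditions for the synaptic-selection demo.

    Defaults emulate the reference setup: a dendrite of five segments with
    four synapses each (20 slots, one presynaptic pool per slot), lifetimes
    of 120 arbitrary time units containing two waves of activation, and 64
    generations of selection.
    """

    n_segments: int = 5
    synapses_per_segment: int = 4
    lifetime: float = 120.0
    waves_per_lifetime: int = 2
    n_generations: int = 64
    noise: float = 0.1               # sensory noise s.d. (bump amplitude = 1)
    learning_rate: float = 2.0       # precision gradient-descent rate
    dt: float = 0.25
    log_prec_init: float = 0.0
    log_prec_bounds: tuple[float, float] = (-5.0, 5.0)
    log_prec_prior_var: float = 16.0  # weak prior keeping precisions finite
    gain_prior_var: float = 1.0
    reduced_gain_var: float = 1e-6   # "synapse removed" prior: gain pinned at 0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_segments", "synapses_per_segment", "waves_per_lifetime",
                     "n_generations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lifetime <= 0 or self.dt <= 0 or self.noise < 0:
            raise ValueError("lifetime and dt must be positive, noise >= 0")

    @property
    def n_slots(self) -> int:
        return self.n_segments * self.synapses_per_segment

    @property
    def n_pools(self) -> int:
        # one pool per slot: the hidden sequence spans the dendrite exactly
        return self.n_slots

    @property
    def wave_period(self) -> float:
        return self.lifetime / self.waves_per_lifetime

    @property
    def bump_width(self) -> float:
        """Bump s.d.: a quarter of the inter-pool spacing, so that adjacent
        pools are temporally resolvable (their bumps barely overlap)."""
        return self.wave_period / (4.0 * self.n_pools)


@dataclass(frozen=True)
class Connectivity:
    """Map from synapse slot (dendrite order) to presynaptic pool id."""

    assignment: tuple[int, ...]

    def __init__(self, assignment):
        object.__setattr__(self, "assignment",
                           tuple(int(p) for p in assignment))

    @classmethod
    def ground_truth(cls, config: DemoConfig) -> "Connectivity":
        """The ordered deployment: pool id increasing along the dendrite."""
        return cls(range(config.n_slots))

    @classmethod
    def random(cls, config: DemoConfig, seed: int) -> "Connectivity":
        rng = np.random.default_rng(seed)
        return cls(rng.integers(0, config.n_pools, size=config.n_slots))

    @property
    def n_slots(self) -> int:
        return len(self.assignment)

    def is_ground_truth(self) -> bool:
        return self.assignment == tuple(range(self.n_slots))

    def swapped(self, i: int, j: int) -> "Connectivity":
        a = list(self.assignment)
        a[i], a[j] = a[j], a[i]
        return Connectivity(a)

    def with_slot(self, slot: int, pool: int) -> "Connectivity":
        a = list(self.assignment)
        a[slot] = pool
        return Connectivity(a)


@dataclass
class PrecisionState:
    """Per-slot log precision (sensitivity), clipped to configured bounds."""

    log_precision: np.ndarray
    bounds: tuple[float, float] = (-5.0, 5.0)

    def __post_init__(self):
        self.log_precision = np.asarray(self.log_precision, dtype=float)
        if not np.all(np.isfinite(self.log_precision)):
            raise ValueError("log precisions must be finite")
        lo, hi = self.bounds
        self.log_precision = np.clip(self.log_precision, lo, hi)

    @classmethod
    def initial(cls, config: DemoConfig) -> "PrecisionState":
        return cls(np.full(config.n_slots, config.log_prec_init),
                   config.log_prec_bounds)


class SynapticEnvironment:
    """Deterministic-given-seed generator of pool firing time series."""

    def __init__(self, config: DemoConfig):
        self.config = config
        n = int(round(config.lifetime / config.dt))
        self.times = config.dt * np.arange(n)
        self.clean = self._pool_matrix()

    def _pool_matrix(self) -> np.ndarray:
        # periodic wave train: one wrapped Gaussian bump per wave period, so
        # every pool's curve is an exact time-translate and carries exactly
        # waves_per_lifetime bumps over the lifetime
        c = self.config
        P, w = c.wave_period, c.bump_width
        U = np.zeros((self.times.size, c.n_pools))
        for k in range(c.n_pools):
            centre = (k + 0.5) * P / c.n_pools   # phase k/n_pools of each wave
            wrapped = np.mod(self.times - centre + P / 2, P) - P / 2
            U[:, k] = np.exp(-0.5 * (wrapped / w) ** 2)
        return U

    def peak_times(self) -> np.ndarray:
        """First-wave peak time of each pool (strictly increasing)."""
        c = self.config
        return (np.arange(c.n_pools) + 0.5) * c.wave_period / c.n_pools

    def sensory(self, connectivity: Connectivity, seed: int) -> np.ndarray:
        """Pool activity routed to each slot, plus sensory noise: (T, slots)."""
        y = self.clean[:, list(connectivity.assignment)].copy()
        if self.config.noise > 0:
            rng = np.random.default_rng(seed)
            y += rng.normal(0.0, self.config.noise, size=y.shape)
        return y

    def predictions(self) -> np.ndarray:
        """The cell's predicted travelling wave: slot j expects pool j's bump."""
        return self.clean


def make_environment(config: DemoConfig) -> SynapticEnvironment:
    return SynapticEnvironment(config)


# ---------------------------------------------------------------------------
# fast scale: one lifetime


@dataclass
class LifetimeOutput:
    F_trace: np.ndarray
    action: float
    precisions: PrecisionState
    gain_posterior: VariationalDensity    # diagonal, one gain per slot
    gain_prior: VariationalDensity
    seed: int


def run_lifetime(connectivity: Connectivity, precisions: PrecisionState,
                 env: SynapticEnvironment, config: DemoConfig,
                 *, seed: int = 0) -> LifetimeOutput:
    """Simulate one cell lifetime: perception and precision learning.

    Per step the free energy of the sensory snapshot is

        F(t) = sum_j 1/2 [ ln 2 pi - lam_j + pi_j eps_j(t)^2 ]
             + sum_j (lam_j - lam_0)^2 / (2 v_lam),

    with eps_j = y_j - pred_j the prediction error of slot j, pi_j =
    exp(lam_j) its precision, and a weak Gaussian prior on log precisions.
    Log precisions follow a gradient flow on F (learning rate from config,
    clipped to bounds).  Matched channels accumulate precision; mismatched
    ones are muted, but their residual -lam penalty keeps the mismatch
    costly, so the action still ranks connectivities.

    Alongside, each slot's channel gain (y_j ~ g_j * pred_j + noise) gets a
    conjugate Gaussian posterior used later for model reduction.
    """
    y = env.sensory(connectivity, seed)
    pred = env.predictions()
    eps = y - pred
    eps2 = eps ** 2
    n_steps, n_slots = eps.shape

    lam = precisions.log_precision.copy()
    lo, hi = precisions.bounds
    lam0 = config.log_prec_init
    inv_vlam = 1.0 / config.log_prec_prior_var
    lr_dt = config.learning_rate * config.dt

    F = np.empty(n_steps)
    for t in range(n_steps):
        pi = np.exp(lam)
        F[t] = 0.5 * np.sum(_LOG2PI - lam + pi * eps2[t]) \
            + 0.5 * inv_vlam * np.sum((lam - lam0) ** 2)
        dF_dlam = 0.5 * (pi * eps2[t] - 1.0) + inv_vlam * (lam - lam0)
        lam = np.clip(lam - lr_dt * dF_dlam, lo, hi)

    pi_final = np.exp(lam)
    # conjugate per-slot gain posterior under the final precisions
    S_pp = np.sum(pred ** 2, axis=0)
    S_py = np.sum(pred * y, axis=0)
    prior_prec = 1.0 / config.gain_prior_var
    post_prec = prior_prec + pi_final * S_pp
    post_mean = pi_final * S_py / post_prec

    return LifetimeOutput(
        F_trace=F,
        action=action_from_lagrangians(F, config.dt),
        precisions=PrecisionState(lam, precisions.bounds),
        gain_posterior=VariationalDensity(post_mean, np.diag(1.0 / post_prec)),
        gain_prior=VariationalDensity(np.zeros(n_slots),
                                      np.diag(np.full(n_slots,
                                                      config.gain_prior_var))),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# slow scale: one generation of synaptic selection


def generation_step(connectivity: Connectivity, lifetime: LifetimeOutput,
                    config: DemoConfig, *, seed: int = 0
                    ) -> tuple[Connectivity, list[dict]]:
    """Audit every synapse by Bayesian model reduction; relocate the losers.

    Each slot's reduction candidate pins its gain to zero (prior variance
    ``reduced_gain_var``).  Greedy structure selection applies every
    reduction with positive evidence change; each removed synapse's slot is
    rewired to a pool drawn uniformly at random from the pools not
    currently assigned to it.  The decision log records every slot's
    evidence delta, verdict, and any relocation target.
    """
    n = connectivity.n_slots
    prior, post = lifetime.gain_prior, lifetime.gain_posterior
    def _pin(j):
        def reduce_prior(current: VariationalDensity) -> VariationalDensity:
            var = np.diag(current.cov).copy()
            var[j] = config.reduced_gain_var
            mean = current.mean.copy()
            mean[j] = 0.0
            return VariationalDensity(mean, np.diag(var))
        return reduce_prior

    candidates = {f"slot_{j}": _pin(j) for j in range(n)}
    sel = structure_select(prior, post, candidates)

    rng = np.random.default_rng(seed)
    new_assignment = list(connectivity.assignment)
    log = []
    for entry, j in zip(sel.decision_log, range(n)):
        rec = dict(entry)
        rec["slot"] = j
        rec["pool"] = connectivity.assignment[j]
        if entry["accepted"]:
            current = connectivity.assignment[j]
            allowed = [p for p in range(config.n_pools) if p != current]
            rec["new_pool"] = int(rng.choice(allowed))
            new_assignment[j] = rec["new_pool"]
        log.append(rec)
    return Connectivity(new_assignment), log


# ---------------------------------------------------------------------------
# the full demo


@dataclass
class DemoResult:
    table: pd.DataFrame = field(repr=False)   # generation, action, ...
    connectivities: list[Connectivity] = field(repr=False)
    precision_history: np.ndarray = field(repr=False)  # (gens, slots)
    config: DemoConfig = None

    @property
    def actions(self) -> np.ndarray:
        return self.table["action"].to_numpy()

    @property
    def final_connectivity(self) -> Connectivity:
        return self.connectivities[-1]


def run_demo(config: DemoConfig, *,
             initial_connectivity: Connectivity | None = None) -> DemoResult:
    """Run ``n_generations`` of lifetime + synaptic selection.

    Precisions persist across generations except for relocated slots, which
    restart from the initial log precision (a fresh specialisation knows
    nothing).  Deterministic given ``config.seed``.
    """
    env = make_environment(config)
    conn = (Connectivity.random(config, _subseed(config.seed, 0xC0))
            if initial_connectivity is None else initial_connectivity)
    prec = PrecisionState.initial(config)

    rows = []
    conns = [conn]
    prec_hist = np.empty((config.n_generations, config.n_slots))
    for gen in range(config.n_generations):
        life = run_lifetime(conn, prec, env, config,
                            seed=_subseed(config.seed, 1, gen))
        new_conn, log = generation_step(conn, life, config,
                                        seed=_subseed(config.seed, 2, gen))
        relocated = [e["slot"] for e in log if e["accepted"]]
        lam = life.precisions.log_precision.copy()
        prec_hist[gen] = lam
        lam[relocated] = config.log_prec_init
        prec = PrecisionState(lam, prec.bounds)
        rows.append({
            "generation": gen,
            "action": life.action,
            "n_relocations": len(relocated),
            "mean_log_precision": float(prec_hist[gen].mean()),
            "n_matched": sum(p == j for j, p in enumerate(conn.assignment)),
        })
        conn = new_conn
        conns.append(conn)

    return DemoResult(table=pd.DataFrame(rows), connectivities=conns,
                      precision_history=prec_hist, config=config)
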