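"""Renormalisation operators: grouping states into particles, reducing paths
to slow states, and composing the two across scales.

The grouping operator G partitions the states of a sparsely coupled system
into *particles*, each with its own internal states and a blanket of sensory
and active states.  A particle's external states are simply the (blanket)
states of the remaining particles that influence it.  The reduction operator
R maps a particle's path to its slow states — the flow parameters and
initial states that are time-invariant over a lifetime, plus any empirically
slow modes.  Composing R after G at one scale yields the state vector of the
next: particles of particles, i.e. populations, whose characteristic
timescales are strictly slower.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .langevin import Trajectory

_EXACT_MAX_NODES = 10


class NoValidPartition(Warning):
    """The coupling graph admits no particular partition into >= 2 particles."""


@dataclass
class CouplingGraph:
    """Directed influence graph: edge (j, k) means state j drives state k."""

    d: int
    edges: frozenset[tuple[int, int]]

    def __init__(self, d: int, edges: Iterable[tuple[int, int]]):
        self.d = int(d)
        self.edges = frozenset((int(j), int(k)) for j, k in edges)
        for j, k in self.edges:
            if not (0 <= j < self.d and 0 <= k < self.d):
                raise ValueError(f"edge ({j}, {k}) outside 0..{self.d - 1}")

    @classmethod
    def from_jacobian(cls, J: np.ndarray, tol: float = 1e-12) -> "CouplingGraph":
        J = np.asarray(J, dtype=float)
        d = J.shape[0]
        edges = [(j, k) for k in range(d) for j in range(d) if abs(J[k, j]) > tol]
        return cls(d, edges)

    def in_neighbours(self, k: int) -> set[int]:
        """States driving k, self excluded (self-loops are ignored by grouping)."""
        return {j for j, kk in self.edges if kk == k and j != k}

    def out_neighbours(self, j: int) -> set[int]:
        return {k for jj, k in self.edges if jj == j and k != j}

    def to_dict(self) -> dict:
        return {"d": self.d, "edges": sorted(map(list, self.edges))}

    @classmethod
    def from_dict(cls, spec: dict) -> "CouplingGraph":
        return cls(spec["d"], [tuple(e) for e in spec["edges"]])


@dataclass
class ParticleAssignment:
    """A partition of states into particles with per-state role labels.

    Roles follow from the cut edges: a state receiving influence from
    outside its particle is *sensory*; one that only transmits outside is
    *active*; the rest are *internal*.  Internal and active states never
    receive edges from outside their particle, and each particle contains
    at least one internal state (a thing needs states of its own).
    """

    particle_of: tuple[int, ...]           # particle id per state index
    roles: tuple[str, ...]                 # 'sensory' | 'active' | 'internal'
    scale: int = 0
    n_alternatives: int = 1                # valid finest partitions found
    trivial: bool = False                  # True if only 1 particle possible

    @property
    def n_particles(self) -> int:
        return len(set(self.particle_of))

    def members(self, p: int) -> list[int]:
        return [i for i, q in enumerate(self.particle_of) if q == p]

    def role_indices(self, p: int, role: str) -> list[int]:
        return [i for i in self.members(p) if self.roles[i] == role]

    def validate(self, graph: CouplingGraph) -> "ParticleAssignment":
        """Machine-check the invariants against the coupling graph."""
        if len(self.particle_of) != graph.d:
            raise ValueError("assignment does not cover every state exactly once")
        for i in range(graph.d):
            outside_in = {j for j in graph.in_neighbours(i)
                          if self.particle_of[j] != self.particle_of[i]}
            if self.roles[i] in ("active", "internal") and outside_in:
                raise AssertionError(
                    f"{self.roles[i]} state {i} receives edges from outside "
                    f"its particle: {sorted(outside_in)}")
            if self.roles[i] == "sensory":
                bad = {j for j in outside_in if self.roles[j] == "internal"}
                if bad:
                    raise AssertionError(
                        f"sensory state {i} receives from internal states of "
                        f"other particles: {sorted(bad)}")
        for p in set(self.particle_of):
            if not self.role_indices(p, "internal"):
                raise AssertionError(f"particle {p} has no internal state")
        return self

    def to_dict(self) -> dict:
        return {"particle_of": list(self.particle_of), "roles": list(self.roles),
                "scale": self.scale, "n_alternatives": self.n_alternatives,
                "trivial": self.trivial}


def _labels_for(parts: Sequence[frozenset[int]], graph: CouplingGraph,
                d: int) -> tuple[tuple[int, ...], tuple[str, ...]]:
    part_of = [0] * d
    for p, part in enumerate(parts):
        for i in part:
            part_of[i] = p
    roles = []
    for i in range(d):
        cross_in = any(part_of[j] != part_of[i] for j in graph.in_neighbours(i))
        cross_out = any(part_of[k] != part_of[i] for k in graph.out_neighbours(i))
        if cross_in:
            roles.append("sensory")
        elif cross_out:
            roles.append("active")
        else:
            roles.append("internal")
    return tuple(part_of), tuple(roles)


def _is_valid(parts: Sequence[frozenset[int]], graph: CouplingGraph, d: int,
              candidate_roles: dict[int, str] | None) -> bool:
    part_of, roles = _labels_for(parts, graph, d)
    # every particle must own at least one internal state
    internal_by_part = {}
    for i in range(d):
        if roles[i] == "internal":
            internal_by_part[part_of[i]] = True
    if len(internal_by_part) < len(parts):
        return False
    if candidate_roles:
        for i, allowed in candidate_roles.items():
            if allowed == "blanket":
                if roles[i] == "internal":
                    return False
            elif roles[i] != allowed:
                return False
    return True


def _set_partitions(items: list[int]):
    """All set partitions, canonical order (first item anchors first block)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [smaller[k] | {first}] + smaller[k + 1:]
        yield smaller + [{first}]


def brute_force_finest(graph: CouplingGraph,
                       candidate_roles: dict[int, str] | None = None
                       ) -> tuple[list[frozenset[int]], int]:
    """Enumerate every valid partition; return one finest and the count of
    finest alternatives.  Exponential — used as an oracle on small graphs."""
    d = graph.d
    best: list[frozenset[int]] | None = None
    n_best = 0
    for parts in _set_partitions(list(range(d))):
        fparts = [frozenset(p) for p in parts]
        if not _is_valid(fparts, graph, d, candidate_roles):
            continue
        if best is None or len(fparts) > len(best):
            best, n_best = fparts, 1
        elif len(fparts) == len(best):
            n_best += 1
    if best is None:
        return [frozenset(range(d))], 0
    return best, n_best


def _heuristic_partition(graph: CouplingGraph) -> list[frozenset[int]]:
    """Blanket-removal condensation for graphs too large to enumerate.

    Candidate blanket nodes are those whose removal increases the number of
    weakly connected components (they mediate between would-be particles).
    The components of the remaining autonomous influence graph become
    internal cores; each blanket node then joins the core it shares the
    most edges with (ties to the lowest core id).  Deterministic throughout.
    """
    import networkx as nx

    d = graph.d
    G = nx.DiGraph()
    G.add_nodes_from(range(d))
    G.add_edges_from((j, k) for j, k in graph.edges if j != k)
    U = G.to_undirected()

    base = nx.number_connected_components(U)
    blanket = [v for v in range(d)
               if U.degree(v) > 0
               and nx.number_connected_components(
                   U.subgraph([u for u in range(d) if u != v])) > base]
    core_graph = U.subgraph([v for v in range(d) if v not in blanket])
    cores = [set(c) for c in
             sorted(nx.connected_components(core_graph), key=min)]
    if not cores:
        return [frozenset(range(d))]
    for v in blanket:
        counts = [sum(1 for u in (graph.in_neighbours(v)
                                  | graph.out_neighbours(v)) if u in core)
                  for core in cores]
        cores[int(np.argmax(counts))].add(v)
    return [frozenset(c) for c in cores]


def group(graph: CouplingGraph,
          candidate_roles: dict[int, str] | None = None,
          *, scale: int = 0) -> ParticleAssignment:
    """Grouping operator G: partition states into particles by sparse coupling.

    Returns the finest valid partition (maximal particle count), with role
    labels induced by the cut edges and, on small graphs, the number of
    alternative finest partitions.  When no partition into >= 2 particles
    exists, returns the trivial single particle flagged ``trivial``.
    """
    d = graph.d
    if d <= _EXACT_MAX_NODES:
        parts, n_alt = brute_force_finest(graph, candidate_roles)
    else:
        parts = _heuristic_partition(graph)
        if not _is_valid(parts, graph, d, candidate_roles):
            parts = [frozenset(range(d))]
        n_alt = 1
    trivial = len(parts) == 1
    part_of, roles = _labels_for(parts, graph, d)
    return ParticleAssignment(part_of, roles, scale=scale,
                              n_alternatives=max(n_alt, 1),
                              trivial=trivial).validate(graph)


# ---------------------------------------------------------------------------
# reduction


@dataclass
class SlowStates:
    """R applied to a particle's path: parameters, initial states, slow modes."""

    theta: np.ndarray                       # declared flow parameters, unchanged
    x0: np.ndarray                          # declared initial states, unchanged
    slow_state_indices: tuple[int, ...]     # empirically slow states
    variance_scores: dict[int, float]       # normalised path variance per state
    epsilon: float

    @property
    def values(self) -> np.ndarray:
        """The slow-state vector at the next scale: (theta, x0)."""
        return np.concatenate([np.atleast_1d(self.theta), np.atleast_1d(self.x0)])


def reduce_particle(traj: Trajectory, state_indices: Sequence[int],
                    theta: np.ndarray, x0: np.ndarray, *,
                    epsilon: float = 0.05,
                    ness_variance: np.ndarray | None = None) -> SlowStates:
    """Reduction operator R over one particle's lifetime.

    Declared parameters ``theta`` and initial states ``x0`` pass through
    unchanged (they are time-invariant by construction).  Additionally, any
    simulated state whose path variance over the lifetime, normalised by its
    NESS variance, falls below ``epsilon`` is flagged as slow.

    ``ness_variance`` holds the stationary variance of each state in
    ``state_indices``; without it, the (lifetime-limited) sample variance is
    used as its own reference and no state can score as slow.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    state_indices = list(state_indices)
    scores: dict[int, float] = {}
    slow: list[int] = []
    for pos, i in enumerate(state_indices):
        path_var = float(np.var(traj.states[:, i], ddof=1))
        ref = (float(ness_variance[pos]) if ness_variance is not None
               else max(path_var, 1e-300))
        score = path_var / ref
        scores[i] = score
        if score < epsilon:
            slow.append(i)
    return SlowStates(theta=theta, x0=x0, slow_state_indices=tuple(slow),
                      variance_scores=scores, epsilon=epsilon)


# ---------------------------------------------------------------------------
# recursion across scales


@dataclass
class NextScaleSystem:
    """The scale-(i+1) system produced by composing R and G."""

    states: np.ndarray                      # concatenated genotype vectors
    offsets: tuple[int, ...]                # start of each particle's slice
    graph: CouplingGraph                    # coupling among particles
    assignment: ParticleAssignment          # particles grouped into populations
    scale: int


def renormalise(slow: Sequence[SlowStates], *,
                coupling: CouplingGraph | None = None,
                action_fn: Callable[[int, Sequence[np.ndarray]], float] | None = None,
                h: float = 1e-4, threshold: float = 1e-8,
                scale: int = 1) -> NextScaleSystem:
    """Compose reduction and grouping to build the next-scale system.

    Each particle's slow states (its genotype) become one block of the
    scale-(i+1) state vector.  Coupling among particles is either supplied
    or estimated by finite-difference cross-sensitivity: particle j drives
    particle k when perturbing j's genotype changes k's action.  Grouping
    the resulting graph yields populations; the construction can be applied
    to its own output (particles of particles).
    """
    n = len(slow)
    thetas = [s.values for s in slow]
    if coupling is None:
        if action_fn is None:
            raise ValueError("supply either a coupling graph or an action function")
        edges = []
        base = [t.copy() for t in thetas]
        A0 = [action_fn(k, base) for k in range(n)]
        for j in range(n):
            for c in range(len(base[j])):
                pert = [t.copy() for t in base]
                pert[j][c] += h
                for k in range(n):
                    if any((jj, kk) == (j, k) for jj, kk in edges):
                        continue
                    if abs(action_fn(k, pert) - A0[k]) > threshold:
                        edges.append((j, k))
        coupling = CouplingGraph(n, edges)
    assignment = group(coupling, scale=scale)
    offsets, states = [], []
    pos = 0
    for t in thetas:
        offsets.append(pos)
        states.append(t)
        pos += len(t)
    return NextScaleSystem(states=np.concatenate(states) if states else np.empty(0),
                           offsets=tuple(offsets), graph=coupling,
                           assignment=assignment, scale=scale)


def autocorrelation_time(x: np.ndarray, dt: float = 1.0,
                         max_lag: int | None = None) -> float:
    """Integrated autocorrelation time of a scalar series, in time units.

    tau = dt * (1 + 2 sum_k rho_k), summed until the first non-positive
    autocorrelation (initial positive sequence estimator).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return np.inf
    if max_lag is None:
        max_lag = n // 2
    tau = 1.0
    for k in range(1, max_lag):
        rho = float(x[:-k] @ x[k:]) / (n * var)
        if rho <= 0:
            break
        tau += 2.0 * rho
    return tau * dt
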