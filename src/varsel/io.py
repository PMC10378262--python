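"""Configuration, serialisation, output headers, and test fixtures.

Conventions: numeric tables are CSV, structured objects JSON, run
configurations YAML; matrices serialise as nested lists.  Every output file
begins with comment lines recording the package version, a hash of the
configuration, and the seed, so any artefact can be traced to the run that
produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .langevin import HelmholtzFlow, PartitionSpec, Trajectory
from .selection import (FilteringEnvironment, QuadraticStubEnvironment,
                        ThermostatEnvironment)
from .synaptic import Connectivity, DemoConfig


class ConfigError(ValueError):
    """A run configuration failed to parse or validate."""


@dataclasses.dataclass
class RunConfig:
    """One reproducible run: command, config block, seed, output directory."""

    command: str
    config: dict
    seed: int
    out: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(command=d["command"], config=dict(d.get("config", {})),
                   seed=int(d["seed"]), out=d.get("out", "."),
                   log_level=d.get("log_level", "INFO"))


def config_hash(config: Any) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_yaml(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as e:
        mark = getattr(e, "problem_mark", None)
        loc = f" (line {mark.line + 1})" if mark is not None else ""
        raise ConfigError(f"malformed YAML in {path}{loc}: {e}") from e
    if not isinstance(data, dict):
        raise ConfigError(f"{path} must contain a mapping at top level")
    return data


def file_header(seed: int, cfg_hash: str) -> str:
    return (f"# varsel {__version__}\n"
            f"# config_hash {cfg_hash}\n"
            f"# seed {seed}\n")


def write_csv(path: str | Path, df: pd.DataFrame, *, seed: int,
              cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(file_header(seed, cfg_hash))
        df.to_csv(fh, index=False)


def write_json(path: str | Path, obj: Any, *, seed: int, cfg_hash: str) -> None:
    payload = {"_meta": {"version": __version__, "config_hash": cfg_hash,
                         "seed": seed},
               "data": obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"cannot serialise {type(obj)}")


def trajectory_to_csv(path: str | Path, traj: Trajectory,
                      partition: PartitionSpec, *, cfg_hash: str) -> None:
    write_csv(path, traj.to_frame(partition), seed=traj.seed or 0,
              cfg_hash=cfg_hash)


def flow_from_config(cfg: dict) -> HelmholtzFlow:
    try:
        return HelmholtzFlow.from_dict(cfg)
    except KeyError as e:
        raise ConfigError(f"flow specification is missing {e}") from e


def environment_from_config(cfg: dict):
    """Build a fitness environment from its config block (``kind`` selects)."""
    kind = cfg.get("kind")
    params = {k: v for k, v in cfg.items() if k != "kind"}
    builders: dict[str, Callable] = {
        "quadratic-stub": lambda: QuadraticStubEnvironment(**params),
        "filtering": lambda: FilteringEnvironment(**params),
        "thermostat": lambda: ThermostatEnvironment(**params),
    }
    if kind not in builders:
        raise ConfigError(
            f"unknown environment kind {kind!r}; expected one of "
            f"{sorted(builders)}")
    try:
        return builders[kind]()
    except TypeError as e:
        raise ConfigError(f"bad {kind} environment parameters: {e}") from e


# ---------------------------------------------------------------------------
# fixtures: ready-to-run configs with machine-readable ground truth


@dataclasses.dataclass
class Fixture:
    name: str
    config: dict
    ground_truth: dict


def _scalar_ou() -> Fixture:
    return Fixture(
        name="scalar-ou",
        config={"partition": {"eta_idx": [], "s_idx": [], "a_idx": [],
                              "mu_idx": [0]},
                "Pi": [[1.0]], "Q": [[0.0]], "Gamma": [[1.0]],
                "dt": 0.01, "T": 100.0, "x0": [0.0]},
        ground_truth={"stationary_variance": 1.0, "relaxation_rate": 1.0},
    )


def _particular_4d() -> Fixture:
    # tridiagonal potential: eta-s, s-a, a-mu couplings only (no eta-mu block)
    Pi = [[2.0, 0.5, 0.0, 0.0],
          [0.5, 2.0, 0.5, 0.0],
          [0.0, 0.5, 2.0, 0.5],
          [0.0, 0.0, 0.5, 2.0]]
    Q = [[0.0, 0.3, 0.0, 0.0],
         [-0.3, 0.0, 0.0, 0.0],
         [0.0, 0.0, 0.0, 0.3],
         [0.0, 0.0, -0.3, 0.0]]
    return Fixture(
        name="particular-4d",
        config={"partition": {"eta_idx": [0], "s_idx": [1], "a_idx": [2],
                              "mu_idx": [3]},
                "Pi": Pi, "Q": Q,
                "Gamma": np.eye(4).tolist(),
                "dt": 0.01, "T": 2000.0, "x0": [0.0, 0.0, 0.0, 0.0]},
        ground_truth={"stationary_covariance":
                      np.linalg.inv(np.array(Pi)).tolist()},
    )


def _thermostat() -> Fixture:
    cfg = {"kind": "thermostat", "k_env": 1.0, "eta_amb": 0.0,
           "coupling": 1.0, "prior_prec": 1.0, "obs_prec": 4.0,
           "kappa": 4.0, "dt": 0.01}
    return Fixture(
        name="thermostat",
        config={"environment": cfg, "theta": [2.0], "lifetime": 40.0},
        ground_truth={"fixed_point_sensed": 2.0},
    )


def _two_timescale() -> Fixture:
    return Fixture(
        name="two-timescale",
        config={"partition": {"eta_idx": [], "s_idx": [], "a_idx": [],
                              "mu_idx": [0, 1]},
                "Pi": [[1.0, 0.0], [0.0, 1.0]], "Q": [[0.0, 0.0], [0.0, 0.0]],
                "Gamma": [[1.0, 0.0], [0.0, 1e-3]],
                "dt": 0.01, "T": 10.0, "x0": [0.0, 0.0]},
        ground_truth={"fast_index": 0, "slow_index": 1,
                      "relaxation_rates": [1.0, 1e-3],
                      "ness_variance": [1.0, 1.0]},
    )


def _quadratic_stub() -> Fixture:
    return Fixture(
        name="quadratic-stub",
        config={"environment": {"kind": "quadratic-stub", "theta_star": [1.5]},
                "selection": {"population_size": 20, "generations": 200,
                              "gamma_slow": 0.2, "dt_slow": 0.5,
                              "lifetime": 1.0}},
        ground_truth={"theta_star": [1.5]},
    )


def _predator_prey() -> Fixture:
    # two kinds whose actions depend on each other's genotype
    c = 0.8

    def action_fn(k: int, thetas) -> float:
        other = thetas[1 - k][0]
        return 0.5 * (thetas[k][0] - c * other) ** 2

    return Fixture(
        name="predator-prey",
        config={"coupling_strength": c, "n_agents": 2, "action_fn": action_fn},
        ground_truth={"n_populations": 1, "cross_sensitive": True},
    )


def _demo_small() -> Fixture:
    cfg = DemoConfig(n_segments=3, synapses_per_segment=2, noise=0.0)
    return Fixture(
        name="demo-small",
        config={"demo": cfg},
        ground_truth={"ordered_connectivity":
                      list(Connectivity.ground_truth(cfg).assignment)},
    )


_FIXTURES: dict[str, Callable[[], Fixture]] = {
    "scalar-ou": _scalar_ou,
    "particular-4d": _particular_4d,
    "thermostat": _thermostat,
    "two-timescale": _two_timescale,
    "quadratic-stub": _quadratic_stub,
    "predator-prey": _predator_prey,
    "demo-small": _demo_small,
}


def fixtures(name: str) -> Fixture:
    """Ready-to-run config plus machine-readable ground truth, by name."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: "
                       f"{sorted(_FIXTURES)}")
    return _FIXTURES[name]()
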