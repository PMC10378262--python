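"""Shared fixtures: small validated flows and models built per test run."""

import numpy as np
import pytest

from varsel import (GenerativeModel, HelmholtzFlow, PartitionSpec,
                    fixtures, make_particular_flow)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def one_per_role():
    """d = 4 partition with one state per role: eta=0, s=1, a=2, mu=3."""
    return PartitionSpec([0], [1], [2], [3])


@pytest.fixture
def diagonal_flow(one_per_role):
    """Independent unit OU processes: drift f(x) = -x."""
    I = np.eye(4)
    return make_particular_flow(one_per_role, I, np.zeros((4, 4)), I)


@pytest.fixture
def particular_flow():
    """The 4-d fixture flow: tridiagonal potential, solenoidal coupling."""
    return HelmholtzFlow.from_dict(fixtures("particular-4d").config)


@pytest.fixture
def scalar_internal():
    return PartitionSpec([], [], [], [0])


@pytest.fixture
def scalar_ou_flow(scalar_internal):
    return make_particular_flow(scalar_internal, [[1.0]], [[0.0]], [[1.0]])


@pytest.fixture
def conjugate_model():
    """Prior eta ~ N(0,1), sensation s = eta + N(0,1) noise."""
    return GenerativeModel(prior_mean=[0.0], prior_precision=[[1.0]],
                           likelihood=[[1.0]], noise_precision=[[1.0]])


def random_particular_flow(rng, *, with_solenoidal=True):
    """A random stable 4-d particular flow (one state per role).

    Diagonal Gamma plus a tridiagonal potential (eta-s, s-a, a-mu couplings
    only) keeps the drift Jacobian inside the allowed sparsity pattern, and
    Gamma > 0 with Pi > 0 guarantees stability.
    """
    part = PartitionSpec([0], [1], [2], [3])
    off = rng.uniform(0.2, 0.6, 3) * rng.choice([-1.0, 1.0], 3)
    Pi = np.diag(rng.uniform(1.5, 3.0, 4))
    for i, o in enumerate(off):
        Pi[i, i + 1] = Pi[i + 1, i] = o
    Gamma = np.diag(rng.uniform(0.5, 1.5, 4))
    Q = np.zeros((4, 4))
    if with_solenoidal:
        Q[0, 1], Q[2, 3] = rng.uniform(-0.5, 0.5, 2)
        Q[1, 0], Q[3, 2] = -Q[0, 1], -Q[2, 3]
    return make_particular_flow(part, Pi, Q, Gamma)
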