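"""Shared fixtures: toy networks, random networks, the packaged cell model."""

from __future__ import annotations

import math

import numpy as np
import pytest

from redivsys.core import RateLaw, ReactionNetwork
from redivsys.ecoli import load_default_parameters, build_full_model
from redivsys import sna


def make_toy(w: float = 1.0, d: float = 1.0, k: float = 1.0) -> ReactionNetwork:
    """Two-species birth/death/synthesis toy with a closed-form steady state.

    Species 1 (massless): produced at constant intensive rate w, degraded at
    d * X1.  Species 2 (unit mass): produced at k * X1, so lambda = k * X1.
    On the simplex X2 = 1 and X1 solves w - d X1 - k X1^2 = 0.
    """
    nu = np.array([[1.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
    laws = [
        RateLaw("constant", {"k": w}),
        RateLaw("linear", {"k": d}, {"s": "x1"}),
        RateLaw("linear", {"k": k}, {"s": "x1"}),
    ]
    return ReactionNetwork(["x1", "x2"], nu, [0.0, 1.0], laws,
                           ["production_x1", "degradation_x1", "synthesis_x2"],
                           ["source", "degradation", "synthesis"])


def toy_steady_state(w: float = 1.0, d: float = 1.0, k: float = 1.0):
    x1 = (-d + math.sqrt(d * d + 4 * k * w)) / (2 * k)
    return np.array([x1, 1.0]), k * x1


def random_network(rng: np.random.Generator, N: int | None = None, R: int | None = None):
    """Random mass-annotated network with affine non-negative rates."""
    N = N or rng.integers(2, 6)
    R = R or rng.integers(2, 7)
    nu = rng.integers(-2, 3, size=(N, R)).astype(float)
    mass = np.where(rng.random(N) < 0.3, 0.0, rng.integers(1, 5, size=N)).astype(float)
    if mass.sum() == 0:
        mass[0] = 1.0
    A = rng.random((R, N)) * rng.integers(0, 2, size=(R, N))
    b = rng.random(R) * 0.5

    def rate_fn(X):
        return A @ X + b

    return ReactionNetwork([f"s{i}" for i in range(N)], nu, mass, rate_fn)


def random_simplex_state(rng: np.random.Generator, net: ReactionNetwork):
    X = rng.random(net.N) + 0.05
    return X / float(net.mass @ X)


@pytest.fixture(scope="session")
def default_params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def full_net(default_params):
    return build_full_model(default_params)


@pytest.fixture(scope="session")
def full_steady_state(full_net):
    return sna.steady_state_mean(full_net)
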