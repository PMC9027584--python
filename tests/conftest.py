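"""Shared fixtures: toy optimization models implementing the classifier
protocol (param_groups / loss_and_grads / get_state / set_state) so the
schedule, LR-finder and trainer can be exercised against closed-form
oracles."""

from __future__ import annotations

import numpy as np
import pytest


class _VectorGroup:
    """One layer group holding a plain parameter vector."""

    def __init__(self, theta: np.ndarray):
        self.theta = np.asarray(theta, dtype=np.float64).copy()

    @property
    def n_params(self) -> int:
        return self.theta.size

    def get_flat(self) -> np.ndarray:
        return self.theta.copy()

    def set_flat(self, vec: np.ndarray) -> None:
        self.theta = np.asarray(vec, dtype=np.float64).copy()


class QuadraticModel:
    """J(theta) = 0.5 * ||theta||^2 split across ``n_groups`` layer groups.

    Gradient is theta itself, so every update has an exact closed form;
    batches passed in are ignored (the loss does not depend on data).
    """

    def __init__(self, theta0, n_groups: int = 1):
        theta0 = np.asarray(theta0, dtype=np.float64)
        chunks = np.array_split(theta0, n_groups)
        self.param_groups = [_VectorGroup(c) for c in chunks]

    def loss_and_grads(self, X=None, y=None, grad_scale: float = 1.0):
        loss = 0.5 * sum(float(g.theta @ g.theta) for g in self.param_groups)
        return loss, [grad_scale * g.theta.copy() for g in self.param_groups]

    def get_state(self):
        return [g.get_flat() for g in self.param_groups]

    def set_state(self, state):
        for g, v in zip(self.param_groups, state, strict=True):
            g.set_flat(v)


class ConstantLossModel:
    """Loss independent of parameters: zero gradient, flat sweep curve."""

    def __init__(self, loss: float = 1.0, n_params: int = 3):
        self.loss = loss
        self.param_groups = [_VectorGroup(np.zeros(n_params))]

    def loss_and_grads(self, X=None, y=None, grad_scale: float = 1.0):
        return self.loss, [np.zeros(g.n_params) for g in self.param_groups]

    def get_state(self):
        return [g.get_flat() for g in self.param_groups]

    def set_state(self, state):
        for g, v in zip(self.param_groups, state, strict=True):
            g.set_flat(v)


@pytest.fixture
def quadratic_model():
    return QuadraticModel


@pytest.fixture
def constant_model():
    return ConstantLossModel


@pytest.fixture
def dummy_batches():
    """Placeholder batch stream for data-independent toy models."""
    return [(None, None)]


@pytest.fixture
def small_dataset():
    """Tiny separable 3-class set at 32 px for fast end-to-end tests."""
    from dftkit.synthetic import SyntheticSpec, generate

    return generate(SyntheticSpec(K=3, n=120, side=32, signal_strength=0.9, seed=7))
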