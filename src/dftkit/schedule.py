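"""Per-layer triangular learning-rate/momentum schedules and the DFT update.

Discriminative fine-tuning (DFT) assigns each layer group of a network its
own learning rate and momentum: earlier layers, which already encode
primitive features after pretraining, receive smaller rates; later layers
receive larger ones.  On top of that layer-wise spread, a single triangular
cycle modulates the rates over the run: they rise for the first ``kappa``
fraction of iterations and fall for the remainder.

The parameter update is classical momentum SGD applied per layer group::

    v' = m * v - alpha * g
    theta' = theta + v'

All functions here are pure: identical inputs yield identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "LRBounds",
    "PhasePlan",
    "LayerOptimState",
    "Schedule",
    "layer_base_rate",
    "layer_base_momentum",
    "iteration_factor",
    "dft_update",
    "build_schedule",
]

Phase = Literal["rising", "falling"]


@dataclass(frozen=True)
class LRBounds:
    """Learning-rate and momentum ranges feeding the schedule.

    ``alpha_min``/``alpha_max`` bound the per-layer rates (dimensionless,
    positive); ``m_min``/``m_max`` bound the momenta, both in [0, 1).
    """

    alpha_min: float
    alpha_max: float
    m_min: float = 0.85
    m_max: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_min <= self.alpha_max:
            raise ValueError(
                f"need 0 < alpha_min <= alpha_max, got "
                f"({self.alpha_min}, {self.alpha_max})"
            )
        if not 0.0 <= self.m_min <= self.m_max < 1.0:
            raise ValueError(
                f"need 0 <= m_min <= m_max < 1, got ({self.m_min}, {self.m_max})"
            )


@dataclass(frozen=True)
class PhasePlan:
    """Iteration budget and layer count shaping the triangular schedule.

    ``t_max`` is the total iteration count (dataset size / batch size x
    epochs), ``l_max`` the number of layer groups, ``kappa`` the fraction of
    the run spent in the rising phase.
    """

    t_max: int
    l_max: int
    kappa: float = 0.5

    def __post_init__(self) -> None:
        if self.t_max < 2:
            raise ValueError(f"t_max must be >= 2, got {self.t_max}")
        if self.l_max < 1:
            raise ValueError(f"l_max must be >= 1, got {self.l_max}")
        if not 0.0 < self.kappa < 1.0:
            raise ValueError(f"kappa must lie in (0, 1), got {self.kappa}")


@dataclass(frozen=True)
class LayerOptimState:
    """Snapshot of one layer group's parameters, velocity, rate and momentum."""

    layer_index: int
    parameters: np.ndarray
    velocity: np.ndarray
    alpha: float
    momentum: float

    def __post_init__(self) -> None:
        if self.parameters.shape != self.velocity.shape:
            raise ValueError(
                f"velocity shape {self.velocity.shape} != parameters shape "
                f"{self.parameters.shape}"
            )


def _check_layer(l: int, l_max: int) -> None:
    if not 0 <= l < l_max:
        raise IndexError(f"layer index {l} outside [0, {l_max})")


def layer_base_rate(l: int, l_max: int, bounds: LRBounds) -> float:
    """Peak learning rate of layer group ``l``: linear from alpha_min (layer 0)
    to alpha_max (last layer).  A single group gets alpha_max."""
    _check_layer(l, l_max)
    if l_max == 1:
        return bounds.alpha_max
    frac = l / (l_max - 1)
    return bounds.alpha_min + (bounds.alpha_max - bounds.alpha_min) * frac


def layer_base_momentum(l: int, l_max: int, bounds: LRBounds, phase: Phase) -> float:
    """Momentum of layer group ``l``: rising phase interpolates m_min -> m_max
    across layers; falling phase mirrors it, m_max -> m_min."""
    _check_layer(l, l_max)
    if phase not in ("rising", "falling"):
        raise ValueError(f"phase must be 'rising' or 'falling', got {phase!r}")
    frac = 1.0 if l_max == 1 else l / (l_max - 1)
    if phase == "rising":
        return bounds.m_min + (bounds.m_max - bounds.m_min) * frac
    return bounds.m_max - (bounds.m_max - bounds.m_min) * frac


def iteration_factor(t: int, plan: PhasePlan) -> float:
    """Triangular modulation factor in [0, 1] at iteration ``t``.

    Rises 0 -> 1 over iterations [0, kappa*t_max), falls 1 -> 0 over
    [kappa*t_max, t_max).  The factor scales the layer-wise spread above
    alpha_min, so no layer ever drops below alpha_min (never frozen).
    """
    if not 0 <= t < plan.t_max:
        raise IndexError(f"iteration {t} outside [0, {plan.t_max})")
    peak = plan.kappa * plan.t_max
    if t < peak:
        return t / peak
    return 1.0 - (t - peak) / (plan.t_max - peak)


def dft_update(state: LayerOptimState, gradient: np.ndarray) -> LayerOptimState:
    """One momentum-SGD step on a layer group; pure, returns a new state.

    ``v' = m*v - alpha*g``; ``theta' = theta + v'``.  With momentum 0 this
    reduces to plain SGD, ``theta' = theta - alpha*g``.
    """
    gradient = np.asarray(gradient)
    if gradient.shape != state.parameters.shape:
        raise ValueError(
            f"gradient shape {gradient.shape} != parameters shape "
            f"{state.parameters.shape}"
        )
    velocity = state.momentum * state.velocity - state.alpha * gradient
    parameters = state.parameters + velocity
    return replace(state, parameters=parameters, velocity=velocity)


@dataclass(frozen=True)
class Schedule:
    """Dense (t_max x l_max) tables of learning rate and momentum.

    ``alpha[t, l]`` / ``momentum[t, l]`` give layer group ``l``'s values at
    iteration ``t``.
    """

    alpha: np.ndarray
    momentum: np.ndarray
    plan: PhasePlan
    bounds: LRBounds

    def alpha_at(self, t: int, l: int) -> float:
        return float(self.alpha[t, l])

    def momentum_at(self, t: int, l: int) -> float:
        return float(self.momentum[t, l])

    def to_frame(self):
        """Long-format table (t, layer, alpha, momentum) for inspection."""
        import pandas as pd

        t_idx, l_idx = np.meshgrid(
            np.arange(self.plan.t_max), np.arange(self.plan.l_max), indexing="ij"
        )
        return pd.DataFrame(
            {
                "t": t_idx.ravel(),
                "layer": l_idx.ravel(),
                "alpha": self.alpha.ravel(),
                "momentum": self.momentum.ravel(),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_schedule(
    plan: PhasePlan, bounds: LRBounds, invert_momentum: bool = False
) -> Schedule:
    """Materialize the full per-iteration, per-layer schedule.

    The effective rate of layer ``l`` at iteration ``t`` is::

        alpha_min + iteration_factor(t) * (layer_base_rate(l) - alpha_min)

    so every rate stays in [alpha_min, alpha_max], rates are non-decreasing
    in layer index at any fixed iteration, and each layer's trajectory is
    triangular with its peak exactly at the phase boundary.

    Momentum follows the layer-wise interpolation of the current phase
    (rising: m_min -> m_max across layers; falling: mirrored).  With
    ``invert_momentum`` the phases swap, cycling momentum opposite to the
    rate as is common practice.
    """
    t_max, l_max = plan.t_max, plan.l_max
    base = np.array([layer_base_rate(l, l_max, bounds) for l in range(l_max)])
    factor = np.array([iteration_factor(t, plan) for t in range(t_max)])
    alpha = bounds.alpha_min + factor[:, None] * (base[None, :] - bounds.alpha_min)
    alpha = np.clip(alpha, bounds.alpha_min, bounds.alpha_max)

    peak = plan.kappa * t_max
    momentum = np.empty((t_max, l_max))
    for t in range(t_max):
        phase: Phase = "rising" if t < peak else "falling"
        if invert_momentum:
            phase = "falling" if phase == "rising" else "rising"
        momentum[t] = [
            layer_base_momentum(l, l_max, bounds, phase) for l in range(l_max)
        ]
    return Schedule(alpha=alpha, momentum=momentum, plan=plan, bounds=bounds)
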