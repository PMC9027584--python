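"""Learning-rate range test: a single sweep of increasing rates with loss
tracking, and automatic bound selection at the steepest loss descent.

The sweep takes one plain-SGD step per candidate rate on successive batches
(cycling the stream if needed), records raw and exponentially smoothed
loss, and aborts once the smoothed loss exceeds four times its running
minimum (divergence guard).  Model weights are restored afterward, so the
sweep is side-effect free.

Bound selection replaces the usual visual choice: the most negative
finite-difference slope of smoothed loss against log-rate marks alpha_max,
and alpha_min = alpha_max / 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import LRBounds

__all__ = ["SweepSpec", "SweepCurve", "NoDescendingRegionError",
           "run_sweep", "select_bounds"]

DIVERGENCE_FACTOR = 4.0


class NoDescendingRegionError(RuntimeError):
    """The loss never decreased anywhere along the sweep."""


@dataclass(frozen=True)
class SweepSpec:
    """Rate grid and smoothing for one range test."""

    lr_start: float = 1e-4
    lr_end: float = 10.0
    num_steps: int = 60
    spacing: str = "geometric"   # or "linear"
    smoothing: float = 0.98      # exponential-average weight in [0, 1)

    def __post_init__(self) -> None:
        if not 0 < self.lr_start < self.lr_end:
            raise ValueError("need 0 < lr_start < lr_end")
        if self.num_steps < 10:
            raise ValueError(f"num_steps must be >= 10, got {self.num_steps}")
        if self.spacing not in ("geometric", "linear"):
            raise ValueError(f"spacing must be geometric or linear, got {self.spacing!r}")
        if not 0.0 <= self.smoothing < 1.0:
            raise ValueError("smoothing must lie in [0, 1)")

    def rates(self) -> np.ndarray:
        if self.spacing == "geometric":
            return np.geomspace(self.lr_start, self.lr_end, self.num_steps)
        return np.linspace(self.lr_start, self.lr_end, self.num_steps)


@dataclass(frozen=True)
class SweepCurve:
    """Result of one sweep: rates tried, raw and smoothed losses, and the
    index where the divergence guard fired (None if it never did)."""

    rates: np.ndarray
    losses: np.ndarray           # raw per-step loss
    smoothed: np.ndarray
    diverged_at: int | None = None

    def __post_init__(self) -> None:
        if len(self.rates) != len(self.losses) or len(self.rates) != len(self.smoothed):
            raise ValueError("rates/losses/smoothed lengths differ")
        if len(self.rates) > 1 and not (np.diff(self.rates) > 0).all():
            raise ValueError("rates must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"rate": self.rates, "loss": self.losses, "smoothed_loss": self.smoothed}
        )


def run_sweep(model, data_stream, spec: SweepSpec, seed: int = 0) -> SweepCurve:
    """One optimizer step per candidate rate; weights restored afterward.

    ``model`` follows the classifier protocol (``param_groups``,
    ``loss_and_grads``, ``get_state``/``set_state``); ``data_stream`` is a
    sequence of (X, y) batches, cycled if shorter than the sweep.
    """
    batches = list(data_stream)
    if not batches:
        raise ValueError("data stream is empty")
    rates = spec.rates()
    saved = model.get_state()
    losses, smoothed = [], []
    avg = 0.0
    best = np.inf
    diverged_at = None
    try:
        for i, rate in enumerate(rates):
            X, y = batches[i % len(batches)]
            loss, grads = model.loss_and_grads(X, y)
            losses.append(loss)
            avg = spec.smoothing * avg + (1.0 - spec.smoothing) * loss
            debiased = avg / (1.0 - spec.smoothing ** (i + 1))
            smoothed.append(debiased)
            best = min(best, debiased)
            if not np.isfinite(loss) or debiased > DIVERGENCE_FACTOR * best:
                diverged_at = i
                break
            for group, g in zip(model.param_groups, grads):
                group.set_flat(group.get_flat() - rate * g)
    finally:
        model.set_state(saved)
    n = len(losses)
    return SweepCurve(
        rates=rates[:n],
        losses=np.asarray(losses),
        smoothed=np.asarray(smoothed),
        diverged_at=diverged_at,
    )


def select_bounds(
    curve: SweepCurve,
    m_min: float = 0.85,
    m_max: float = 0.95,
    window: int | None = None,
) -> LRBounds:
    """Pick (alpha_min, alpha_max) at the steepest descent of the curve.

    Scans every segment of ``window`` steps for the most negative
    finite-difference slope of smoothed loss w.r.t. log-rate; alpha_max is
    the right endpoint of the steepest segment, additionally capped at the
    rate of the curve's minimum and below any divergence point, and
    alpha_min = alpha_max / 10.  The default window is one-twentieth of the
    curve (so short clean curves degrade to the consecutive-pair scan);
    widening it suppresses single-batch noise in long sweeps, where a lone
    one-step drop must not outrank a sustained descent.  Momentum bounds
    are passed through from configuration defaults.
    """
    finite = np.isfinite(curve.smoothed)
    if finite.sum() < 3:
        raise ValueError("curve needs at least 3 finite points")
    last = len(curve.rates) if curve.diverged_at is None else curve.diverged_at
    rates = curve.rates[:last]
    loss = curve.smoothed[:last]
    if len(rates) < 2:
        raise NoDescendingRegionError(
            "sweep diverged immediately; widen the sweep toward smaller rates"
        )
    w = max(1, len(rates) // 20) if window is None else max(1, int(window))
    w = min(w, len(rates) - 1)
    log_r = np.log(rates)
    slopes = (loss[w:] - loss[:-w]) / (log_r[w:] - log_r[:-w])
    if not (slopes < 0).any():
        raise NoDescendingRegionError(
            "loss never decreased along the sweep; widen the sweep range"
        )
    i = int(np.argmin(slopes))
    alpha_max = float(min(rates[i + w], rates[int(np.argmin(loss))]))
    return LRBounds(alpha_min=alpha_max / 10.0, alpha_max=alpha_max,
                    m_min=m_min, m_max=m_max)
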