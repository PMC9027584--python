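"""Fine-tuning orchestration: stratified splits, the regularized objective,
DFT-scheduled epochs, an emulated mixed-precision step, and evaluation.

The objective minimized is J(theta) = (1/|B|) sum_i L(f(x_i), theta) +
lambda * Omega(theta) with L cross-entropy and Omega the squared norm of
all trainable weights.  Each layer group is updated by the momentum
velocity rule with its own (alpha, momentum) drawn from the triangular
schedule; collapsing the bounds and zeroing momentum recovers plain SGD
exactly, which the tests exploit as an equivalence oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import ImageSet
from .metrics import ClassMetrics, ConfusionMatrix, confusion_matrix, summary_metrics
from .schedule import LRBounds, LayerOptimState, PhasePlan, build_schedule, dft_update
from .synthetic import largest_remainder_counts

__all__ = [
    "TrainConfig",
    "Objective",
    "TrainResult",
    "TrainingDivergedError",
    "split_indices",
    "split_dataset",
    "compute_objective",
    "mixed_precision_grads",
    "train_dft",
    "evaluate",
]


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; message names the iteration and layer group."""


@dataclass(frozen=True)
class TrainConfig:
    """Training conventions: epoch budget, batch/image geometry, split, seed.

    Defaults follow the intended production setting (batch 64, 400 px
    images, 80:15:5 split, at most 50 epochs); tests run the same code at
    64 px.
    """

    epochs: int = 10
    batch_size: int = 64
    image_side: int = 400
    split_ratio: tuple[int, int, int] = (80, 15, 5)
    weight_decay: float = 1e-4
    seed: int = 0
    mixed_precision: bool = False
    loss_scale: float = 1024.0
    kappa: float = 0.5
    cycle: str = "run"           # one triangular cycle per "run" or per "epoch"
    invert_momentum: bool = False
    epoch_cap: int = 50

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.epochs > self.epoch_cap:
            raise ValueError(f"epochs must lie in [0, {self.epoch_cap}]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if len(self.split_ratio) != 3 or any(r <= 0 for r in self.split_ratio):
            raise ValueError("split_ratio must be three positive parts")
        if sum(self.split_ratio) != 100:
            raise ValueError(f"split_ratio must sum to 100, got {self.split_ratio}")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.loss_scale <= 0:
            raise ValueError("loss_scale must be > 0")
        if self.cycle not in ("run", "epoch"):
            raise ValueError("cycle must be 'run' or 'epoch'")


@dataclass(frozen=True)
class Objective:
    """Decomposed objective value J = data_loss + lam * regularizer."""

    data_loss: float
    regularizer: float
    lam: float

    @property
    def total(self) -> float:
        return self.data_loss + self.lam * self.regularizer


def compute_objective(batch_losses, theta_groups, lam: float) -> Objective:
    """Mean batch loss plus lambda times the squared weight norm."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    data_loss = float(np.mean(batch_losses))
    omega = float(sum(np.sum(np.square(t)) for t in theta_groups))
    return Objective(data_loss=data_loss, regularizer=omega, lam=lam)


# -- dataset splitting -------------------------------------------------------

def _per_class_take(class_indices: dict, n_take: int, n_remaining: int) -> dict:
    """Largest-remainder allocation of n_take across classes, capped by
    availability; any shortfall tops up from classes with spare items."""
    classes = sorted(class_indices)
    avail = np.array([len(class_indices[c]) for c in classes])
    if n_take == 0:
        return {c: 0 for c in classes}
    quota = largest_remainder_counts(n_take, avail / n_remaining)
    quota = np.minimum(quota, avail)
    short = n_take - quota.sum()
    while short > 0:
        spare = avail - quota
        k = int(np.argmax(spare))
        grant = min(short, spare[k])
        quota[k] += grant
        short -= grant
    return {c: int(q) for c, q in zip(classes, quota)}


def split_indices(labels, ratio=(80, 15, 5), seed: int = 0):
    """Stratified disjoint (train, val, test) index arrays.

    Overall sizes are the rounded proportions with the remainder assigned
    to train; within that, each split takes a largest-remainder share of
    every class so the class mix is preserved where counts permit.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if any(r <= 0 for r in ratio) or sum(ratio) != 100:
        raise ValueError("ratio parts must be positive and sum to 100")
    if n < 3:
        raise ValueError(f"need at least 3 items to form 3 partitions, got {n}")
    n_val = round(n * ratio[1] / 100)
    n_test = round(n * ratio[2] / 100)
    rng = np.random.default_rng(seed)
    pools = {
        int(c): list(rng.permutation(np.flatnonzero(labels == c)))
        for c in np.unique(labels)
    }
    parts: list[list[int]] = []
    remaining = n
    for n_take in (n_test, n_val):
        quota = _per_class_take(pools, n_take, remaining)
        taken: list[int] = []
        for c, q in quota.items():
            taken.extend(pools[c][:q])
            pools[c] = pools[c][q:]
        parts.append(taken)
        remaining -= n_take
    test_idx, val_idx = parts
    train_idx = [i for pool in pools.values() for i in pool]
    return (
        np.sort(np.asarray(train_idx, dtype=int)),
        np.sort(np.asarray(val_idx, dtype=int)),
        np.sort(np.asarray(test_idx, dtype=int)),
    )


def split_dataset(items: ImageSet, ratio=(80, 15, 5), seed: int = 0):
    """Stratified (train, val, test) ImageSets; disjoint and exhaustive."""
    tr, va, te = split_indices(items.labels, ratio, seed)
    return items.subset(tr), items.subset(va), items.subset(te)


# -- mixed precision ---------------------------------------------------------

def mixed_precision_grads(
    model,
    X: np.ndarray,
    y: np.ndarray,
    loss_scale: float = 1024.0,
    compute_dtype=np.float16,
):
    """Scaled-gradient step contract against full-precision master weights.

    The loss is scaled by ``loss_scale`` before backpropagation; scaled
    gradients are stored at ``compute_dtype`` (the reduced-precision path),
    then unscaled into float64 for the master update.  Parameters and
    inputs are rounded to ``compute_dtype`` for the pass and the master
    copy restored afterward.  Returns (loss, grads) or (loss, None) when
    any scaled gradient is non-finite — the caller must then skip the step.

    With ``compute_dtype=np.float32`` and ``loss_scale=1`` the result is
    identical to the plain full-precision step.
    """
    if loss_scale <= 0:
        raise ValueError("loss_scale must be > 0")
    reduced = np.dtype(compute_dtype).itemsize < 4
    master = model.get_state()
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            if reduced:
                for group, vec in zip(model.param_groups, master):
                    group.set_flat(vec.astype(compute_dtype).astype(np.float64))
                if X is not None:
                    X = X.astype(compute_dtype).astype(np.float32)
            loss, grads = model.loss_and_grads(X, y, grad_scale=loss_scale)
            stored = [g.astype(compute_dtype) for g in grads] if reduced else grads
    finally:
        model.set_state(master)
    if any(not np.isfinite(g).all() for g in stored):
        return loss, None
    return loss, [np.asarray(g, dtype=np.float64) / loss_scale for g in stored]


# -- training loop -----------------------------------------------------------

@dataclass
class TrainResult:
    """Per-epoch history plus the best-validation checkpoint bookkeeping."""

    history: list = field(default_factory=list)
    best_epoch: int | None = None
    best_val_accuracy: float = -1.0
    skipped_steps: int = 0


def _data_loss_and_acc(model, X, y, batch_size=256):
    from .models import softmax_cross_entropy

    losses, correct = [], 0
    for i in range(0, len(X), batch_size):
        logits = model.predict_logits(X[i : i + batch_size])
        loss, _ = softmax_cross_entropy(logits, y[i : i + batch_size])
        losses.append(loss * len(logits))
        correct += int((np.argmax(logits, axis=1) == y[i : i + batch_size]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train_dft(model, train: ImageSet, val: ImageSet, config: TrainConfig,
              bounds: LRBounds) -> TrainResult:
    """Run DFT epochs with the triangular per-layer schedule.

    The best-validation-accuracy checkpoint (ties to the earlier epoch) is
    restored into ``model`` before returning.  Raises
    :class:`TrainingDivergedError` on a non-finite loss, naming the
    iteration; persistently-overflowing mixed-precision steps are skipped
    and counted instead.
    """
    result = TrainResult()
    if config.epochs == 0:
        return result
    X = train.as_batch()
    y = train.labels
    Xv = val.as_batch()
    yv = val.labels
    n = len(X)
    iters_per_epoch = max(1, math.ceil(n / config.batch_size))
    cycle_len = iters_per_epoch if config.cycle == "epoch" else iters_per_epoch * config.epochs
    plan = PhasePlan(t_max=max(2, cycle_len), l_max=len(model.param_groups),
                     kappa=config.kappa)
    schedule = build_schedule(plan, bounds, invert_momentum=config.invert_momentum)
    velocities = [np.zeros(g.n_params) for g in model.param_groups]
    rng = np.random.default_rng(config.seed)
    lam = config.weight_decay
    best_state = None
    t = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for b in range(iters_per_epoch):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            Xb, yb = X[idx], y[idx]
            t_sched = t % plan.t_max
            if config.mixed_precision:
                loss, grads = mixed_precision_grads(
                    model, Xb, yb, loss_scale=config.loss_scale
                )
                if grads is None:
                    result.skipped_steps += 1
                    t += 1
                    continue
            else:
                loss, grads = model.loss_and_grads(Xb, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at iteration {t} (epoch {epoch})"
                )
            epoch_losses.append(loss)
            for l, (group, g, v) in enumerate(
                zip(model.param_groups, grads, velocities)
            ):
                theta = group.get_flat()
                if lam:
                    g = g + 2.0 * lam * theta
                if not np.isfinite(g).all():
                    raise TrainingDivergedError(
                        f"non-finite gradient at iteration {t}, layer group {l}"
                    )
                state = LayerOptimState(
                    layer_index=l,
                    parameters=theta,
                    velocity=v,
                    alpha=schedule.alpha_at(t_sched, l),
                    momentum=schedule.momentum_at(t_sched, l),
                )
                new = dft_update(state, g)
                group.set_flat(new.parameters)
                velocities[l] = new.velocity
            t += 1
        val_loss, val_acc = _data_loss_and_acc(model, Xv, yv)
        _, train_acc = _data_loss_and_acc(model, X, y)
        result.history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)) if epoch_losses else float("nan"),
                "train_accuracy": train_acc,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        if val_acc > result.best_val_accuracy:
            result.best_val_accuracy = val_acc
            result.best_epoch = epoch
            best_state = model.get_state()
    if best_state is not None:
        model.set_state(best_state)
    return result


def evaluate(model, subset: ImageSet, K: int | None = None
             ) -> tuple[ConfusionMatrix, ClassMetrics]:
    """Argmax predictions (ties to the lowest class index) -> metrics."""
    if len(subset) == 0:
        raise ValueError("evaluation subset is empty")
    preds = model.predict(subset.as_batch())
    if K is None:
        K = int(max(subset.labels.max(), preds.max())) + 1
    cm = confusion_matrix(subset.labels, preds, K)
    return cm, summary_metrics(cm)
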