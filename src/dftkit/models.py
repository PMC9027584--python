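"""Minimal layer-group network backend consumed by the trainer.

The DFT optimizer only needs models that expose an ordered list of
*parameter groups* (one convolution/linear block = one group, classifier
head last), each with flat get/set access to its weights and gradient.
This module provides exactly that: a small, explicit-backprop stack of
conv / dense / relu / pooling layers in pure numpy, sufficient for training
small grayscale classifiers on CPU.  Any object honoring the same protocol
(``param_groups``, ``loss_and_grads``) plugs into the trainer unchanged.

Arrays are float32 throughout; inputs are (N, C, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "Conv2d",
    "ReLU",
    "GlobalAvgPool",
    "Flatten",
    "Sequential",
    "NetClassifier",
    "SmallCNN",
    "softmax_cross_entropy",
    "replace_head",
    "HeadNotFoundError",
]


class HeadNotFoundError(RuntimeError):
    """The model exposes no final classification layer to replace."""


class _Layer:
    """Stateless layer; subclasses with weights override the param API."""

    params: list  # list of np.ndarray, empty for stateless layers

    def __init__(self) -> None:
        self.params = []
        self.grads: list = []

    # -- flat parameter access (one group = one vector) --
    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def get_flat(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self.params]).astype(np.float64)

    def set_flat(self, vec: np.ndarray) -> None:
        off = 0
        for p in self.params:
            p[...] = vec[off : off + p.size].reshape(p.shape).astype(p.dtype)
            off += p.size
        if off != vec.size:
            raise ValueError(f"flat vector size {vec.size}, expected {off}")

    def grad_flat(self) -> np.ndarray:
        return np.concatenate([g.ravel() for g in self.grads]).astype(np.float64)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ReLU(_Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Flatten(_Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class GlobalAvgPool(_Layer):
    """(N, C, H, W) -> (N, C): spatial mean."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class AvgPool2d(_Layer):
    """Non-overlapping window average; spatial dims must divide the factor."""

    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x):
        f = self.factor
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def backward(self, dy):
        f = self.factor
        up = np.repeat(np.repeat(dy, f, axis=2), f, axis=3)
        return up / (f * f)


class Dense(_Layer):
    """Affine layer y = x W^T + b; He-initialized."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.W = (rng.standard_normal((out_features, in_features)) * scale).astype(
            np.float32
        )
        self.b = np.zeros(out_features, dtype=np.float32)
        self.params = [self.W, self.b]

    @property
    def in_features(self) -> int:
        return self.W.shape[1]

    @property
    def out_features(self) -> int:
        return self.W.shape[0]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        dW = dy.T @ self._x
        db = dy.sum(axis=0)
        self.grads = [dW, db]
        return dy @ self.W


class Conv2d(_Layer):
    """3x3-style convolution via im2col, with stride and zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
    ):
        super().__init__()
        k = kernel_size
        scale = np.sqrt(2.0 / (in_channels * k * k))
        self.W = (
            rng.standard_normal((out_channels, in_channels, k, k)) * scale
        ).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.params = [self.W, self.b]
        self.stride = stride
        self.padding = padding
        self.kernel_size = k

    def _im2col(self, x):
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._padded_shape = x.shape
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, oh, ow, k, k) -> (N, oh, ow, C, k, k)
        self._oh, self._ow = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(
            x.shape[0] * self._oh * self._ow, -1
        )
        return np.ascontiguousarray(cols)

    def forward(self, x):
        n = x.shape[0]
        cols = self._im2col(x)
        self._cols = cols
        self._n = n
        wmat = self.W.reshape(self.W.shape[0], -1)
        y = cols @ wmat.T + self.b
        return y.reshape(n, self._oh, self._ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        k, s, p = self.kernel_size, self.stride, self.padding
        n = self._n
        dymat = dy.transpose(0, 2, 3, 1).reshape(-1, self.W.shape[0])
        wmat = self.W.reshape(self.W.shape[0], -1)
        dW = (dymat.T @ self._cols).reshape(self.W.shape)
        db = dymat.sum(axis=0)
        self.grads = [dW, db]
        dcols = (dymat @ wmat).reshape(n, self._oh, self._ow, -1, k, k)
        dx_pad = np.zeros(self._padded_shape, dtype=np.float64)
        for i in range(k):
            for j in range(k):
                dx_pad[
                    :, :, i : i + self._oh * s : s, j : j + self._ow * s : s
                ] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            dx_pad = dx_pad[:, :, p:-p, p:-p]
        return dx_pad.astype(np.float32)


class Sequential:
    """Layer stack; parameterized layers form the ordered layer groups."""

    def __init__(self, layers: list[_Layer]):
        self.layers = layers

    @property
    def param_groups(self) -> list[_Layer]:
        return [l for l in self.layers if l.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def get_state(self) -> list[np.ndarray]:
        return [g.get_flat() for g in self.param_groups]

    def set_state(self, state: list[np.ndarray]) -> None:
        for g, vec in zip(self.param_groups, state, strict=True):
            g.set_flat(vec)

    def checksum(self) -> float:
        return float(sum(np.abs(v).sum() for v in self.get_state()))


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(probs[np.arange(n), y] + eps).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class NetClassifier:
    """A Sequential net paired with the cross-entropy data loss.

    ``loss_and_grads`` returns the batch data loss (no penalty term) and the
    per-group flat gradients; the trainer adds the weight-decay contribution
    so the objective stays J = mean loss + lambda * ||theta||^2.
    """

    def __init__(self, net: Sequential):
        self.net = net

    @property
    def param_groups(self):
        return self.net.param_groups

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        return self.net.forward(X.astype(np.float32))

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(X), batch_size):
            out.append(np.argmax(self.predict_logits(X[i : i + batch_size]), axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, grad_scale: float = 1.0):
        logits = self.net.forward(X.astype(np.float32))
        loss, dlogits = softmax_cross_entropy(logits, y)
        self.net.backward((dlogits * grad_scale).astype(np.float32))
        grads = [g.grad_flat() for g in self.param_groups]
        return loss, grads

    def get_state(self):
        return self.net.get_state()

    def set_state(self, state):
        self.net.set_state(state)


def SmallCNN(
    side: int,
    n_classes: int,
    seed: int = 0,
    channels: tuple[int, ...] = (8, 16),
) -> NetClassifier:
    """Strided conv blocks + coarse average pooling + linear head.

    The head sees a coarsely pooled spatial map rather than a global
    average, so position-coded class structure stays visible.  Parameter
    groups follow registration order (head last), exercising the layer-wise
    rate spread of DFT end to end.  ``side`` must be divisible by
    ``2 ** (len(channels) + 1)``.
    """
    rng = np.random.default_rng(seed)
    layers: list[_Layer] = []
    c_in = 1
    for c_out in channels:
        layers += [Conv2d(c_in, c_out, 3, rng, stride=2, padding=1), ReLU()]
        c_in = c_out
    feat_side = side // (2 ** len(channels) * 2)
    layers += [AvgPool2d(2), Flatten(),
               Dense(c_in * feat_side * feat_side, n_classes, rng)]
    return NetClassifier(Sequential(layers))


def replace_head(model: NetClassifier, n_classes: int, seed: int = 0) -> NetClassifier:
    """Swap the final Dense layer for a fresh ``n_classes``-way head.

    All other weights are untouched.  Raises :class:`HeadNotFoundError` when
    the last parameterized layer is not a Dense classifier.
    """
    groups = model.net.param_groups
    if not groups or not isinstance(groups[-1], Dense):
        raise HeadNotFoundError("model's last parameter group is not a Dense head")
    old = groups[-1]
    rng = np.random.default_rng(seed)
    new = Dense(old.in_features, n_classes, rng)
    idx = model.net.layers.index(old)
    model.net.layers[idx] = new
    return model
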