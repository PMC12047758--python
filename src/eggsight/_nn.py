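"""Minimal CNN engine: layers, backprop, and SGD with momentum.

All tensors are channel-first ``(N, C, H, W)`` numpy arrays.  The engine is
deliberately small — 3x3 same-padding convolutions, 2x2 max pooling, dense
layers — which is exactly the vocabulary a VGG-style block architecture
needs.  Every layer caches its forward inputs so that gradients can be
requested not only for parameters but for any intermediate activation,
which is what class-activation mapping requires.

Float32 is the default compute dtype; float64 is supported for
finite-difference verification of the backward passes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Conv3x3",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Sequential",
    "SGDMomentum",
    "softmax",
    "cross_entropy_grad",
]

_OFFSETS = [(di, dj) for di in range(3) for dj in range(3)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits.

    ``y`` holds integer class indices.
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.log(p[np.arange(n), y] + eps).mean())
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return loss, g / n


class Layer:
    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same-padding, via im2col + GEMM.

    Borders are replicate-padded rather than zero-padded: on images whose
    frame borders are plain backdrop this keeps border activations
    statistically identical to interior ones, so saliency maps carry no
    frame-edge artifacts.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        std = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, std, size=(c_out, c_in * 9)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.c_in, self.c_out = c_in, c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="edge")
        patches = np.stack(
            [xp[:, :, di:di + h, dj:dj + w] for di, dj in _OFFSETS], axis=2
        )  # (N, C, 9, H, W)
        return np.ascontiguousarray(patches.reshape(n, c * 9, h * w))

    def forward(self, x, cache=False):
        n, c, h, w = x.shape
        cols = self._im2col(x)
        out = np.matmul(self.W[None], cols)  # (N, c_out, H*W)
        out += self.b[None, :, None]
        if cache:
            self._cols, self._shape = cols, x.shape
        return out.reshape(n, self.c_out, h, w)

    def backward(self, dy):
        n, c, h, w = self._shape
        dyf = dy.reshape(n, self.c_out, h * w)
        self.dW = np.einsum("nop,nfp->of", dyf, self._cols, optimize=True)
        self.db = dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T[None], dyf)  # (N, c_in*9, H*W)
        dcols = dcols.reshape(n, c, 9, h, w)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=dy.dtype)
        for k, (di, dj) in enumerate(_OFFSETS):
            dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, k]
        # adjoint of replicate padding: fold pad-border gradients back in
        dx = dxp[:, :, 1:-1, 1:-1].copy()
        dx[:, :, 0, :] += dxp[:, :, 0, 1:-1]
        dx[:, :, -1, :] += dxp[:, :, -1, 1:-1]
        dx[:, :, :, 0] += dxp[:, :, 1:-1, 0]
        dx[:, :, :, -1] += dxp[:, :, 1:-1, -1]
        dx[:, :, 0, 0] += dxp[:, :, 0, 0]
        dx[:, :, 0, -1] += dxp[:, :, 0, -1]
        dx[:, :, -1, 0] += dxp[:, :, -1, 0]
        dx[:, :, -1, -1] += dxp[:, :, -1, -1]
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, cache=False):
        out = np.maximum(x, 0)
        if cache:
            self._mask = x > 0
        return out

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    def forward(self, x, cache=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        if cache:
            self._arg = xr.argmax(axis=-1)
            self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return flat.reshape(n, c, h, w)


class Flatten(Layer):
    def forward(self, x, cache=False):
        if cache:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        std = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, std, size=(n_out, n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, cache=False):
        if cache:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.W

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, cache=cache)
        return x

    def backward(self, dy: np.ndarray, stop_after: int = 0) -> np.ndarray:
        """Backpropagate ``dy`` from the top down to (and including) layer
        index ``stop_after``; returns the gradient w.r.t. that layer's input.

        Requires a preceding cached forward pass.
        """
        for layer in reversed(self.layers[stop_after:]):
            dy = layer.backward(dy)
        return dy

    def activation_grad(self, x: np.ndarray, layer_index: int,
                        dy_top: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (activation, gradient) at the output of ``layer_index``.

        ``dy_top`` is the upstream gradient on the network output (e.g. a
        one-hot class selector on the logits).
        """
        a = x
        target = None
        for i, layer in enumerate(self.layers):
            a = layer.forward(a, cache=True)
            if i == layer_index:
                target = a
        dy = dy_top
        for layer in reversed(self.layers[layer_index + 1:]):
            dy = layer.backward(dy)
        return target, dy

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p[...] = state[f"p{i}"]

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_params(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), values):
            p[...] = v


class SGDMomentum:
    """Classic momentum SGD: v <- mu*v - lr*g ; p <- p + v."""

    def __init__(self, params: list[np.ndarray], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.v):
            v *= self.momentum
            v -= self.lr * g
            p += v
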