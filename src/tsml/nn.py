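"""Minimal NumPy layer framework for the student networks.

The backbones in this package are small convolutional classifiers that
must train on a single CPU, so the layer set is deliberately compact:
same-padding 3x3 convolutions, 2x2 max pooling, global average pooling
and a dense head, with hand-written backward passes.  Tensors are NHWC
``float32``; convolutions are evaluated as nine shifted GEMMs, which is
substantially faster in NumPy than an im2col copy at these sizes.

Every layer reports its multiply-accumulate (MAC) count for a given
input shape, which is what :func:`tsml.backbones.count_flops` sums.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "SGD",
]

logger = logging.getLogger(__name__)


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def macs(self, in_shape: tuple) -> tuple[int, tuple]:
        """(MAC count, output shape) for one sample of ``in_shape``."""
        return 0, in_shape


class Conv2d(Layer):
    """3x3 (or kxk) same-padding, stride-1 convolution in NHWC."""

    def __init__(self, cin: int, cout: int, k: int = 3, *, rng: np.random.Generator):
        if k % 2 != 1:
            raise InvalidInputError("kernel size must be odd for same padding")
        self.cin, self.cout, self.k = cin, cout, k
        std = np.sqrt(2.0 / (k * k * cin))
        w = (rng.standard_normal((k, k, cin, cout)) * std).astype(np.float32)
        self.W = Param("W", w)
        self.b = Param("b", np.zeros(cout, dtype=np.float32))
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[3] != self.cin:
            raise InvalidInputError(
                f"conv expects NHWC input with {self.cin} channels, got shape {x.shape}"
            )
        N, H, W, _ = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.empty((N, H, W, self.cout), dtype=np.float32)
        out[:] = self.b.value
        acc = out.reshape(-1, self.cout)
        for i in range(self.k):
            for j in range(self.k):
                xs = xp[:, i : i + H, j : j + W, :].reshape(-1, self.cin)
                acc += xs @ self.W.value[i, j]
        self._xp = xp
        return out

    def backward(self, g: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        xp = self._xp
        N, Hp, Wp, _ = xp.shape
        p = self.k // 2
        H, W = Hp - 2 * p, Wp - 2 * p
        gf = g.reshape(-1, self.cout)
        self.b.grad += gf.sum(axis=0)
        dxp = np.zeros_like(xp) if need_input_grad else None
        for i in range(self.k):
            for j in range(self.k):
                xs = xp[:, i : i + H, j : j + W, :].reshape(-1, self.cin)
                self.W.grad[i, j] += xs.T @ gf
                if need_input_grad:
                    dxp[:, i : i + H, j : j + W, :] += (
                        gf @ self.W.value[i, j].T
                    ).reshape(N, H, W, self.cin)
        self._xp = None
        if not need_input_grad:
            return g  # placeholder; the chain ends here
        return dxp[:, p : p + H, p : p + W, :] if p else dxp

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def macs(self, in_shape: tuple) -> tuple[int, tuple]:
        H, W, _ = in_shape
        return H * W * self.k * self.k * self.cin * self.cout, (H, W, self.cout)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0)


class MaxPool2(Layer):
    """2x2, stride-2 max pooling; gradient routed to the window argmax."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, H, W, C = x.shape
        if H % 2 or W % 2:
            raise InvalidInputError(f"pooling needs even spatial dims, got {H}x{W}")
        win = x.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(N, H // 2, W // 2, C, 4)
        self._argmax = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        N, H, W, C = self._in_shape
        onehot = (
            self._argmax[..., None] == np.arange(4, dtype=self._argmax.dtype)
        ).astype(g.dtype)
        gw = g[..., None] * onehot  # N,H/2,W/2,C,4
        gw = gw.reshape(N, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(gw.reshape(N, H, W, C))

    def macs(self, in_shape: tuple) -> tuple[int, tuple]:
        H, W, C = in_shape
        return 0, (H // 2, W // 2, C)


class GlobalAvgPool(Layer):
    """NHWC -> NC spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g: np.ndarray) -> np.ndarray:
        N, H, W, C = self._in_shape
        return np.broadcast_to(g[:, None, None, :] / (H * W), (N, H, W, C)).astype(
            g.dtype
        )

    def macs(self, in_shape: tuple) -> tuple[int, tuple]:
        H, W, C = in_shape
        return 0, (C,)


class Dense(Layer):
    def __init__(self, din: int, dout: int, *, rng: np.random.Generator):
        self.din, self.dout = din, dout
        std = np.sqrt(2.0 / din)
        self.W = Param("W", (rng.standard_normal((din, dout)) * std).astype(np.float32))
        self.b = Param("b", np.zeros(dout, dtype=np.float32))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.din:
            raise InvalidInputError(
                f"dense expects (N, {self.din}) input, got shape {x.shape}"
            )
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        self._x = None
        return g @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def macs(self, in_shape: tuple) -> tuple[int, tuple]:
        return self.din * self.dout, (self.dout,)


class Sequential(Layer):
    def __init__(self, layers: list[Layer], *, in_channels: int, num_classes: int):
        self.layers = layers
        self.in_channels = in_channels
        self.num_classes = num_classes

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        # the input itself needs no gradient, so the first convolution can
        # skip its (expensive) input-gradient accumulation
        for i, layer in zip(range(len(self.layers) - 1, -1, -1),
                            reversed(self.layers)):
            if i == 0 and isinstance(layer, Conv2d):
                return layer.backward(g, need_input_grad=False)
            g = layer.backward(g)
        return g

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad.fill(0)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"{i}.{p.name}": p.value.copy()
            for i, layer in enumerate(self.layers)
            for p in layer.params()
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {
            f"{i}.{p.name}": p
            for i, layer in enumerate(self.layers)
            for p in layer.params()
        }
        if set(own) != set(state):
            raise InvalidInputError(
                f"state dict keys {sorted(state)} do not match network {sorted(own)}"
            )
        for k, p in own.items():
            if state[k].shape != p.value.shape:
                raise InvalidInputError(f"shape mismatch for {k}")
            p.value[...] = state[k]


class SGD:
    """Gradient descent with classical momentum: v <- mu v - lr g; w <- w + v."""

    def __init__(self, net: Sequential, lr: float, momentum: float = 0.9):
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in net.params()]

    def step(self) -> None:
        for v, p in zip(self.velocity, self.net.params()):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v

    def state(self) -> list[np.ndarray]:
        return [v.copy() for v in self.velocity]

    def load_state(self, state: list[np.ndarray]) -> None:
        if len(state) != len(self.velocity):
            raise InvalidInputError("optimizer state length mismatch")
        for v, s in zip(self.velocity, state):
            v[...] = s
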