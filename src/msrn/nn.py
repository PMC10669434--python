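"""Minimal NumPy neural-network core used by the SRN builders.

Implements exactly the pieces the OCT classifiers need — 2-D convolution
(stride 1, zero 'same' padding), 2x2 max-pooling, ReLU, global average
pooling, a fully connected layer — together with manual backpropagation
and an SGD optimizer with momentum and weight decay.  Convolutions are
evaluated as a single GEMM per layer via an im2col lowering, in float32.

All parameter initialization is funneled through a ``numpy.random.Generator``
so that two builds from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    # He fan-in scaling for ReLU networks
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """Square convolution, stride 1, zero padding k//2 ('same' output size).

    Weight layout is (out_channels, in_channels, k, k); a flattened
    (in_channels*k*k, out_channels) view is kept for the GEMM.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 name: str = "conv") -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = int(kernel_size)
        if rng is None:
            rng = np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        w = kaiming_normal(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_channels), f"{name}.bias") if bias else None
        # set False on a network's first layer: its input gradient is never used
        self.needs_input_grad = True
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    @property
    def _wmat(self) -> np.ndarray:
        # (Cin*k*k, Cout)
        return self.weight.value.reshape(self.out_channels, -1).T

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        """Zero-pad by k//2 and lower to (N*H*W, C*k*k) patch rows."""
        n, c, h, w = x.shape
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x, self.kernel_size)
        y = cols @ self._wmat
        if self.bias is not None:
            y += self.bias.value
        if train:
            self._cols = cols
            self._in_shape = (n, c, h, w)
        return y.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        assert self._cols is not None, "forward(train=True) required before backward"
        n, c, h, w = self._in_shape
        k = self.kernel_size
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * h * w, self.out_channels)
        dw = (self._cols.T @ dyr).T.reshape(self.weight.value.shape)
        self.weight.grad += dw
        if self.bias is not None:
            self.bias.grad += dyr.sum(axis=0)
        self._cols = None
        if not self.needs_input_grad:
            return None
        # dx is the correlation of dy with spatially flipped, transposed kernels
        dy4 = np.ascontiguousarray(dy, dtype=DTYPE)
        dcols = self._im2col(dy4, k)
        wt = self.weight.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin,Cout,k,k)
        dx = dcols @ wt.reshape(c, -1).T
        return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2x2(Layer):
    """2x2, stride 2, floor mode: a trailing odd row/column is dropped."""

    def __init__(self) -> None:
        self._argmax: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, :h2 * 2, :w2 * 2]
        win = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._argmax = idx
            self._in_shape = (n, c, h, w)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        dwin = np.zeros((n, c, h2, w2, 4), dtype=DTYPE)
        np.put_along_axis(dwin, self._argmax[..., None], dy[..., None].astype(DTYPE), axis=-1)
        dx = np.zeros((n, c, h, w), dtype=DTYPE)
        dx[:, :, :h2 * 2, :w2 * 2] = (
            dwin.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx


class GlobalAvgPool(Layer):
    """Spatial mean, (N, C, H, W) -> (N, C)."""

    def __init__(self) -> None:
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), (n, c, h, w)).astype(DTYPE)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = "fc") -> None:
        if rng is None:
            rng = np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Param(kaiming_normal(rng, (in_features, out_features), in_features),
                            f"{name}.weight")
        self.bias = Param(np.zeros(out_features), f"{name}.bias") if bias else None
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        y = x @ self.weight.value
        if self.bias is not None:
            y = y + self.bias.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dy
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value.T


class SGD:
    """SGD with classical momentum and decoupled-from-nothing L2 weight decay:
    v <- mu*v + (g + wd*w);  w <- w - lr*v.
    """

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= self.lr * v


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def state_dict(params: list[Param]) -> dict[str, np.ndarray]:
    return {f"{i}:{p.name}": p.value.copy() for i, p in enumerate(params)}


def load_state_dict(params: list[Param], state: dict[str, np.ndarray]) -> None:
    if len(state) != len(params):
        raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
    for i, p in enumerate(params):
        key = f"{i}:{p.name}"
        if key not in state:
            raise KeyError(f"missing parameter {key}")
        if state[key].shape != p.value.shape:
            raise ValueError(f"shape mismatch for {key}")
        p.value[...] = state[key]
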