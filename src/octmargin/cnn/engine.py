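"""Minimal numpy CNN engine (NHWC, float32) with exact backpropagation.

Implements the handful of layer types the patch classifier needs — 3×3
same-padding convolution, ReLU, 2×2 max-pooling, flatten, dense, inverted
dropout — plus softmax cross-entropy and Adam. Convolutions run as BLAS
matrix products: a materialized im2col for shallow inputs, nine shifted
accumulating products otherwise. Layers keep persistent scratch buffers so
steady-state training does not churn hundreds of megabytes of allocations
per step (a first-class concern on the single-core targets this classifier
is meant for). Gradients are exact and verified against finite differences
in the test suite; all randomness flows through explicitly passed
generators.

Note on ReLU: the subgradient convention ReLU'(0) = 0 is used, so
finite-difference checks must avoid parameter points that place
pre-activations exactly at the kink (e.g. freshly zero-initialized biases
with all-zero input windows).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Dropout",
    "Network",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class _Scratch:
    """Named, shape-checked reusable buffers."""

    def __init__(self):
        self._bufs: dict[str, np.ndarray] = {}

    def get(self, name: str, shape: tuple[int, ...], dtype=np.float32) -> np.ndarray:
        buf = self._bufs.get(name)
        if buf is None or buf.shape != shape or buf.dtype != dtype:
            buf = np.empty(shape, dtype)
            self._bufs[name] = buf
        return buf


class Conv2D:
    """3×3 convolution, stride 1, zero padding 1 (spatial size preserved).

    ``needs_input_grad=False`` (set on the first layer of a network) skips
    the input-gradient pass entirely.
    """

    # Below this input-channel count a materialized im2col + single GEMM is
    # cheaper than nine accumulating products (the wide shallow first layer).
    _IM2COL_MAX_CIN = 2

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 needs_input_grad: bool = True):
        fan_in = 9 * in_channels
        self.W = (rng.standard_normal((3, 3, in_channels, out_channels)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.needs_input_grad = needs_input_grad
        self._scratch = _Scratch()
        self._xpad: np.ndarray | None = None
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int, int, int] | None = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xpad = self._scratch.get("xpad", (n, h + 2, w + 2, c), x.dtype)
        xpad[:, 0, :, :] = 0
        xpad[:, -1, :, :] = 0
        xpad[:, :, 0, :] = 0
        xpad[:, :, -1, :] = 0
        xpad[:, 1 : h + 1, 1 : w + 1, :] = x
        return xpad

    def _im2col(self, xpad: np.ndarray, n: int, h: int, w: int, c: int) -> np.ndarray:
        sw = np.lib.stride_tricks.sliding_window_view(xpad, (3, 3), axis=(1, 2))
        cols = self._scratch.get("cols", (n, h, w, 3, 3, c), xpad.dtype)
        # rows indexed by (ky, kx, c) to match the (3, 3, c_in, c_out) W layout
        np.copyto(cols, sw.transpose(0, 1, 2, 4, 5, 3))
        return cols.reshape(n * h * w, 9 * c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.W.shape[2]:
            raise ValueError(f"expected {self.W.shape[2]} input channels, got {c}")
        f = self.W.shape[3]
        xpad = self._pad(np.asarray(x, dtype=self.W.dtype))
        self._xpad, self._shape = xpad, (n, h, w, c)
        y = self._scratch.get("y", (n * h * w, f), self.W.dtype)
        if c <= self._IM2COL_MAX_CIN:
            self._cols = self._im2col(xpad, n, h, w, c)
            np.matmul(self._cols, self.W.reshape(9 * c, f), out=y)
            y += self.b
        else:
            self._cols = None
            tmp = self._scratch.get("ytmp", (n * h * w, f), self.W.dtype)
            y[:] = self.b
            for ky in range(3):
                for kx in range(3):
                    xs = self._shift(xpad, ky, kx, n, h, w, c)
                    np.matmul(xs, self.W[ky, kx], out=tmp)
                    y += tmp
        return y.reshape(n, h, w, f)

    def _shift(self, xpad: np.ndarray, ky: int, kx: int,
               n: int, h: int, w: int, c: int) -> np.ndarray:
        xs = self._scratch.get("xs", (n, h, w, c), xpad.dtype)
        np.copyto(xs, xpad[:, ky : ky + h, kx : kx + w, :])
        return xs.reshape(n * h * w, c)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        f = self.W.shape[3]
        dyf = np.ascontiguousarray(dy, dtype=self.W.dtype).reshape(n * h * w, f)
        self.db[...] = dyf.sum(axis=0)
        if self._cols is not None:
            self.dW[...] = (self._cols.T @ dyf).reshape(3, 3, c, f)
        else:
            for ky in range(3):
                for kx in range(3):
                    xs = self._shift(self._xpad, ky, kx, n, h, w, c)
                    self.dW[ky, kx] = xs.T @ dyf
        if not self.needs_input_grad:
            self._xpad = self._cols = None
            return np.zeros((n, h, w, c), dtype=dyf.dtype)
        dxpad = self._scratch.get("dxpad", self._xpad.shape, dyf.dtype)
        dxpad[...] = 0
        tmp = self._scratch.get("dxtmp", (n * h * w, c), dyf.dtype)
        for ky in range(3):
            for kx in range(3):
                np.matmul(dyf, self.W[ky, kx].T, out=tmp)
                dxpad[:, ky : ky + h, kx : kx + w, :] += tmp.reshape(n, h, w, c)
        self._xpad = self._cols = None
        return dxpad[:, 1 : h + 1, 1 : w + 1, :]


class ReLU:
    def __init__(self):
        self._scratch = _Scratch()
        self._out: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self._scratch.get("out", x.shape, x.dtype)
        np.maximum(x, 0, out=out)
        self._out = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self._scratch.get("dx", dy.shape, dy.dtype)
        np.multiply(dy, self._out > 0, out=dx)
        self._out = None
        return dx


class MaxPool2:
    """2×2 max pooling, stride 2; odd trailing rows/columns are dropped.

    Gradient routing uses the four strided quadrant views; on ties the
    earliest cell in (row, column) scan order receives the gradient.
    """

    def __init__(self):
        self._scratch = _Scratch()
        self._x: np.ndarray | None = None
        self._out: np.ndarray | None = None

    def params(self):
        return []

    @staticmethod
    def _quadrants(x: np.ndarray):
        h2, w2 = x.shape[1] // 2, x.shape[2] // 2
        xc = x[:, : h2 * 2, : w2 * 2, :]
        return (xc[:, 0::2, 0::2, :], xc[:, 0::2, 1::2, :],
                xc[:, 1::2, 0::2, :], xc[:, 1::2, 1::2, :])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        a, b, c_, d = self._quadrants(x)
        out = self._scratch.get("out", a.shape, x.dtype)
        np.maximum(a, b, out=out)
        np.maximum(out, c_, out=out)
        np.maximum(out, d, out=out)
        self._x, self._out = x, out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, out = self._x, self._out
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        dx = self._scratch.get("dx", x.shape, dy.dtype)
        if h % 2:
            dx[:, h2 * 2 :, :, :] = 0
        if w % 2:
            dx[:, :, w2 * 2 :, :] = 0
        remaining = self._scratch.get("rem", dy.shape, bool)
        remaining[...] = True
        hit = self._scratch.get("hit", dy.shape, bool)
        routed = self._scratch.get("routed", dy.shape, dy.dtype)
        for src, dst in zip(self._quadrants(x), self._quadrants(dx)):
            np.equal(src, out, out=hit)
            hit &= remaining
            np.multiply(dy, hit, out=routed)
            dst[...] = routed
            remaining &= ~hit
        self._x = self._out = None
        return dx


class Flatten:
    def __init__(self):
        self._shape: tuple[int, ...] | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((in_features, out_features)) *
                  np.sqrt(2.0 / in_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.W.shape[0]:
            raise ValueError(f"expected {self.W.shape[0]} features, got {x.shape[1]}")
        self._x = x.copy()  # Flatten passes a reshaped scratch view; snapshot it
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.asarray(dy, dtype=self.W.dtype)
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx


class Dropout:
    """Inverted dropout; identity at rate 0 or in inference mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._rng = rng
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean weighted CE loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=np.float64)
    loss = float(-(w * np.log(np.clip(p[np.arange(n), y], 1e-12, None))).sum() / w.sum())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / w.sum())[:, None]
    return loss, dlogits.astype(np.float32)


class Network:
    """A plain sequence of layers with forward, backward, and weight I/O."""

    def __init__(self, layers: list):
        self.layers = layers

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray, stop_at: int = 0) -> np.ndarray:
        """Backpropagate to (and excluding) layer ``stop_at``; returns the
        gradient flowing into layer ``stop_at``'s output."""
        for layer in reversed(self.layers[stop_at:]):
            dy = layer.backward(dy)
        return dy

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list does not match the network")
        for (p, _), w in zip(own, weights):
            p[...] = w


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
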