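"""Compact numpy neural-network core.

Implements exactly the layer set needed by the leaf-identification models:
valid-mode stride-1 2-D convolution, non-overlapping max-pooling, ReLU,
global average pooling, dense layers, softmax cross-entropy, and the Adam
optimizer.  Arrays are NHWC ``float32`` by default (``float64`` is supported
for gradient checking).  All randomness flows through an explicit
``numpy.random.Generator`` so every forward/backward pass is reproducible.

Convolutions are computed as a loop over kernel offsets, each step a single
GEMM; this keeps peak memory proportional to the activations rather than to
an im2col buffer, which matters when a whole pair batch is pushed through
the network at once.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "MaxPool2D",
    "ReLU",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Layer:
    """Base class: a differentiable map with optional trainable parameters."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Valid (no padding), stride-1 convolution, NHWC layout.

    Weights ``W`` have shape ``(k, k, c_in, c_out)`` and are He-initialized
    (zero biases), the standard choice for ReLU trunks.  The forward pass
    lowers the convolution to one GEMM over an im2col patch matrix, which
    is cached during training for the weight-gradient GEMM; the input
    gradient folds the patch gradients back with a loop of slice adds.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        k = int(kernel_size)
        fan_in = k * k * in_channels
        std = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, size=(k, k, in_channels, out_channels)).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel_size = k
        self._cols: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _im2col(self, x):
        # (N,H,W,C) -> (N*hc*wc, k*k*C), patch rows ordered (u, v, channel)
        k = self.kernel_size
        n, h, w, c = x.shape
        hc, wc = h - k + 1, w - k + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        # win: (N, hc, wc, C, k, k) -> (N, hc, wc, k, k, C)
        return win.transpose(0, 1, 2, 4, 5, 3).reshape(n * hc * wc, k * k * c)

    def forward(self, x, train=False):
        k = self.kernel_size
        n, h, w, c = x.shape
        if h < k or w < k:
            raise ValueError(f"input {h}x{w} smaller than kernel {k}x{k}")
        hc, wc = h - k + 1, w - k + 1
        f = self.W.shape[-1]
        cols = self._im2col(x)
        out = (cols @ self.W.reshape(-1, f) + self.b).reshape(n, hc, wc, f)
        if train:
            self._cols, self._xshape = cols, x.shape
        else:
            self._cols = None
        return out

    def backward(self, dout):
        cols = self._cols
        if cols is None:
            raise RuntimeError("backward before forward(train=True)")
        k = self.kernel_size
        n, h, w, c = self._xshape
        hc, wc, f = dout.shape[1], dout.shape[2], dout.shape[3]
        dflat = dout.reshape(-1, f)
        self.dW += (cols.T @ dflat).reshape(self.dW.shape)
        self.db += dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(-1, f).T).reshape(n, hc, wc, k, k, c)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        for u in range(k):
            for v in range(k):
                dx[:, u:u + hc, v:v + wc, :] += dcols[:, :, :, u, v, :]
        return dx


class MaxPool2D(Layer):
    """Non-overlapping max pooling (pool size equals stride).

    Trailing rows/columns that do not fill a full window are dropped, the
    convention of the frameworks this mirrors.  Gradients route to the first
    maximal element of each window.
    """

    def __init__(self, pool_size: int = 2, stride: int | None = None):
        stride = pool_size if stride is None else stride
        if stride != pool_size:
            raise NotImplementedError("only pool_size == stride is supported")
        self.p = int(pool_size)

    def forward(self, x, train=False):
        p = self.p
        n, h, w, c = x.shape
        hp, wp = h // p, w // p
        if hp == 0 or wp == 0:
            raise ValueError(f"input {h}x{w} smaller than pool {p}x{p}")
        xc = x[:, :hp * p, :wp * p, :]
        xw = (xc.reshape(n, hp, p, wp, p, c)
                .transpose(0, 1, 3, 5, 2, 4)
                .reshape(n, hp, wp, c, p * p))
        idx = xw.argmax(axis=-1)
        out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, (n, h, w, c)
        return out

    def backward(self, dout):
        p = self.p
        n, h, w, c = self._shape
        hp, wp = h // p, w // p
        dxw = np.zeros((n, hp, wp, c, p * p), dtype=dout.dtype)
        np.put_along_axis(dxw, self._idx[..., None], dout[..., None], axis=-1)
        dxc = (dxw.reshape(n, hp, wp, c, p, p)
                  .transpose(0, 1, 4, 2, 5, 3)
                  .reshape(n, hp * p, wp * p, c))
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, :hp * p, :wp * p, :] = dxc
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class GlobalAvgPool(Layer):
    """Average each channel over the spatial grid: (N,H,W,C) -> (N,C)."""

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :], (n, h, w, c)) / (h * w)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(2.0 / in_features)
        self.W = rng.normal(0.0, std, size=(in_features, out_features)).astype(dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout

    def zero_grad(self):
        for g in self.grads():
            g[...] = 0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for i, p in enumerate(params):
            src = state[f"p{i}"]
            if src.shape != p.shape:
                raise ValueError(f"shape mismatch for p{i}: {src.shape} vs {p.shape}")
            p[...] = src


class Adam:
    """Adam optimizer updating a fixed list of (param, grad) arrays in place."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-5, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grad_arrays = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grad_arrays, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch and its gradient w.r.t. the logits.

    ``labels`` are integer class indices.  Returns ``(loss, dlogits)``.
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n
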