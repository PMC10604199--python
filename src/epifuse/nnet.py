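"""Minimal seeded neural-network engine (3D/1D convolutions, numpy).

Implements exactly the layer vocabulary the fusion classifier needs:
3D and 1D convolution (kernel 3, stride 1, same padding), max/average
pooling with ceil-mode shape handling, ReLU, dropout, batch
normalisation over the spatial/length axis, dense layers and plain SGD
on a binary cross-entropy objective.  Forward and backward passes are
written against ``float32`` arrays with an im2col formulation so the
heavy work is a single matmul per layer.

All randomness (weight initialisation, dropout masks) flows from one
``numpy.random.Generator`` so that build + train + predict is exactly
reproducible for a fixed seed on a fixed machine.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def bce_from_logit(logit: float, y: int, eps: float = 1e-12) -> float:
    """Binary cross-entropy of a single logit against a 0/1 label."""
    p = float(sigmoid(logit))
    p = min(max(p, eps), 1.0 - eps)
    return -(y * np.log(p) + (1 - y) * np.log(1.0 - p))


class Layer:
    """Base class: stateless layers override forward/backward only."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient-accumulator) pairs."""
        return []

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0


# ---------------------------------------------------------------- conv


class Conv3d(Layer):
    """3D convolution, kernel ``k``, stride 1, zero same-padding.

    Input/output layout is channels-first: (C, D, H, W).
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = in_ch * k ** 3
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = (rng.standard_normal((out_ch, fan_in)) * scale).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, training=False):
        c, d, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        # (C, D, H, W, k, k, k) -> (D*H*W, C*k^3)
        cols = np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
            d * h * w, c * k ** 3
        )
        self._cols, self._shape = cols, (c, d, h, w)
        out = cols @ self.W.T + self.b
        return out.T.reshape(self.out_ch, d, h, w)

    def backward(self, grad):
        c, d, h, w = self._shape
        k, p = self.k, self.k // 2
        gmat = grad.reshape(self.out_ch, -1).T  # (N, out_ch)
        self.dW += (gmat.T @ self._cols).astype(DTYPE)
        self.db += gmat.sum(axis=0).astype(DTYPE)
        dcols = (gmat @ self.W).reshape(d, h, w, c, k, k, k)
        dxp = np.zeros((c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    dxp[:, dz : dz + d, dy : dy + h, dx : dx + w] += (
                        dcols[:, :, :, :, dz, dy, dx].transpose(3, 0, 1, 2)
                    )
        return dxp[:, p : p + d, p : p + h, p : p + w]


class Conv1d(Layer):
    """1D convolution, kernel ``k``, stride 1, zero same-padding; layout (C, L)."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = in_ch * k
        scale = np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((out_ch, fan_in)) * scale).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, training=False):
        c, L = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        cols = np.ascontiguousarray(win.transpose(1, 0, 2)).reshape(L, c * k)
        self._cols, self._shape = cols, (c, L)
        return (cols @ self.W.T + self.b).T

    def backward(self, grad):
        c, L = self._shape
        k, p = self.k, self.k // 2
        gmat = grad.T  # (L, out_ch)
        self.dW += (gmat.T @ self._cols).astype(DTYPE)
        self.db += gmat.sum(axis=0).astype(DTYPE)
        dcols = (gmat @ self.W).reshape(L, c, k)
        dxp = np.zeros((c, L + 2 * p), dtype=DTYPE)
        for dx in range(k):
            dxp[:, dx : dx + L] += dcols[:, :, dx].T
        return dxp[:, p : p + L]


# ---------------------------------------------------------------- pooling


def _ceil_pad(n: int, s: int) -> int:
    return (-n) % s


class MaxPool3d(Layer):
    """Non-overlapping max pooling, ceil mode (-inf padding on the high side)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, training=False):
        s = self.size
        c, d, h, w = x.shape
        pd, ph, pw = (_ceil_pad(n, s) for n in (d, h, w))
        xp = np.pad(x, ((0, 0), (0, pd), (0, ph), (0, pw)), constant_values=-np.inf)
        do, ho, wo = (n // s for n in xp.shape[1:])
        blocks = (
            xp.reshape(c, do, s, ho, s, wo, s)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, do, ho, wo, s ** 3)
        )
        self._arg = blocks.argmax(axis=-1)
        self._inshape, self._padded = (c, d, h, w), xp.shape
        return blocks.max(axis=-1)

    def backward(self, grad):
        s = self.size
        c, d, h, w = self._inshape
        _, dp, hp, wp = self._padded
        do, ho, wo = dp // s, hp // s, wp // s
        dblocks = np.zeros((c, do, ho, wo, s ** 3), dtype=DTYPE)
        np.put_along_axis(dblocks, self._arg[..., None], grad[..., None], axis=-1)
        dxp = (
            dblocks.reshape(c, do, ho, wo, s, s, s)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, dp, hp, wp)
        )
        return dxp[:, :d, :h, :w]


class AvgPool3d(Layer):
    """Non-overlapping average pooling, ceil mode (zero padding, true-count divisor)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, training=False):
        s = self.size
        c, d, h, w = x.shape
        pd, ph, pw = (_ceil_pad(n, s) for n in (d, h, w))
        xp = np.pad(x, ((0, 0), (0, pd), (0, ph), (0, pw)))
        cnt = np.pad(np.ones((d, h, w), dtype=DTYPE), ((0, pd), (0, ph), (0, pw)))
        do, ho, wo = (n // s for n in xp.shape[1:])
        ssum = xp.reshape(c, do, s, ho, s, wo, s).sum(axis=(2, 4, 6))
        csum = cnt.reshape(do, s, ho, s, wo, s).sum(axis=(1, 3, 5))
        self._csum, self._inshape, self._padded = csum, (c, d, h, w), xp.shape
        return ssum / csum

    def backward(self, grad):
        s = self.size
        c, d, h, w = self._inshape
        g = (grad / self._csum)[:, :, None, :, None, :, None]
        dxp = np.broadcast_to(
            g, (c, grad.shape[1], s, grad.shape[2], s, grad.shape[3], s)
        ).reshape(self._padded)
        return np.ascontiguousarray(dxp[:, :d, :h, :w])


class MaxPool1d(Layer):
    """Non-overlapping 1D max pooling, ceil mode."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, training=False):
        s = self.size
        c, L = x.shape
        p = _ceil_pad(L, s)
        xp = np.pad(x, ((0, 0), (0, p)), constant_values=-np.inf)
        lo = xp.shape[1] // s
        blocks = xp.reshape(c, lo, s)
        self._arg, self._inshape, self._lo = blocks.argmax(axis=-1), (c, L), lo
        return blocks.max(axis=-1)

    def backward(self, grad):
        c, L = self._inshape
        s = self.size
        dblocks = np.zeros((c, self._lo, s), dtype=DTYPE)
        np.put_along_axis(dblocks, self._arg[..., None], grad[..., None], axis=-1)
        return dblocks.reshape(c, -1)[:, :L]


class GlobalAvgPool1d(Layer):
    def forward(self, x, training=False):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None], self._L, axis=1) / self._L


# ---------------------------------------------------------------- pointwise


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p, self.rng = p, rng
        self._mask: np.ndarray | float = 1.0

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class BatchNorm1d(Layer):
    """Per-channel normalisation over the length axis of a (C, L) map.

    With batch size 1 the statistics are the within-sample spatial
    moments; running averages are kept for evaluation mode.
    """

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=DTYPE)
        self.beta = np.zeros(ch, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(ch, dtype=DTYPE)
        self.run_var = np.ones(ch, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=1)
            var = x.var(axis=1)
            m = self.momentum
            self.run_mean[...] = (1 - m) * self.run_mean + m * mean
            self.run_var[...] = (1 - m) * self.run_var + m * var
        else:
            mean, var = self.run_mean, self.run_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[:, None]) * self._inv[:, None]
        return self.gamma[:, None] * self._xhat + self.beta[:, None]

    def backward(self, grad):
        L = grad.shape[1]
        self.dgamma += (grad * self._xhat).sum(axis=1).astype(DTYPE)
        self.dbeta += grad.sum(axis=1).astype(DTYPE)
        gx = grad * self.gamma[:, None]
        # training-mode statistics backward (mean/var depend on x)
        dxhat_sum = gx.sum(axis=1, keepdims=True)
        dxhat_dot = (gx * self._xhat).sum(axis=1, keepdims=True)
        return (self._inv[:, None] / L) * (L * gx - dxhat_sum - self._xhat * dxhat_dot)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(-1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer; ``scale=0.0`` zero-initialises the weights
    (useful for a final logit layer so training starts uncommitted)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        if scale is None:
            scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_out, n_in)) * scale).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, training=False):
        self._x = x
        return self.W @ x + self.b

    def backward(self, grad):
        self.dW += np.outer(grad, self._x).astype(DTYPE)
        self.db += grad.astype(DTYPE)
        return self.W.T @ grad


# ---------------------------------------------------------------- container


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class SGD:
    """Stochastic gradient descent with classical momentum.

    Momentum 0 recovers plain SGD; at batch size 1 a heavy-ball term
    smooths the per-subject gradient noise considerably.
    """

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        lr: float,
        momentum: float = 0.0,
    ):
        self.params, self.lr, self.momentum = params, lr, momentum
        self._vel = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        for (p, g), v in zip(self.params, self._vel):
            if self.momentum:
                v *= self.momentum
                v += g
                p -= self.lr * v
            else:
                p -= self.lr * g

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0


class Adam:
    """Adam optimiser (Kingma & Ba defaults for the moment decays).

    Per-parameter step normalisation makes training robust to the very
    different gradient scales of the convolutional and dense stages,
    which batch-size-1 SGD handles poorly.
    """

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params, self.lr = params, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p) for p, _ in params]
        self._v = [np.zeros_like(p) for p, _ in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for (p, g), m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0


def make_optimizer(
    name: str,
    params: list[tuple[np.ndarray, np.ndarray]],
    lr: float,
    momentum: float = 0.0,
):
    if name == "sgd":
        return SGD(params, lr=lr, momentum=momentum)
    if name == "adam":
        return Adam(params, lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")


def n_parameters(layer: Layer) -> int:
    return int(sum(p.size for p, _ in layer.params()))
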