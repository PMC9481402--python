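"""Self-contained numpy neural-network primitives.

Implements exactly the pieces the residual 1-D ConvNet needs — stride-1
"same" convolution (odd kernels), batch normalisation, tanh/ReLU,
inverted dropout, global average pooling, a dense layer and Adam — each
as a small layer object with ``forward``/``backward`` and accumulated
parameter gradients.

Activations are kept channels-last, ``(batch, length, channels)``:
under that layout the im2col patch matrix is gathered from contiguous
memory slabs and both convolution passes reduce to single BLAS matmuls
with no transposes.  The input gradient of a convolution is the same
machinery applied to the kernel flipped in tap order with input/output
channels swapped.  Compute is float32 by default (``dtype`` on each
layer); everything is deterministic given the seeds supplied by the
caller.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "BatchNorm1D",
    "Tanh",
    "ReLU",
    "Dropout",
    "GlobalAvgPool",
    "Dense",
    "Adam",
    "softmax",
]

DEFAULT_DTYPE = np.float32


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shift-invariant and overflow-safe."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B*L, k*C) patches under same-padding, stride 1.

    In channels-last layout the (k, C) patch of one output position is a
    single contiguous block of the padded input, so the reshape below is
    a fast slab copy rather than a strided gather.
    """
    b, l, c = x.shape
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B,L,C,k)
    return win.transpose(0, 1, 3, 2).reshape(b * l, k * c)


class Conv1D:
    """Stride-1 same-length 1-D convolution with an odd kernel.

    The kernel is stored as ``(k*c_in, c_out)`` so both the forward pass
    and the weight gradient are single matmuls against the patch matrix.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        dtype=DEFAULT_DTYPE,
    ):
        if kernel % 2 == 0:
            raise ValueError("only odd kernel sizes are supported")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        scale = np.sqrt(2.0 / (c_in * kernel))  # He initialisation
        self.W = rng.normal(0.0, scale, size=(kernel * c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, l, _ = x.shape
        cols = _im2col(x, self.kernel)
        if training:
            self._cols = cols
        return (cols @ self.W + self.b).reshape(b, l, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, l, _ = dout.shape
        dmat = dout.reshape(b * l, self.c_out)
        self.dW += self._cols.T @ dmat
        self.db += dmat.sum(axis=0)
        # dx = same-conv of dout with tap-flipped, channel-swapped kernels
        w = self.W.reshape(self.kernel, self.c_in, self.c_out)
        w_flip = np.ascontiguousarray(w[::-1].transpose(0, 2, 1)).reshape(
            self.kernel * self.c_out, self.c_in
        )
        dx = _im2col(dout, self.kernel) @ w_flip
        return dx.reshape(b, l, self.c_in)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm1D:
    """Per-channel batch normalisation over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=DEFAULT_DTYPE):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(x.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = dout.shape[0] * dout.shape[1]
        self.dgamma += (dout * xhat).sum(axis=(0, 1))
        self.dbeta += dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma
        s1 = dxhat.sum(axis=(0, 1))
        s2 = (dxhat * xhat).sum(axis=(0, 1))
        return (inv_std / m) * (m * dxhat - s1 - xhat * s2)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class Tanh:
    def forward(self, x, training):
        out = np.tanh(x)
        if training:
            self._out = out
        return out

    def backward(self, dout):
        return dout * (1.0 - self._out**2)

    def params(self):
        return []


class ReLU:
    def forward(self, x, training):
        if training:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class Dropout:
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class GlobalAvgPool:
    """(B, L, C) -> (B, C), averaging each channel over the window."""

    def forward(self, x, training):
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        return np.broadcast_to(
            dout[:, None, :] / self._length,
            (dout.shape[0], self._length, dout.shape[1]),
        )

    def params(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=DEFAULT_DTYPE):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Adam:
    """Adam optimiser over a flat list of (param, grad) pairs."""

    def __init__(self, param_pairs, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = param_pairs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in param_pairs]
        self.v = [np.zeros_like(p) for p, _ in param_pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grad(self) -> None:
        for _, g in self.pairs:
            g[...] = 0.0
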