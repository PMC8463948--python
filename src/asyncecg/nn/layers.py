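"""Minimal NumPy neural-network layers with hand-written backpropagation.

Only what the classifier needs: 1-D convolution with "same" padding and
stride, batch normalization, ReLU, dense layers, average pooling, and the
shape plumbing between them.  Forward passes cache what backward needs;
``backward(dy)`` returns the input gradient and accumulates parameter
gradients in ``grads`` (zeroed by the optimizer step).

All arithmetic is float32: the model is small and the speed matters on a
single CPU.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base: subclasses fill ``params``/``grads`` dicts with same-keyed arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def same_pad_amount(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(left, right, out_length) for "same" padding: out = ceil(len/stride)."""
    out_len = -(-length // stride)
    total = max((out_len - 1) * stride + kernel - length, 0)
    left = total // 2
    return left, total - left, out_len


class Conv1d(Layer):
    """1-D convolution, "same" padding, He-initialized."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        scale = np.sqrt(2.0 / (in_channels * kernel_size))
        self.params["w"] = (
            rng.normal(0, scale, (out_channels, in_channels, kernel_size))
        ).astype(DTYPE)
        self.params["b"] = np.zeros(out_channels, dtype=DTYPE)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self.grads["b"] = np.zeros_like(self.params["b"])

    def _im2col(self, xp: np.ndarray, out_len: int) -> np.ndarray:
        # (N, C, Lp) -> (N*out_len, C*k) rows of receptive fields
        k, s = self.kernel_size, self.stride
        windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        windows = windows[:, :, ::s][:, :, :out_len]  # (N, C, out_len, k)
        cols = windows.transpose(0, 2, 1, 3).reshape(
            xp.shape[0] * out_len, self.in_channels * k
        )
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, length = x.shape
        left, right, out_len = same_pad_amount(length, self.kernel_size, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        cols = self._im2col(xp, out_len)
        w2 = self.params["w"].reshape(self.out_channels, -1)
        y = cols @ w2.T + self.params["b"]
        y = y.reshape(n, out_len, self.out_channels).transpose(0, 2, 1)
        if train:
            self._cache = (xp, cols, left, length, out_len)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, cols, left, length, out_len = self._cache
        n = dy.shape[0]
        k, s = self.kernel_size, self.stride
        dy2 = dy.transpose(0, 2, 1).reshape(n * out_len, self.out_channels)
        w2 = self.params["w"].reshape(self.out_channels, -1)
        self.grads["w"] += (dy2.T @ cols).reshape(self.params["w"].shape)
        self.grads["b"] += dy2.sum(axis=0)
        dcols = (dy2 @ w2).reshape(n, out_len, self.in_channels, k)
        dxp = np.zeros_like(xp)
        for j in range(k):
            dxp[:, :, j : j + s * out_len : s] += dcols[:, :, :, j].transpose(
                0, 2, 1
            )
        return dxp[:, :, left : left + length]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.grads["gamma"] = np.zeros(channels, dtype=DTYPE)
        self.grads["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        g = self.params["gamma"][None, :, None]
        b = self.params["beta"][None, :, None]
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(DTYPE)
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None]) * invstd[None, :, None]
            self._cache = (xhat, invstd.astype(DTYPE))
            return (g * xhat + b).astype(DTYPE)
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None]) * invstd[None, :, None]
        return (g * xhat + b).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        n, _, length = dy.shape
        m = n * length
        dgamma = (dy * xhat).sum(axis=(0, 2))
        dbeta = dy.sum(axis=(0, 2))
        self.grads["gamma"] += dgamma
        self.grads["beta"] += dbeta
        g = self.params["gamma"]
        coef = (g * invstd / m)[None, :, None]
        return (
            coef * (m * dy - dbeta[None, :, None] - xhat * dgamma[None, :, None])
        ).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class AvgPool1d(Layer):
    """Average pooling with kernel == stride and ceil-mode output length.

    Matches the length arithmetic of a stride-``s`` "same"-padded conv
    (out = ceil(len/s)); a ragged final window averages only the samples
    it covers.
    """

    def __init__(self, stride: int) -> None:
        super().__init__()
        self.stride = stride

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = self.stride
        n, c, length = x.shape
        out_len = -(-length // s)
        full = length // s
        y = np.empty((n, c, out_len), dtype=x.dtype)
        if full:
            y[:, :, :full] = x[:, :, : full * s].reshape(n, c, full, s).mean(axis=3)
        if out_len > full:
            y[:, :, full] = x[:, :, full * s :].mean(axis=2)
        if train:
            self._shape = (length, full, out_len)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = self.stride
        length, full, out_len = self._shape
        n, c, _ = dy.shape
        dx = np.zeros((n, c, length), dtype=dy.dtype)
        if full:
            dx[:, :, : full * s] = np.repeat(dy[:, :, :full] / s, s, axis=2)
        if out_len > full:
            tail = length - full * s
            dx[:, :, full * s :] = dy[:, :, full][:, :, None] / tail
        return dx


class GlobalAvgPool(Layer):
    """Average over the length axis: (N, C, L) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._length, axis=2) / self._length


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.params["w"] = rng.normal(0, scale, (in_features, out_features)).astype(
            DTYPE
        )
        self.params["b"] = np.zeros(out_features, dtype=DTYPE)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self.grads["b"] = np.zeros_like(self.params["b"])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["w"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["w"].T


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
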