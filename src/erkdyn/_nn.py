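"""Minimal 1-D convolutional regression network in NumPy.

Architecture (fixed by design, sizes configurable): two same-padding 1-D
convolutions (16 channels, kernel 16) with rectifier activations, a flatten,
three fully connected layers (192, 64, 64) with rectifiers, and a final
linear unit producing one scalar prediction per trace.  Trained with Adam on
mean-squared error plus an L2 penalty on the weights.  The backward pass
also yields gradients with respect to the input, which integrated-gradients
attribution consumes.

Everything runs in float32 on the CPU; all randomness flows through one
seeded generator.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)


class Conv1dSame:
    """Same-padding 1-D convolution via an im2col matrix product."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.pad_l = (kernel - 1) // 2
        self.pad_r = kernel // 2
        self.W = _he_init(rng, (c_out, c_in * kernel), c_in * kernel)
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (N, C_in, T) -> (N, C_out, T)
        n, _, t = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_l, self.pad_r)))
        cols = sliding_window_view(xp, self.k, axis=2)        # (N, C_in, T, K)
        self._cols = cols.transpose(0, 2, 1, 3).reshape(n, t, -1)  # (N, T, C_in*K)
        out = self._cols @ self.W.T + self.b                  # (N, T, C_out)
        return out.transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # dy: (N, C_out, T)
        n, _, t = dy.shape
        dyt = dy.transpose(0, 2, 1)                            # (N, T, C_out)
        self.dW = dyt.reshape(-1, self.c_out).T @ self._cols.reshape(-1, self.c_in * self.k)
        self.db = dyt.sum(axis=(0, 1))
        dcols = dyt @ self.W                                   # (N, T, C_in*K)
        dcols = dcols.reshape(n, t, self.c_in, self.k).transpose(0, 2, 1, 3)
        dxp = np.zeros((n, self.c_in, t + self.pad_l + self.pad_r), dtype=np.float32)
        for j in range(self.k):
            dxp[:, :, j:j + t] += dcols[:, :, :, j]
        return dxp[:, :, self.pad_l:self.pad_l + t]

    @property
    def params(self):
        return [("W", True), ("b", False)]


class Dense:
    def __init__(self, rng, n_in: int, n_out: int, scale: float | None = None):
        self.W = _he_init(rng, (n_in, n_out), n_in) if scale is None else \
            rng.normal(0.0, scale, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    @property
    def params(self):
        return [("W", True), ("b", False)]


class Relu:
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)

    params = ()


class ConvNet1d:
    """Conv-conv-flatten-dense regression network with scalar output."""

    def __init__(self, input_len: int, channels: int = 16, kernel: int = 16,
                 fc_sizes=(192, 64, 64), n_conv_layers: int = 2, seed: int = 0):
        if kernel > input_len:
            raise ValueError("kernel size exceeds input length")
        rng = np.random.default_rng(seed)
        self.input_len = input_len
        self.layers = []
        c_in = 1
        for _ in range(n_conv_layers):
            self.layers += [Conv1dSame(rng, c_in, channels, kernel), Relu()]
            c_in = channels
        self._flat_at = len(self.layers)
        n_in = channels * input_len
        for size in fc_sizes:
            self.layers += [Dense(rng, n_in, size), Relu()]
            n_in = size
        self.layers.append(Dense(rng, n_in, 1, scale=1.0 / np.sqrt(n_in)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, T) standardized traces -> (N,) predictions."""
        h = x.astype(np.float32)[:, None, :]
        for i, layer in enumerate(self.layers):
            if i == self._flat_at:
                self._conv_shape = h.shape
                h = h.reshape(h.shape[0], -1)
            h = layer.forward(h)
        return h[:, 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backprop d(loss)/d(output); returns d(loss)/d(input), (N, T)."""
        g = dout.astype(np.float32)[:, None]
        for i in range(len(self.layers) - 1, -1, -1):
            g = self.layers[i].backward(g)
            if i == self._flat_at:
                g = g.reshape(self._conv_shape)
        return g[:, 0, :]

    def input_gradients(self, x: np.ndarray) -> np.ndarray:
        """d(prediction)/d(input) per sample, shape (N, T)."""
        self.forward(x)
        return self.backward(np.ones(x.shape[0], dtype=np.float32))

    def _param_layers(self):
        return [l for l in self.layers if l.params]

    def fit(self, x: np.ndarray, y: np.ndarray, epochs: int = 100,
            lr: float = 1e-3, l2: float = 1e-3, batch_size: int = 256,
            seed: int = 0, x_val=None, y_val=None):
        """Adam on MSE + l2*sum(W^2); returns per-epoch loss history."""
        rng = np.random.default_rng(seed)
        x = x.astype(np.float32)
        y = y.astype(np.float32)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        state = {}
        for li, layer in enumerate(self._param_layers()):
            for name, _ in layer.params:
                w = getattr(layer, name)
                state[(li, name)] = (np.zeros_like(w), np.zeros_like(w))
        step = 0
        history = []
        n = x.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb = x[idx], y[idx]
                pred = self.forward(xb)
                resid = pred - yb
                epoch_loss += float((resid ** 2).sum())
                self.backward(2.0 * resid / idx.size)
                step += 1
                for li, layer in enumerate(self._param_layers()):
                    for name, decay in layer.params:
                        w = getattr(layer, name)
                        g = getattr(layer, "d" + name)
                        if decay and l2 > 0:
                            g = g + 2.0 * l2 * w
                        m, v = state[(li, name)]
                        m[:] = beta1 * m + (1 - beta1) * g
                        v[:] = beta2 * v + (1 - beta2) * g * g
                        mh = m / (1 - beta1 ** step)
                        vh = v / (1 - beta2 ** step)
                        w -= (lr * mh / (np.sqrt(vh) + eps)).astype(np.float32)
            history.append(epoch_loss / n)
        return history
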