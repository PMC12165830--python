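"""Minimal numpy layers with manual backprop, plus the Adam optimizer.

Only what the virion-protein classifier needs: 1-D convolution over a
single input channel, batch normalization (channel-wise for (N, C, L)
tensors and feature-wise for (N, F) matrices), ReLU, max pooling, flatten
and dense layers. Every layer stores its parameters in ``params`` and the
gradients of the last backward pass in ``grads``; ``forward`` caches what
backward needs. All computation is float64 and deterministic, so two runs
from the same seed produce bit-identical parameters.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32  # network compute dtype; losses/metrics stay float64


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()


class Reshape1ch(Layer):
    """(N, L) -> (N, 1, L) and back."""

    def forward(self, x, training=False):
        return x[:, None, :]

    def backward(self, grad_out):
        return grad_out[:, 0, :]


class Conv1d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        self.stride = stride
        self.kernel = kernel
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=(out_channels, in_channels, kernel)).astype(DTYPE)
        self.params["b"] = np.zeros(out_channels, dtype=DTYPE)

    def forward(self, x, training=False):
        # x: (N, Cin, L) -> windows (N, Cin, Lout, k)
        wins = sliding_window_view(x, self.kernel, axis=2)[:, :, :: self.stride, :]
        self._wins = wins
        self._in_shape = x.shape
        return np.einsum("nclk,ock->nol", wins, self.params["W"]) + self.params["b"][None, :, None]

    def backward(self, grad_out):
        self.grads["W"] = np.einsum("nclk,nol->ock", self._wins, grad_out)
        self.grads["b"] = grad_out.sum(axis=(0, 2))
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        lout = grad_out.shape[2]
        contrib = np.einsum("nol,ock->nclk", grad_out, self.params["W"])
        for j in range(self.kernel):  # strided slices are disjoint per offset j
            dx[:, :, j : j + self.stride * lout : self.stride] += contrib[:, :, :, j]
        return dx


class BatchNorm(Layer):
    """Batch normalization over axis 0 (and axis 2 for 3-D inputs)."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(num_features, dtype=DTYPE)
        self.params["beta"] = np.zeros(num_features, dtype=DTYPE)
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def _axes(self, x):
        return (0, 2) if x.ndim == 3 else (0,)

    def _shape(self, x):
        return (1, -1, 1) if x.ndim == 3 else (1, -1)

    def forward(self, x, training=False):
        axes, shp = self._axes(x), self._shape(x)
        if training:
            mean = x.mean(axis=axes, dtype=DTYPE)
            var = x.var(axis=axes, dtype=DTYPE)
            n = x.size / mean.size
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            unbiased = var * n / max(n - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        self._xhat = (x - mean.reshape(shp)) * inv_std.reshape(shp)
        self._inv_std = inv_std
        self._training = training
        return self.params["gamma"].reshape(shp) * self._xhat + self.params["beta"].reshape(shp)

    def backward(self, grad_out):
        axes, shp = self._axes(grad_out), self._shape(grad_out)
        xhat = self._xhat
        self.grads["gamma"] = (grad_out * xhat).sum(axis=axes)
        self.grads["beta"] = grad_out.sum(axis=axes)
        g = grad_out * self.params["gamma"].reshape(shp)
        inv_std = self._inv_std.reshape(shp)
        if not self._training:
            return g * inv_std
        n = grad_out.size / self.grads["beta"].size
        g -= g.sum(axis=axes).reshape(shp) / n
        g -= xhat * ((g * xhat).sum(axis=axes).reshape(shp) / n)
        g *= inv_std
        return g

    def state(self):
        return {**self.params, "running_mean": self.running_mean, "running_var": self.running_var}

    def load_state(self, state):
        super().load_state(state)
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out):
        return grad_out * self._mask


class Identity(Layer):
    def forward(self, x, training=False):
        return x

    def backward(self, grad_out):
        return grad_out


class MaxPool1d(Layer):
    def __init__(self, kernel: int, stride: int):
        super().__init__()
        self.kernel = kernel
        self.stride = stride

    def forward(self, x, training=False):
        wins = sliding_window_view(x, self.kernel, axis=2)[:, :, :: self.stride, :]
        self._argmax = wins.argmax(axis=3)
        self._in_shape = x.shape
        return wins.max(axis=3)

    def backward(self, grad_out):
        lout = grad_out.shape[2]
        dx = np.zeros(self._in_shape, dtype=grad_out.dtype)
        # route each window's gradient to its argmax via a one-hot mask,
        # then scatter with disjoint strided slices per kernel offset
        onehot = (np.arange(self.kernel) == self._argmax[..., None]) * grad_out[..., None]
        for j in range(self.kernel):
            dx[:, :, j : j + self.stride * lout : self.stride] += onehot[:, :, :, j]
        return dx


class Flatten(Layer):
    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / in_features),
                                      size=(in_features, out_features)).astype(DTYPE)
        self.params["b"] = np.zeros(out_features, dtype=DTYPE)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad_out):
        self.grads["W"] = self._x.T @ grad_out
        self.grads["b"] = grad_out.sum(axis=0)
        return grad_out @ self.params["W"].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state().items():
                out[f"{i}.{k}"] = v.copy()
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            sub = {k.split(".", 1)[1]: v for k, v in state.items()
                   if k.startswith(f"{i}.")}
            if sub:
                layer.load_state(sub)


class Adam:
    """Adam with bias correction; one (m, v) slot pair per parameter tensor."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, layer in enumerate(self.model.layers):
            for name, param in layer.params.items():
                grad = layer.grads.get(name)
                if grad is None:
                    continue
                key = (i, name)
                m = self._m.setdefault(key, np.zeros_like(param))
                v = self._v.setdefault(key, np.zeros_like(param))
                m[:] = b1 * m + (1 - b1) * grad
                v[:] = b2 * v + (1 - b2) * grad * grad
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
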