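"""Minimal NumPy neural-network layers with backpropagation.

Only what the five-block detector needs: 2D convolution with "same" zero
padding, batch normalization, ReLU, non-overlapping max pooling, global
average pooling, flatten, a dense layer, softmax cross-entropy, and Adam.
Arrays are (batch, maps, height, width) throughout. Weight initialization
is the uniform fan-in scheme, drawn from a seeded generator so runs are
reproducible.

Convolutions here only face short 1-D-shaped kernels (1 x k or k x 1), so
the forward/backward passes loop over the few kernel taps and accumulate
shifted einsums; this is fast enough for the ~9.5k-parameter detector on
one CPU core.
"""

from __future__ import annotations

import numpy as np

#: all weights and activations are single precision: the detector is tiny
#: and float32 halves the arithmetic cost on one CPU core
DTYPE = np.float32

__all__ = [
    "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "GlobalAvgPool", "Flatten",
    "Dense", "Sequential", "Adam", "softmax", "softmax_cross_entropy",
]


class Layer:
    """Forward/backward protocol; layers with weights expose ``params()``
    as a list of (array, grad-array) pairs updated in place."""

    train_mode = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def state(self) -> dict[str, np.ndarray]:
        """Copy of all arrays needed to restore the layer (weights + buffers)."""
        return {}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            getattr(self, k)[...] = v


def _same_pad(k: int) -> tuple[int, int]:
    # total pad k-1; the extra element of an even kernel goes on the trailing side
    lead = (k - 1) // 2
    return lead, k - 1 - lead


class Conv2d(Layer):
    def __init__(self, in_maps: int, out_maps: int, kh: int, kw: int,
                 rng: np.random.Generator):
        self.kh, self.kw = kh, kw
        fan_in = in_maps * kh * kw
        bound = 1.0 / np.sqrt(fan_in)
        self.W = rng.uniform(-bound, bound, size=(out_maps, in_maps, kh, kw)).astype(DTYPE)
        self.b = rng.uniform(-bound, bound, size=out_maps).astype(DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        ph, pw = _same_pad(self.kh), _same_pad(self.kw)
        xp = np.pad(x, ((0, 0), (0, 0), ph, pw))
        self._xp = xp
        B, _, H, W = x.shape
        out = np.zeros((B, self.W.shape[0], H, W), dtype=x.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                out += np.einsum("oc,bchw->bohw", self.W[:, :, i, j],
                                 xp[:, :, i:i + H, j:j + W], optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._xp
        B, _, H, W = grad.shape
        self.db[...] = grad.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for i in range(self.kh):
            for j in range(self.kw):
                self.dW[:, :, i, j] = np.einsum(
                    "bohw,bchw->oc", grad, xp[:, :, i:i + H, j:j + W], optimize=True)
                dxp[:, :, i:i + H, j:j + W] += np.einsum(
                    "oc,bohw->bchw", self.W[:, :, i, j], grad, optimize=True)
        (pl, _), (ql, _) = _same_pad(self.kh), _same_pad(self.kw)
        return dxp[:, :, pl:pl + H, ql:ql + W]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def state(self):
        return {"W": self.W.copy(), "b": self.b.copy()}


class BatchNorm2d(Layer):
    """Per-map normalization; gamma/beta are the 2 trainable parameters per
    map, running mean/variance are buffers (excluded from parameter counts)."""

    def __init__(self, maps: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(maps, dtype=DTYPE)
        self.beta = np.zeros(maps, dtype=DTYPE)
        self.dgamma = np.zeros(maps, dtype=DTYPE)
        self.dbeta = np.zeros(maps, dtype=DTYPE)
        self.running_mean = np.zeros(maps, dtype=DTYPE)
        self.running_var = np.ones(maps, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.train_mode:
            mean = x.mean(axis=(0, 2, 3), dtype=DTYPE)
            var = x.var(axis=(0, 2, 3), dtype=DTYPE)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        self.dgamma[...] = (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = grad.sum(axis=(0, 2, 3))
        if not self.train_mode:
            return grad * self.gamma[None, :, None, None] / std[None, :, None, None]
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        g = grad * self.gamma[None, :, None, None]
        return (g - g.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
                ) / std[None, :, None, None]

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def state(self):
        return {"gamma": self.gamma.copy(), "beta": self.beta.copy(),
                "running_mean": self.running_mean.copy(),
                "running_var": self.running_var.copy()}


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    """Non-overlapping max pooling (stride = kernel); trailing remainder
    rows/columns are truncated."""

    def __init__(self, kh: int, kw: int):
        self.kh, self.kw = kh, kw

    def forward(self, x):
        B, C, H, W = x.shape
        oh, ow = H // self.kh, W // self.kw
        xv = x[:, :, :oh * self.kh, :ow * self.kw].reshape(B, C, oh, self.kh, ow, self.kw)
        self._xv_shape = (B, C, H, W)
        xr = xv.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, oh, ow, self.kh * self.kw)
        self._arg = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, grad):
        B, C, H, W = self._xv_shape
        oh, ow = grad.shape[2], grad.shape[3]
        dxr = np.zeros((B, C, oh, ow, self.kh * self.kw), dtype=grad.dtype)
        np.put_along_axis(dxr, self._arg[..., None], grad[..., None], axis=-1)
        dx = np.zeros((B, C, H, W), dtype=grad.dtype)
        dx[:, :, :oh * self.kh, :ow * self.kw] = (
            dxr.reshape(B, C, oh, ow, self.kh, self.kw)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, oh * self.kh, ow * self.kw)
        )
        return dx


class GlobalAvgPool(Layer):
    """Average over the spatial axes, yielding (batch, maps, 1, 1)."""

    def forward(self, x):
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3), keepdims=True)

    def backward(self, grad):
        return np.broadcast_to(grad / self._hw, self._shape).copy()


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out)).astype(DTYPE)
        self.b = rng.uniform(-bound, bound, size=n_out).astype(DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def state(self):
        return {"W": self.W.copy(), "b": self.b.copy()}


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            layer.train_mode = training
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params())

    def state(self) -> list[dict[str, np.ndarray]]:
        return [layer.state() for layer in self.layers]

    def load_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, st in zip(self.layers, state):
            layer.load_state(st)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


class Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
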