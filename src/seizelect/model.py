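"""The five-block lightweight convolutional seizure detector.

Input is a 4-s broadband window of the M selected channels sampled at
256 Hz, shaped (1, M, 1024): one input map, channel axis as height, time
as width. Five blocks of same-padded Conv2D + batch normalization + ReLU
(+ max pooling in the first four) first shrink the time axis (pool widths
8, 4, 4), then collapse the channel axis (pool height M), and a global
average pool + dense layer produce the two-class softmax. Every
convolution preserves its spatial shape via zero padding, so no layer's
parameter count depends on M: the model has the same ~9.5k trainable
parameters for the two-selected-channel (M=2) and four-temporal-channel
(M=4) configurations. Batch-normalization running statistics are buffers,
not trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

#: time samples per detector window: 4 s at 256 Hz
WINDOW_SAMPLES = 1024
SUPPORTED_M = (2, 4)


@dataclass(frozen=True)
class LayerSpec:
    kind: str                      # conv2d | batchnorm | maxpool | averagepool | flatten | dense
    in_shape: tuple[int, ...]      # (maps, height, width) or (features,)
    out_shape: tuple[int, ...]
    filters: int = 0
    kernel: tuple[int, int] | None = None
    param_count: int = 0


@dataclass
class ModelSpec:
    M: int
    T: int
    layers: list[LayerSpec] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(l.param_count for l in self.layers)

    def to_json(self) -> str:
        payload = {
            "M": self.M, "T": self.T, "total_params": self.total_params,
            "layers": [asdict(l) for l in self.layers],
        }
        return json.dumps(payload, indent=2)


def _conv_params(in_maps: int, filters: int, kh: int, kw: int) -> int:
    return in_maps * filters * kh * kw + filters


def build_model(M: int, T: int = WINDOW_SAMPLES) -> ModelSpec:
    """Layer-by-layer architecture for an M-channel input window."""
    if M not in SUPPORTED_M:
        raise ValueError(f"unsupported channel count M={M}; expected one of {SUPPORTED_M}")
    layers: list[LayerSpec] = []
    shape = (1, M, T)

    def conv(filters: int, kh: int, kw: int):
        nonlocal shape
        out = (filters, shape[1], shape[2])
        layers.append(LayerSpec("conv2d", shape, out, filters, (kh, kw),
                                _conv_params(shape[0], filters, kh, kw)))
        shape = out
        layers.append(LayerSpec("batchnorm", shape, shape, param_count=2 * shape[0]))

    def pool(kh: int, kw: int):
        nonlocal shape
        out = (shape[0], shape[1] // kh, shape[2] // kw)
        layers.append(LayerSpec("maxpool", shape, out, kernel=(kh, kw)))
        shape = out

    conv(4, 1, 4);   pool(1, 8)     # (4, M, T/8)
    conv(16, 1, 16); pool(1, 4)     # (16, M, T/32)
    conv(16, 1, 8);  pool(1, 4)     # (16, M, T/128)
    conv(16, 16, 1); pool(M, 1)     # (16, 1, T/128)
    conv(16, 8, 1)                  # (16, 1, T/128)
    layers.append(LayerSpec("averagepool", shape, (shape[0], 1, 1)))
    layers.append(LayerSpec("flatten", (shape[0], 1, 1), (shape[0],)))
    layers.append(LayerSpec("dense", (shape[0],), (2,),
                            param_count=shape[0] * 2 + 2))
    return ModelSpec(M=M, T=T, layers=layers)


def count_parameters(spec: ModelSpec) -> tuple[int, list[tuple[str, int]]]:
    """Total trainable parameters and the per-layer breakdown."""
    breakdown = [(l.kind, l.param_count) for l in spec.layers]
    return spec.total_params, breakdown


class SeizureCNN:
    """Executable network matching a :class:`ModelSpec`, with seeded init."""

    def __init__(self, M: int, seed: int = 0, T: int = WINDOW_SAMPLES):
        self.spec = build_model(M, T)
        self.M, self.T = M, T
        rng = np.random.default_rng(seed)
        net: list[nn.Layer] = []
        for l in self.spec.layers:
            if l.kind == "conv2d":
                net.append(nn.Conv2d(l.in_shape[0], l.filters, *l.kernel, rng=rng))
            elif l.kind == "batchnorm":
                net.append(nn.BatchNorm2d(l.in_shape[0]))
                net.append(nn.ReLU())
            elif l.kind == "maxpool":
                net.append(nn.MaxPool2d(*l.kernel))
            elif l.kind == "averagepool":
                net.append(nn.GlobalAvgPool())
            elif l.kind == "flatten":
                net.append(nn.Flatten())
            elif l.kind == "dense":
                net.append(nn.Dense(l.in_shape[0], l.out_shape[0], rng=rng))
        self.net = nn.Sequential(net)
        assert self.net.n_params() == self.spec.total_params

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim != 4 or x.shape[1:] != (1, self.M, self.T):
            raise ValueError(
                f"expected input (batch, 1, {self.M}, {self.T}), got {x.shape}"
            )
        return x

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(self._check_input(x), training=training)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode class probabilities, rows summing to 1."""
        return nn.softmax(self.forward_logits(x, training=False))

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Hard 0/1 window labels in inference mode, batched for memory."""
        x = self._check_input(x)
        out = np.empty(x.shape[0], dtype=int)
        for i in range(0, x.shape[0], batch_size):
            out[i:i + batch_size] = self.forward(x[i:i + batch_size]).argmax(axis=1)
        return out

    def loss_on(self, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> float:
        """Mean inference-mode cross-entropy over a dataset."""
        x = self._check_input(x)
        total, n = 0.0, x.shape[0]
        for i in range(0, n, batch_size):
            logits = self.forward_logits(x[i:i + batch_size], training=False)
            loss, _ = nn.softmax_cross_entropy(logits, y[i:i + batch_size])
            total += loss * logits.shape[0]
        return total / n

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer: nn.Adam) -> float:
        logits = self.forward_logits(x, training=True)
        loss, dlogits = nn.softmax_cross_entropy(logits, y)
        self.net.backward(dlogits)
        optimizer.step()
        return loss

    # checkpointing -----------------------------------------------------
    def state(self):
        return self.net.state()

    def load_state(self, state) -> None:
        self.net.load_state(state)

    def save(self, path) -> None:
        flat = {}
        for i, layer_state in enumerate(self.state()):
            for k, v in layer_state.items():
                flat[f"{i}.{k}"] = v
        np.savez(path, M=self.M, T=self.T, **flat)

    @classmethod
    def load(cls, path) -> "SeizureCNN":
        data = np.load(path)
        model = cls(int(data["M"]), T=int(data["T"]))
        state = model.state()
        for key in data.files:
            if "." not in key:
                continue
            idx, name = key.split(".", 1)
            state[int(idx)][name] = data[key]
        model.load_state(state)
        return model
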