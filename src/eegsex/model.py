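"""Declarative CNN architecture and the network built from it.

The default stack is the reference 15-row layer stack: six same-padded
ReLU convolutions interleaved with four max-pooling and four 25%-dropout
stages, closed by a 2-unit softmax head.  Kernel and pool sizes are
written (channel-axis x time-axis), matching the 24 x 256 input
orientation; with same padding the channel axis evolves
24-12-6-3-3-3-3 and the time axis 256-128-64-32-16-16-16, leaving a
100 x 3 x 16 = 4800-unit feature block before the dense head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .errors import ArchitectureError

__all__ = [
    "ConvSpec", "PoolSpec", "DropoutSpec", "DenseSpec", "ArchSpec",
    "default_archspec", "build_network", "count_parameters",
    "layer_activation", "input_gradient", "Network",
]


@dataclass(frozen=True)
class ConvSpec:
    n_filters: int
    kh: int
    kw: int
    activation: str = "relu"
    kind: str = "conv"


@dataclass(frozen=True)
class PoolSpec:
    ph: int
    pw: int
    mode: str = "max"
    kind: str = "pool"


@dataclass(frozen=True)
class DropoutSpec:
    rate: float
    kind: str = "dropout"


@dataclass(frozen=True)
class DenseSpec:
    n_units: int
    activation: str = "softmax"
    kind: str = "dense"


@dataclass(frozen=True)
class ArchSpec:
    """Layer stack description from which the network is built.

    ``input_shape`` is (channels, time); ``filter_scale`` multiplies every
    convolutional filter count (rounded, minimum 1) for scaled-down runs.
    """

    input_shape: tuple[int, int] = (24, 256)
    layers: tuple = ()
    filter_scale: float = 1.0

    def scaled_filters(self, n: int) -> int:
        return max(1, int(round(n * self.filter_scale)))

    def validate(self) -> None:
        if not self.layers or not isinstance(self.layers[-1], DenseSpec):
            raise ArchitectureError("last layer must be a dense softmax head")
        if self.layers[-1].n_units != 2 or self.layers[-1].activation != "softmax":
            raise ArchitectureError("head must be dense(2, softmax)")
        for sp in self.layers:
            if isinstance(sp, ConvSpec) and (sp.kh < 1 or sp.kw < 1):
                raise ArchitectureError("kernel sizes must be positive")
            if isinstance(sp, PoolSpec) and (sp.ph < 1 or sp.pw < 1):
                raise ArchitectureError("pool sizes must be positive")
        self.shape_walk()  # raises if pooling collapses a dimension

    def shape_walk(self) -> list[tuple[int, int, int]]:
        """(channels, height, width) after each layer."""
        c, (h, w) = 1, self.input_shape
        shapes = []
        for sp in self.layers:
            if isinstance(sp, ConvSpec):
                c = self.scaled_filters(sp.n_filters)
            elif isinstance(sp, PoolSpec):
                h, w = h // sp.ph, w // sp.pw
                if h < 1 or w < 1:
                    raise ArchitectureError(
                        f"pooling {sp.ph}x{sp.pw} collapses the feature map "
                        f"below 1 (reached {h}x{w})")
            elif isinstance(sp, DenseSpec):
                c, h, w = sp.n_units, 1, 1
            shapes.append((c, h, w))
        return shapes

    def to_json(self) -> str:
        return json.dumps({"input_shape": list(self.input_shape),
                           "filter_scale": self.filter_scale,
                           "layers": [asdict(sp) for sp in self.layers]})

    @classmethod
    def from_json(cls, text: str) -> "ArchSpec":
        d = json.loads(text)
        kinds = {"conv": ConvSpec, "pool": PoolSpec,
                 "dropout": DropoutSpec, "dense": DenseSpec}
        layers = []
        for sp in d["layers"]:
            kind = sp.pop("kind")
            layers.append(kinds[kind](**sp))
        return cls(input_shape=tuple(d["input_shape"]),
                   layers=tuple(layers), filter_scale=d["filter_scale"])


def default_archspec(n_channels: int = 24, n_times: int = 256,
                     filter_scale: float = 1.0) -> ArchSpec:
    """The reference 15-row architecture (100/100/300/300/100/100 filters)."""
    layers = (
        ConvSpec(100, 3, 3),
        PoolSpec(2, 2),
        DropoutSpec(0.25),
        ConvSpec(100, 3, 3),
        PoolSpec(2, 2),
        DropoutSpec(0.25),
        ConvSpec(300, 2, 3),
        PoolSpec(2, 2),
        DropoutSpec(0.25),
        ConvSpec(300, 1, 7),
        PoolSpec(1, 2),
        DropoutSpec(0.25),
        ConvSpec(100, 1, 3),
        ConvSpec(100, 1, 3),
        DenseSpec(2, "softmax"),
    )
    return ArchSpec(input_shape=(n_channels, n_times), layers=layers,
                    filter_scale=filter_scale)


def count_parameters(spec: ArchSpec) -> int:
    """Exact trainable parameter count by the standard hand formulas:
    conv (kh*kw*c_in + 1)*n_f, dense (n_in + 1)*n_units."""
    spec.validate()
    c_in = 1
    h, w = spec.input_shape
    total = 0
    for sp in spec.layers:
        if isinstance(sp, ConvSpec):
            n_f = spec.scaled_filters(sp.n_filters)
            total += (sp.kh * sp.kw * c_in + 1) * n_f
            c_in = n_f
        elif isinstance(sp, PoolSpec):
            h, w = h // sp.ph, w // sp.pw
        elif isinstance(sp, DenseSpec):
            total += (c_in * h * w + 1) * sp.n_units
            c_in, h, w = sp.n_units, 1, 1
    return total


class Network:
    """A built network: ordered layers plus bookkeeping for the conv
    stack (1-based conv indices, as in the layer table)."""

    def __init__(self, spec: ArchSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
        self.layers: list[_nn.Layer] = []
        self.conv_positions: list[int] = []  # layer list index of each conv
        c_in = 1
        h, w = spec.input_shape
        for sp in spec.layers:
            if isinstance(sp, ConvSpec):
                n_f = spec.scaled_filters(sp.n_filters)
                self.conv_positions.append(len(self.layers))
                self.layers.append(_nn.Conv2D(c_in, n_f, sp.kh, sp.kw,
                                              activation=sp.activation,
                                              rng=rng))
                c_in = n_f
            elif isinstance(sp, PoolSpec):
                cls = _nn.MaxPool2D if sp.mode == "max" else _nn.MeanPool2D
                self.layers.append(cls(sp.ph, sp.pw))
                h, w = h // sp.ph, w // sp.pw
            elif isinstance(sp, DropoutSpec):
                self.layers.append(_nn.Dropout(sp.rate))
            elif isinstance(sp, DenseSpec):
                self.layers.append(_nn.Flatten())
                self.layers.append(_nn.Dense(c_in * h * w, sp.n_units, rng=rng))

    # -- basic passes -------------------------------------------------
    @property
    def n_conv_layers(self) -> int:
        return len(self.conv_positions)

    @property
    def input_shape(self) -> tuple[int, int]:
        return self.spec.input_shape

    def parameters(self):
        out = []
        for layer in self.layers:
            if layer.trainable:
                out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def forward_logits(self, x: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, train=train, rng=rng)
        return out

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Per-input class probabilities (female, male); dropout disabled.

        Accepts (n, time, channels) epochs or net-layout input."""
        x = _to_net_layout(x, self.input_shape)
        chunks = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward_logits(x[i:i + batch_size], train=False)
            chunks.append(_nn.softmax(logits))
        return np.concatenate(chunks, axis=0)

    # -- conv-layer access -------------------------------------------
    def _conv_pos(self, conv_index: int) -> int:
        if not 1 <= conv_index <= self.n_conv_layers:
            raise IndexError(
                f"conv layer index {conv_index} out of range "
                f"1..{self.n_conv_layers}")
        return self.conv_positions[conv_index - 1]

    def forward_to_conv(self, conv_index: int, x: np.ndarray,
                        keep_cache: bool = False) -> np.ndarray:
        """Post-activation feature maps of the conv layer (1-based index),
        returned as (batch, filters, height, width); dropout is inactive
        (inference path)."""
        pos = self._conv_pos(conv_index)
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers[:pos + 1]:
            out = layer.forward(out, train=False)
        if not keep_cache:
            for layer in self.layers[:pos + 1]:
                if isinstance(layer, _nn.Conv2D):
                    layer._cache = None
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward_from_conv(self, conv_index: int,
                           dmaps: np.ndarray) -> np.ndarray:
        """Propagate a (batch, filters, height, width) feature-map gradient
        back to the input (requires a preceding
        ``forward_to_conv(..., keep_cache=True)``)."""
        pos = self._conv_pos(conv_index)
        grad = np.ascontiguousarray(
            np.asarray(dmaps, dtype=np.float32).transpose(0, 2, 3, 1))
        for layer in reversed(self.layers[:pos + 1]):
            grad = layer.backward(grad)
        return grad

    # -- persistence --------------------------------------------------
    def save(self, path) -> None:
        """Weights as an ``.npz`` next to the JSON spec."""
        path = Path(path)
        arrays = {}
        for i, (p, _) in enumerate(self.parameters()):
            arrays[f"p{i}"] = p
        np.savez(path, spec=self.spec.to_json(), seed=self.seed, **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path, allow_pickle=False) as data:
            spec = ArchSpec.from_json(str(data["spec"]))
            net = cls(spec, seed=int(data["seed"]))
            for i, (p, _) in enumerate(net.parameters()):
                p[:] = data[f"p{i}"]
        return net


def build_network(spec: ArchSpec, seed: int = 0) -> Network:
    """Build a network with deterministic, seed-controlled initialization."""
    return Network(spec, seed=seed)


def layer_activation(net: Network, conv_index: int,
                     input_batch: np.ndarray) -> np.ndarray:
    """Post-activation feature maps of the conv layer (1-based index).

    ``input_batch`` is (batch, time, channels) epochs or an already
    net-shaped (batch, 1, channels, time) array.
    """
    x = _to_net_layout(input_batch, net.input_shape)
    return net.forward_to_conv(conv_index, x)


def input_gradient(net: Network, conv_index: int, filter_index: int,
                   input_matrix: np.ndarray) -> np.ndarray:
    """Gradient of the chosen filter's mean activation w.r.t. the input.

    Returns an array with the same (time, channels) layout as the input.
    """
    single = input_matrix.ndim == 2
    x = _to_net_layout(input_matrix[None] if single else input_matrix,
                       net.input_shape)
    maps = net.forward_to_conv(conv_index, x, keep_cache=True)
    if not 0 <= filter_index < maps.shape[1]:
        raise IndexError(f"filter index {filter_index} out of range "
                         f"0..{maps.shape[1] - 1}")
    dmaps = np.zeros_like(maps)
    dmaps[:, filter_index] = 1.0 / (maps.shape[2] * maps.shape[3])
    dx = net.backward_from_conv(conv_index, dmaps)  # (b, ch, time, 1)
    if not np.all(np.isfinite(dx)):
        raise FloatingPointError("non-finite input gradient")
    grad = dx[..., 0].transpose(0, 2, 1)  # back to (batch, time, channels)
    return grad[0] if single else grad


def _to_net_layout(batch: np.ndarray, input_shape: tuple[int, int]) -> np.ndarray:
    """Accept (b, time, channels) epochs or the engine's channels-last
    (b, channels, time, 1) layout; return the latter."""
    batch = np.asarray(batch, dtype=np.float32)
    n_ch, n_t = input_shape
    if batch.ndim == 4:
        return batch
    if batch.ndim != 3 or batch.shape[1] != n_t or batch.shape[2] != n_ch:
        raise ValueError(
            f"expected epochs of shape (n, {n_t}, {n_ch}), got {batch.shape}")
    return np.ascontiguousarray(batch.transpose(0, 2, 1))[..., None]
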