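"""The Ga-CNN patch classifier: declarative layer table and realized network.

The architecture is three convolution blocks (conv -> ReLU -> local
response normalization -> max-pool) followed by two fully connected layers
with dropout 0.3 after the first, and a two-class softmax (background,
liver).  Weights are initialized i.i.d. from a zero-mean Gaussian with a
small standard deviation (default 1e-4); biases start at zero.

Both the forward pass and backpropagation are implemented here directly on
numpy arrays (im2col + GEMM for convolutions), so the network is fully
self-contained and its gradients are testable against central differences.

Layer-table arithmetic for the default spec (input 1x32x32):

====================  ======  ======  =======  =======  =====  ==========
layer                 kernel  stride  padding  output   depth  parameters
====================  ======  ======  =======  =======  =====  ==========
conv1                 7       2       0        13x13    32     1,600
max-pool              3       1       1        13x13    32     0
conv2                 5       1       2        13x13    192    153,792
max-pool              3       2       0        6x6      192    0
conv3                 3       1       1        6x6      256    442,624
max-pool              2       2       0        3x3      256    0
fully connected       --      --      --       1x1      4096   9,441,280
fully connected       --      --      --       1x1      2      8,194
softmax               --      --      --       1x1      2      0
====================  ======  ======  =======  =======  =====  ==========

Total trainable parameters: 10,047,490.  The first pool preserves spatial
size (stride 1, padding 1): that is the unique small-kernel configuration
consistent with both the 13x13 output of the second convolution and the
first fully connected layer's 3*3*256 = 2304 input forced by its parameter
count.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "LRNParams",
    "LayerSpec",
    "NetworkSpec",
    "GaCNN",
    "default_spec",
    "output_shape",
    "count_parameters",
    "shape_chain",
    "lrn",
    "init_gaussian",
]


@dataclass(frozen=True)
class LRNParams:
    """Cross-channel local response normalization hyperparameters.

    b_i = a_i / (k + alpha * sum_{j in window(i)} a_j^2)^beta, where the
    window spans n//2 channels on each side of i, truncated at the channel
    boundaries.  Defaults are the convention of the architecture this
    normalization originates from: k=2, n=5, alpha=1e-4, beta=0.75.
    """

    k: float = 2.0
    alpha: float = 1e-4
    beta: float = 0.75
    n: int = 5

    def validate(self) -> None:
        if self.k < 0 or self.alpha < 0 or self.beta <= 0 or self.n < 1:
            raise ConfigError("invalid LRN parameters")


@dataclass(frozen=True)
class LayerSpec:
    """One row of the layer table."""

    kind: str  # conv | maxpool | fc | softmax
    kernel: int = 1
    stride: int = 1
    padding: int = 0
    out_channels: int | None = None  # conv out channels / fc out units

    def validate(self) -> None:
        if self.kind not in ("conv", "maxpool", "fc", "softmax"):
            raise ConfigError(f"unknown layer kind {self.kind!r}")
        if self.kernel < 1 or self.stride < 1 or self.padding < 0:
            raise ConfigError(f"invalid kernel/stride/padding in {self}")
        if self.kind in ("conv", "fc") and not self.out_channels:
            raise ConfigError(f"{self.kind} layer needs out_channels")


def default_layers() -> tuple[LayerSpec, ...]:
    return (
        LayerSpec("conv", kernel=7, stride=2, padding=0, out_channels=32),
        LayerSpec("maxpool", kernel=3, stride=1, padding=1),
        LayerSpec("conv", kernel=5, stride=1, padding=2, out_channels=192),
        LayerSpec("maxpool", kernel=3, stride=2, padding=0),
        LayerSpec("conv", kernel=3, stride=1, padding=1, out_channels=256),
        LayerSpec("maxpool", kernel=2, stride=2, padding=0),
        LayerSpec("fc", out_channels=4096),
        LayerSpec("fc", out_channels=2),
        LayerSpec("softmax"),
    )


@dataclass(frozen=True)
class NetworkSpec:
    input_shape: tuple[int, int, int] = (1, 32, 32)
    layers: tuple[LayerSpec, ...] = field(default_factory=default_layers)
    dropout_rate: float = 0.3
    lrn_params: LRNParams = field(default_factory=LRNParams)

    def validate(self) -> None:
        if len(self.input_shape) != 3:
            raise ConfigError("input_shape must be (channels, H, W)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must lie in [0, 1)")
        self.lrn_params.validate()
        for layer in self.layers:
            layer.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "NetworkSpec":
        return NetworkSpec(
            input_shape=tuple(d.get("input_shape", (1, 32, 32))),
            layers=tuple(LayerSpec(**ls) for ls in d["layers"]),
            dropout_rate=d.get("dropout_rate", 0.3),
            lrn_params=LRNParams(**d.get("lrn_params", {})),
        )


def default_spec() -> NetworkSpec:
    return NetworkSpec()


def output_shape(layer: LayerSpec, input_side: int) -> int:
    """Spatial output side of a conv/pool layer: floor((s+2p-k)/stride)+1."""
    out = (input_side + 2 * layer.padding - layer.kernel) // layer.stride + 1
    if out < 1:
        raise ConfigError(
            f"layer {layer} reduces side {input_side} to {out} (< 1)"
        )
    return out


def count_parameters(spec: NetworkSpec) -> tuple[list[int], int]:
    """Per-layer trainable parameter counts (aligned with spec.layers) and
    their total.  Conv: k^2*in_ch*out_ch + out_ch; fc: in*out + out."""
    spec.validate()
    ch, side, _ = spec.input_shape[0], spec.input_shape[1], spec.input_shape[2]
    units: int | None = None
    counts = []
    for layer in spec.layers:
        if layer.kind == "conv":
            counts.append(layer.kernel ** 2 * ch * layer.out_channels + layer.out_channels)
            ch = layer.out_channels
            side = output_shape(layer, side)
        elif layer.kind == "maxpool":
            counts.append(0)
            side = output_shape(layer, side)
        elif layer.kind == "fc":
            fan_in = units if units is not None else ch * side * side
            counts.append(fan_in * layer.out_channels + layer.out_channels)
            units = layer.out_channels
        else:  # softmax
            counts.append(0)
    return counts, int(sum(counts))


def shape_chain(spec: NetworkSpec) -> list[tuple[int, int]]:
    """(spatial side, depth) after each conv/pool layer, in layer order."""
    spec.validate()
    ch, side = spec.input_shape[0], spec.input_shape[1]
    chain = []
    for layer in spec.layers:
        if layer.kind in ("conv", "maxpool"):
            side = output_shape(layer, side)
            if layer.kind == "conv":
                ch = layer.out_channels
            chain.append((side, ch))
    return chain


# ---------------------------------------------------------------------------
# local response normalization (also exposed standalone)
# ---------------------------------------------------------------------------

def _channel_window_sum(x: np.ndarray, n: int) -> np.ndarray:
    """Sum over the truncated channel window [i - n//2, i + n//2] along
    axis 1 of an (N, C, H, W) array, via a padded cumulative sum."""
    half = n // 2
    c = x.shape[1]
    padded = np.zeros((x.shape[0], c + 2 * half, *x.shape[2:]), dtype=x.dtype)
    padded[:, half:half + c] = x
    out = padded[:, 0:c].copy()
    for t in range(1, 2 * half + 1):
        out += padded[:, t:t + c]
    return out


def lrn(activations: np.ndarray, params: LRNParams | None = None) -> np.ndarray:
    """Cross-channel local response normalization of an (N, C, H, W) or
    (C, H, W) feature map; channel windows truncate at the boundaries."""
    params = params or LRNParams()
    params.validate()
    a = np.asarray(activations)
    squeeze = a.ndim == 3
    if squeeze:
        a = a[None]
    if a.ndim != 4:
        raise DataError("lrn expects (N, C, H, W) or (C, H, W)")
    denom = (params.k + params.alpha * _channel_window_sum(a * a, params.n)) ** params.beta
    out = a / denom
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# layers (forward + backward on numpy arrays)
# ---------------------------------------------------------------------------


class _Layer:
    trainable = False
    name = "layer"

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Conv(_Layer):
    """Convolution as a sum of k*k shifted GEMMs in channels-last layout
    (fast on one core: contiguous copies feed BLAS directly).  The weight
    store is (k*k*in_ch, out_ch) with rows ordered (ki, kj, channel)."""

    trainable = True

    def __init__(self, name, in_ch, out_ch, kernel, stride, padding, dtype):
        self.name = name
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.w = np.zeros((kernel * kernel * in_ch, out_ch), dtype=dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None
        self._cols = None
        self._fout = None
        self._gcols = None

    def _buffer(self, attr, shape, dtype):
        buf = getattr(self, attr)
        if buf is None or buf.shape != shape or buf.dtype != dtype:
            buf = np.empty(shape, dtype=dtype)
            setattr(self, attr, buf)
        return buf

    def forward(self, x, train):
        k, s, p = self.kernel, self.stride, self.padding
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise DataError(f"{self.name}: expected {self.in_ch} channels, got {c}")
        xl = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # (n, h, w, c)
        if p:
            xl = np.pad(xl, ((0, 0), (p, p), (p, p), (0, 0)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = self._buffer("_cols", (n * ho * wo, k * k * c), xl.dtype)
        for ki in range(k):
            for kj in range(k):
                j = (ki * k + kj) * c
                cols[:, j:j + c] = xl[:, ki:ki + s * ho:s,
                                      kj:kj + s * wo:s, :].reshape(-1, c)
        out = self._buffer("_fout", (n * ho * wo, self.out_ch), self.w.dtype)
        np.matmul(cols, self.w, out=out)
        out += self.b
        self._cache = ((n, c, h, w), (ho, wo))
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, g):
        (n, c, h, w), (ho, wo) = self._cache
        cols = self._cols
        k, s, p = self.kernel, self.stride, self.padding
        gmat = np.ascontiguousarray(
            g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, self.out_ch)
        np.matmul(cols.T, gmat, out=self.gw)
        self.gb = gmat.sum(axis=0)
        gcols = self._buffer("_gcols", (n * ho * wo, k * k * c), self.w.dtype)
        np.matmul(gmat, self.w.T, out=gcols)
        gxl = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=g.dtype)
        gc = gcols.reshape(n, ho, wo, k * k * c)
        for ki in range(k):
            for kj in range(k):
                j = (ki * k + kj) * c
                gxl[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :] += gc[..., j:j + c]
        if p:
            gxl = gxl[:, p:-p, p:-p, :]
        return np.ascontiguousarray(gxl.transpose(0, 3, 1, 2))


class _ReLU(_Layer):
    name = "relu"

    def forward(self, x, train):
        self._pos = x > 0
        return x * self._pos

    def backward(self, g):
        return g * self._pos


class _LRN(_Layer):
    name = "lrn"

    def __init__(self, params: LRNParams):
        self.params = params

    @staticmethod
    def _neg_pow(denom, beta):
        # d^-0.75 = 1/(sqrt(d)*sqrt(sqrt(d))): sqrt is far cheaper than pow
        if beta == 0.75:
            root = np.sqrt(denom)
            return 1.0 / (root * np.sqrt(root))
        return denom ** (-beta)

    def forward(self, x, train):
        p = self.params
        denom = p.k + p.alpha * _channel_window_sum(x * x, p.n)
        scale = self._neg_pow(denom, p.beta)
        self._cache = (x, denom, scale)
        return x * scale

    def backward(self, g):
        p = self.params
        x, denom, scale = self._cache
        inner = _channel_window_sum(g * x * scale / denom, p.n)
        return g * scale - 2.0 * p.alpha * p.beta * x * inner


class _MaxPool(_Layer):
    """Max pooling via k*k shifted maximum reductions.  The backward pass
    routes the gradient to the window maximum; exact ties share it equally
    (a symmetric subgradient choice)."""

    def __init__(self, name, kernel, stride, padding):
        self.name = name
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def _shifts(self, xp, ho, wo):
        k, s = self.kernel, self.stride
        for ki in range(k):
            for kj in range(k):
                yield ki, kj, xp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s]

    def forward(self, x, train):
        k, s, p = self.kernel, self.stride, self.padding
        n, c, h, w = x.shape
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                       constant_values=-np.inf)
        hp, wp = x.shape[2], x.shape[3]
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        out = None
        for _, _, slab in self._shifts(x, ho, wo):
            out = slab.copy() if out is None else np.maximum(out, slab, out=out)
        self._cache = (x, out, (n, c, h, w), (ho, wo))
        return out

    def backward(self, g):
        xp, out, (n, c, h, w), (ho, wo) = self._cache
        p = self.padding
        ties = None
        for _, _, slab in self._shifts(xp, ho, wo):
            eq = slab == out
            ties = eq.astype(g.dtype) if ties is None else ties + eq
        share = g / ties
        gx = np.zeros_like(xp, dtype=g.dtype)
        for ki, kj, slab in self._shifts(xp, ho, wo):
            target = gx[:, :, ki:ki + self.stride * ho:self.stride,
                        kj:kj + self.stride * wo:self.stride]
            target += share * (slab == out)
        if p:
            gx = gx[:, :, p:-p, p:-p]
        return gx


class _Flatten(_Layer):
    name = "flatten"

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class _FC(_Layer):
    trainable = True

    def __init__(self, name, in_units, out_units, dtype):
        self.name = name
        self.in_units, self.out_units = in_units, out_units
        self.w = np.zeros((in_units, out_units), dtype=dtype)
        self.b = np.zeros(out_units, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train):
        if x.shape[1] != self.in_units:
            raise DataError(f"{self.name}: expected {self.in_units} inputs, "
                            f"got {x.shape[1]}")
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        np.matmul(self._x.T, g, out=self.gw)
        self.gb = g.sum(axis=0)
        return g @ self.w.T


class _Dropout(_Layer):
    name = "dropout"

    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


# ---------------------------------------------------------------------------
# the realized network
# ---------------------------------------------------------------------------


class GaCNN:
    """Realized parameterized network built from a :class:`NetworkSpec`.

    ``mode`` is 'train' (stochastic dropout) or 'eval' (deterministic).
    Use :func:`init_gaussian` to construct a freshly initialized model.
    """

    def __init__(self, spec: NetworkSpec, dtype=np.float32, dropout_seed: int = 0):
        spec.validate()
        self.spec = spec
        self.dtype = dtype
        self.mode = "eval"
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([int(dropout_seed) & 0x7FFFFFFF, 0xD120])
        )
        self.layers: list[_Layer] = []
        ch, side = spec.input_shape[0], spec.input_shape[1]
        units: int | None = None
        conv_i = fc_i = 0
        n_fc = sum(1 for l in spec.layers if l.kind == "fc")
        for layer in spec.layers:
            if layer.kind == "conv":
                conv_i += 1
                self.layers.append(_Conv(f"conv{conv_i}", ch, layer.out_channels,
                                         layer.kernel, layer.stride, layer.padding,
                                         dtype))
                self.layers.append(_ReLU())
                self.layers.append(_LRN(spec.lrn_params))
                ch = layer.out_channels
                side = output_shape(layer, side)
            elif layer.kind == "maxpool":
                self.layers.append(_MaxPool("pool", layer.kernel, layer.stride,
                                            layer.padding))
                side = output_shape(layer, side)
            elif layer.kind == "fc":
                fc_i += 1
                if units is None:
                    self.layers.append(_Flatten())
                    fan_in = ch * side * side
                else:
                    fan_in = units
                self.layers.append(_FC(f"fc{fc_i}", fan_in, layer.out_channels, dtype))
                units = layer.out_channels
                if fc_i < n_fc and spec.dropout_rate > 0:
                    self.layers.append(_Dropout(spec.dropout_rate, self._dropout_rng))
            # softmax handled in forward()

    # -- parameter access ---------------------------------------------------

    def trainable_layers(self):
        return [l for l in self.layers if l.trainable]

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for l in self.trainable_layers():
            out[f"{l.name}.weight"] = l.w
            out[f"{l.name}.bias"] = l.b
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for l in self.trainable_layers():
            out[f"{l.name}.weight"] = l.gw
            out[f"{l.name}.bias"] = l.gb
        return out

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for l in self.trainable_layers():
            l.w = np.asarray(params[f"{l.name}.weight"], dtype=self.dtype)
            l.b = np.asarray(params[f"{l.name}.bias"], dtype=self.dtype)

    def weight_square_sum(self) -> float:
        return float(sum((l.w.astype(np.float64) ** 2).sum()
                         for l in self.trainable_layers()))

    # -- execution ----------------------------------------------------------

    def _check_batch(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=self.dtype)
        if batch.ndim != 4 or batch.shape[1:] != tuple(self.spec.input_shape):
            raise DataError(
                f"batch must be (N, {', '.join(map(str, self.spec.input_shape))}); "
                f"got {batch.shape}"
            )
        return batch

    def forward_logits(self, batch: np.ndarray, train: bool | None = None) -> np.ndarray:
        train = (self.mode == "train") if train is None else train
        x = self._check_batch(batch)
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def forward(self, batch: np.ndarray, train: bool | None = None) -> np.ndarray:
        """Class probabilities (N, 2): softmax over the final logits."""
        logits = self.forward_logits(batch, train=train)
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the final logits; per-layer
        parameter gradients are left on the layers (see gradients())."""
        g = np.asarray(dlogits, dtype=self.dtype)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    # -- persistence --------------------------------------------------------

    def save(self, path, extra: dict | None = None) -> None:
        """Single-archive checkpoint: parameters + spec (+ metadata)."""
        meta = {"spec": self.spec.to_dict(), "extra": extra or {}}
        np.savez_compressed(Path(path), __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.parameters())

    @staticmethod
    def load(path) -> "GaCNN":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            spec = NetworkSpec.from_dict(meta["spec"])
            model = GaCNN(spec)
            model.set_parameters({k: data[k] for k in data.files if k != "__meta__"})
        return model


def init_gaussian(spec: NetworkSpec, sigma: float = 1e-4, seed: int = 0,
                  dtype=np.float32) -> GaCNN:
    """Build a GaCNN with every weight ~ N(0, sigma^2) and zero biases.

    Deterministic in ``seed``; each layer draws from an independent
    substream so the draw is independent of layer evaluation order.
    """
    if sigma <= 0:
        raise ConfigError("sigma must be > 0")
    model = GaCNN(spec, dtype=dtype, dropout_seed=seed)
    root = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x6A55])
    streams = root.spawn(len(model.trainable_layers()))
    for layer, stream in zip(model.trainable_layers(), streams):
        rng = np.random.default_rng(stream)
        layer.w = (sigma * rng.standard_normal(layer.w.shape)).astype(dtype)
        layer.b = np.zeros_like(layer.b)
    return model
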