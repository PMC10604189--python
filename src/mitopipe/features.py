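"""Feature extraction with a depthwise-separable-convolution backbone.

The full variant mirrors the Extreme-Inception layout: 36 convolution layers
grouped into 14 blocks, with linear residual connections on every block
except the first and the last (a depthwise-separable convolution counts as
one layer; 1x1 residual projections are not counted). A ``tiny`` 4-block
analogue of the same design is the desk-scale default used for training and
testing. Either backbone is followed by a custom head of three convolutions
and three max-pooling layers, a flatten (the feature tap), dropout, and a
sigmoid unit giving a class probability in (0, 1).

The backbone here is trained from scratch on the synthetic classification
set; ``load_pretrained_weights`` is the hook for externally supplied weight
files (nothing is ever downloaded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn
from ._nn import (Adam, BatchNorm, Conv2D, Dense, Dropout, Flatten, MaxPool2,
                  Residual, Sequential, SeparableConv2D)

CHECKPOINT_VERSION = 1


def separable_conv(x: np.ndarray, depthwise_kernel: np.ndarray,
                   pointwise_kernel: np.ndarray) -> np.ndarray:
    """Depthwise spatial filtering per channel then 1x1 pointwise mixing.

    x: (H, W, C) or (N, H, W, C); depthwise_kernel: (k, k, C);
    pointwise_kernel: (C, C_out).
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if depthwise_kernel.shape[2] != pointwise_kernel.shape[0]:
        raise ValueError("depthwise and pointwise channel counts disagree")
    mid = SeparableConv2D.depthwise(x, np.asarray(depthwise_kernel, float))
    out = mid @ np.asarray(pointwise_kernel, float)
    return out[0] if squeeze else out


@dataclass(frozen=True)
class BackboneConfig:
    variant: str = "tiny"               # "tiny" or "full"
    input_size: int = 32                # expected square patch side
    width: int = 8                      # base channel count
    head_channels: tuple[int, int, int] = (16, 16, 16)
    dropout_rate: float = 0.5
    batch_norm: bool = True
    feature_dim: int | None = None      # derived from shapes when None

    def __post_init__(self):
        if self.variant not in ("tiny", "full"):
            raise ValueError("variant must be 'tiny' or 'full'")
        if self.input_size % 8:
            raise ValueError("input_size must be a multiple of 8 (three pools)")


@dataclass
class FeatureVector:
    values: np.ndarray
    source: str


@dataclass
class _Block:
    name: str
    layers: list
    residual: Residual | None = None

    def module(self):
        return self.residual if self.residual is not None else Sequential(self.layers)


def _sep(c_in, c_out, rng):
    return SeparableConv2D(c_in, c_out, 3, rng, activation="relu")


def _residual_block(name, c_in, c_out, n_convs, rng):
    body = [_sep(c_in if i == 0 else c_out, c_out, rng) for i in range(n_convs)]
    shortcut = None
    if c_in != c_out:
        proj = Conv2D(c_in, c_out, 1, rng)
        proj.counts_in_census = False
        shortcut = [proj]
    return _Block(name, body, Residual(body, shortcut))


class Backbone:
    """Block list plus census helpers; forward/backward via Sequential."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.width
        blocks: list[_Block] = []
        if config.variant == "full":
            # 2 + 3*2 + 8*3 + 2 + 2 = 36 conv layers in 14 blocks;
            # residuals on blocks 2-13.
            blocks.append(_Block("entry_1", [
                Conv2D(3, w, 3, rng, activation="relu"),
                Conv2D(w, w, 3, rng, activation="relu")]))
            c = w
            for i, c_out in enumerate([w * 2, w * 4, w * 8]):
                blocks.append(_residual_block(f"entry_{i + 2}", c, c_out, 2, rng))
                c = c_out
            for i in range(8):
                blocks.append(_residual_block(f"middle_{i + 1}", c, c, 3, rng))
            blocks.append(_residual_block("exit_1", c, c, 2, rng))
            blocks.append(_Block("exit_2", [_sep(c, c, rng), _sep(c, c, rng)]))
        else:
            blocks.append(_Block("block_1", [
                Conv2D(3, w, 3, rng, activation="relu"),
                Conv2D(w, w, 3, rng, activation="relu")]))
            blocks.append(_residual_block("block_2", w, 2 * w, 2, rng))
            blocks.append(_residual_block("block_3", 2 * w, 2 * w, 2, rng))
            blocks.append(_Block("block_4", [_sep(2 * w, 2 * w, rng),
                                             _sep(2 * w, 2 * w, rng)]))
        self.blocks = blocks
        self.out_channels = blocks[-1].layers[-1].b.shape[0]
        self.net = Sequential([b.module() for b in blocks])

    # census -------------------------------------------------------------

    def conv_layer_count(self) -> int:
        return sum(1 for b in self.blocks for layer in b.layers
                   if getattr(layer, "counts_in_census", False))

    def block_count(self) -> int:
        return len(self.blocks)

    def residual_connection_count(self) -> int:
        return sum(1 for b in self.blocks if b.residual is not None)

    # graph --------------------------------------------------------------

    def forward(self, x, train=False):
        return self.net.forward(x, train=train)

    def backward(self, grad):
        return self.net.backward(grad)

    def parameters(self):
        return self.net.parameters()


class FeatureExtractor:
    """Backbone + custom head; the flatten output is the feature vector."""

    def __init__(self, config: BackboneConfig = BackboneConfig(), seed: int = 0):
        self.config = config
        self.backbone = Backbone(config, seed=seed)
        rng = np.random.default_rng(seed + 1)
        head = []
        c = self.backbone.out_channels
        for ch in config.head_channels:
            head.append(Conv2D(c, ch, 3, rng, activation="relu"))
            if config.batch_norm:
                head.append(BatchNorm(ch))
            head.append(MaxPool2())
            c = ch
        head.append(Flatten())
        self.head = Sequential(head)
        side = config.input_size // 8
        computed = side * side * config.head_channels[-1]
        if config.feature_dim is not None and config.feature_dim != computed:
            raise ValueError(
                f"feature_dim {config.feature_dim} inconsistent with shapes "
                f"(flatten gives {computed})")
        self.feature_dim = computed
        self.dropout = Dropout(config.dropout_rate, np.random.default_rng(seed + 2))
        self.out = Dense(self.feature_dim, 1, rng)

    def parameters(self):
        return (self.backbone.parameters() + self.head.parameters()
                + self.out.parameters())

    def _check_input(self, patches):
        x = np.asarray(patches, dtype=float)
        if x.ndim == 3:
            x = x[None]
        s = self.config.input_size
        if x.shape[1] != s or x.shape[2] != s or x.shape[3] != 3:
            raise ValueError(
                f"patches must be {s}x{s}x3 (got {x.shape[1:]})")
        return x

    def forward(self, patches, train=False):
        """Returns (features n x feature_dim, sigmoid logits n)."""
        x = self._check_input(patches) / 255.0
        h = self.backbone.forward(x, train=train)
        feats = self.head.forward(h, train=train)
        dropped = self.dropout.forward(feats, train=train)
        logits = self.out.forward(dropped, train=train)[:, 0]
        return feats, logits

    def backward(self, dlogits):
        g = self.out.backward(np.asarray(dlogits).reshape(-1, 1))
        g = self.dropout.backward(g)
        g = self.head.backward(g)
        self.backbone.backward(g)


def build_backbone(config: BackboneConfig, seed: int = 0) -> FeatureExtractor:
    """Instantiate the full model (backbone + head) with a fixed seed."""
    return FeatureExtractor(config, seed=seed)


def train_backbone(model: FeatureExtractor, patches, labels, epochs: int = 10,
                   batch_size: int = 16, lr: float = 2e-3, seed: int = 0):
    """Brief supervised training of the sigmoid head (binary cross-entropy).

    ``labels`` are 0/1 (1 = mitotic). Returns the per-epoch loss trace.
    """
    x = np.stack([np.asarray(p) for p in patches])
    y = np.asarray(labels, dtype=float)
    rng = np.random.default_rng(seed)
    opt = Adam(model, lr=lr)
    trace = []
    n = len(y)
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            _, logits = model.forward(x[idx], train=True)
            loss, dlogits = _nn.bce_with_logits(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        trace.append(epoch_loss / n)
    return trace


def extract_features(patches, model: FeatureExtractor,
                     sources=None):
    """Inference-mode features + class probabilities for a patch batch.

    Dropout is disabled and batch norm uses running statistics, so repeated
    calls give identical results. Returns (list of FeatureVector, probs).
    """
    feats, logits = model.forward(patches, train=False)
    probs = _nn.sigmoid(logits)
    if sources is None:
        sources = [f"patch_{i}" for i in range(len(feats))]
    vectors = [FeatureVector(values=f, source=s) for f, s in zip(feats, sources)]
    return vectors, probs


# ---------------------------------------------------------------------------
# I/O


def write_features(vectors, labels, path: str) -> None:
    """Feature matrix as TSV: rows = candidates, columns = features + label."""
    mat = np.stack([v.values for v in vectors])
    df = pd.DataFrame(mat, columns=[f"f{i}" for i in range(mat.shape[1])])
    df.insert(0, "source", [v.source for v in vectors])
    df["label"] = list(labels)
    df.to_csv(path, sep="\t", index=False)


def read_features(path: str):
    df = pd.read_csv(path, sep="\t")
    labels = df.pop("label").to_numpy()
    sources = df.pop("source").to_numpy()
    return df.to_numpy(dtype=float), labels, sources


def save_checkpoint(model: FeatureExtractor, path: str) -> None:
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.parameters())}
    meta = json.dumps({"version": CHECKPOINT_VERSION,
                       "variant": model.config.variant,
                       "input_size": model.config.input_size,
                       "width": model.config.width})
    np.savez(path, __meta__=meta, **arrays)


def load_pretrained_weights(model: FeatureExtractor, path: str) -> None:
    """Load externally supplied weights into an already-built model."""
    data = np.load(path, allow_pickle=False)
    try:
        meta = json.loads(str(data["__meta__"]))
    except KeyError as exc:
        raise ValueError("weight file lacks metadata block") from exc
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported weight-file version {meta.get('version')}")
    params = model.parameters()
    for i, (p, _) in enumerate(params):
        key = f"p{i}"
        if key not in data:
            raise ValueError(f"weight file missing parameter {key}")
        if data[key].shape != p.shape:
            raise ValueError(
                f"parameter {key}: file shape {data[key].shape} "
                f"!= model shape {p.shape}")
        p[...] = data[key]
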