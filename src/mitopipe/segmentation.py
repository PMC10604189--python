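"""U-Net nuclei segmentation and connected-component candidate extraction.

The network is the classic encoder-decoder: per contracting stage two 3x3
convolutions + ReLU then 2x2 max-pool (stride 2), channel count doubling per
stage; per expansive stage a 2x2 transposed convolution halving the channels,
concatenation with the matching encoder output (skip connection), then two
3x3 convolutions + ReLU; a final 1x1 convolution maps to the class channels
and a per-pixel softmax normalises to [0, 1]. All 3x3 convolutions use same
padding so the output resolution equals the input resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label, regionprops

from . import _nn
from ._nn import Conv2D, ConvTranspose2, MaxPool2, relu  # noqa: F401  (relu re-exported)

CHECKPOINT_VERSION = 1


@dataclass
class ConvLayerParams:
    """Weights and bias of one convolution layer (k x k x C_in x C_out)."""

    w: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.w.ndim != 4 or self.w.shape[0] != self.w.shape[1]:
            raise ValueError("w must be (k, k, C_in, C_out) with square kernel")
        if self.b.shape != (self.w.shape[3],):
            raise ValueError("b must have one entry per output channel")


def conv2d(x: np.ndarray, params: ConvLayerParams) -> np.ndarray:
    """Same-padding cross-correlation plus broadcast bias (linear part only).

    ``x`` may be (H, W), (H, W, C) or (N, H, W, C).
    """
    x = np.asarray(x, dtype=float)
    squeeze_batch = squeeze_chan = False
    if x.ndim == 2:
        x = x[..., None]
        squeeze_chan = True
    if x.ndim == 3:
        x = x[None]
        squeeze_batch = True
    out = _nn.conv2d_same(x, params.w, params.b)
    if squeeze_batch:
        out = out[0]
    if squeeze_chan and out.shape[-1] == 1:
        out = out[..., 0]
    return out


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 2
    base_channels: int = 64
    n_classes: int = 2
    input_channels: int = 3

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1 or self.n_classes < 2:
            raise ValueError("invalid U-Net configuration")

    @property
    def encoder_channels(self) -> list[int]:
        """Channel schedule of the contracting path (doubling per stage)."""
        return [self.base_channels * 2 ** d for d in range(self.depth)]

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * 2 ** self.depth


@dataclass
class SegmentationResult:
    prob_map: np.ndarray        # H x W x n_classes in [0, 1]
    mask: np.ndarray            # H x W uint8, channel-1 probability > threshold
    threshold: float = 0.5


class UNet:
    """Encoder-decoder with skip connections; explicit forward/backward."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c_in = config.input_channels
        self.enc_blocks = []
        for ch in config.encoder_channels:
            self.enc_blocks.append((
                Conv2D(c_in, ch, 3, rng, activation="relu"),
                Conv2D(ch, ch, 3, rng, activation="relu"),
                MaxPool2(),
            ))
            c_in = ch
        cb = config.bottleneck_channels
        self.bottleneck = (Conv2D(c_in, cb, 3, rng, activation="relu"),
                           Conv2D(cb, cb, 3, rng, activation="relu"))
        self.dec_blocks = []
        c_in = cb
        for ch in reversed(config.encoder_channels):
            self.dec_blocks.append((
                ConvTranspose2(c_in, ch, rng),
                Conv2D(2 * ch, ch, 3, rng, activation="relu"),
                Conv2D(ch, ch, 3, rng, activation="relu"),
            ))
            c_in = ch
        self.head = Conv2D(c_in, config.n_classes, 1, rng)

    # -- graph -------------------------------------------------------------

    def _layers(self):
        for block in self.enc_blocks:
            yield from block
        yield from self.bottleneck
        for block in self.dec_blocks:
            yield from block
        yield self.head

    def parameters(self):
        return [p for layer in self._layers() for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits (N, H, W, n_classes) for a NHWC batch."""
        x = np.asarray(x, dtype=float)
        mult = 2 ** self.config.depth
        if x.shape[1] % mult or x.shape[2] % mult:
            raise ValueError(
                f"spatial dims must be multiples of {mult} "
                f"(got {x.shape[1]}x{x.shape[2]})"
            )
        skips = []
        h = x
        for c1, c2, pool in self.enc_blocks:
            h = c2.forward(c1.forward(h))
            skips.append(h)
            h = pool.forward(h)
        b1, b2 = self.bottleneck
        h = b2.forward(b1.forward(h))
        for (up, c1, c2), skip in zip(self.dec_blocks, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=-1)
            h = c2.forward(c1.forward(h))
        self._skip_channels = [s.shape[-1] for s in skips]
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        # reversed(dec_blocks) pairs with skips in encoder order
        dskips = []
        for (up, c1, c2), ch in zip(reversed(self.dec_blocks),
                                    self._skip_channels):
            g = c1.backward(c2.backward(g))
            dskips.append(g[..., :ch])
            g = up.backward(g[..., ch:])
        b1, b2 = self.bottleneck
        g = b1.backward(b2.backward(g))
        for (c1, c2, pool), dskip in zip(reversed(self.enc_blocks),
                                         reversed(dskips)):
            g = pool.backward(g) + dskip
            g = c1.backward(c2.backward(g))

    def segment(self, image: np.ndarray, threshold: float = 0.5
                ) -> SegmentationResult:
        img = np.asarray(image, dtype=float)
        if img.ndim == 2:
            img = img[..., None]
        logits = self.forward((img / 255.0)[None])
        prob = _nn.softmax(logits[0], axis=-1)
        mask = (prob[..., 1] > threshold).astype(np.uint8)
        return SegmentationResult(prob_map=prob, mask=mask, threshold=threshold)


def unet_forward(image: np.ndarray, net: UNet,
                 threshold: float = 0.5) -> SegmentationResult:
    """Functional wrapper: probability map + thresholded mask for one tile."""
    return net.segment(image, threshold=threshold)


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainOptions:
    epochs: int = 8
    batch_size: int = 5
    lr: float = 3e-3
    seed: int = 0


def train_unet(tiles, config: UNetConfig, options: TrainOptions = TrainOptions()):
    """Train with per-pixel cross-entropy + Adam; returns (net, loss_trace)."""
    if len(tiles) == 0:
        raise ValueError("cannot train on an empty dataset")
    net = UNet(config, seed=options.seed)
    opt = _nn.Adam(net, lr=options.lr)
    rng = np.random.default_rng(options.seed)
    images = np.stack([t.image for t in tiles]).astype(float) / 255.0
    masks = np.stack([t.mask for t in tiles]).astype(int)
    n = len(tiles)
    trace = []
    for _ in range(options.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, options.batch_size):
            idx = order[start:start + options.batch_size]
            logits = net.forward(images[idx])
            loss, dlogits = _nn.softmax_xent(logits, masks[idx])
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        trace.append(epoch_loss / n)
    return net, trace


def dice_score(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(pred_mask) > 0
    b = np.asarray(true_mask) > 0
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * (a & b).sum() / denom


# ---------------------------------------------------------------------------
# candidate extraction


@dataclass
class Candidate:
    row: float
    col: float
    area: int
    patch: np.ndarray           # patch_size x patch_size x C


def extract_candidates(seg: SegmentationResult, image: np.ndarray,
                       patch_size: int = 32, min_area: int = 30
                       ) -> list[Candidate]:
    """One square crop per connected component above ``min_area``.

    Crops are centred on component centroids (row-major, 0-based, half-open
    windows) and edge-padded near borders.
    """
    mask = np.asarray(seg.mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[..., None]
    labeled = cc_label(mask, connectivity=2)
    pad = patch_size
    padded = np.pad(img, ((pad, pad), (pad, pad), (0, 0)), mode="edge")
    half = patch_size // 2
    out = []
    for region in regionprops(labeled):
        if region.area < min_area:
            continue
        cr, cc = region.centroid
        r0 = int(round(cr)) - half + pad
        c0 = int(round(cc)) - half + pad
        patch = padded[r0:r0 + patch_size, c0:c0 + patch_size]
        out.append(Candidate(row=cr, col=cc, area=int(region.area),
                             patch=patch))
    return out


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(net: UNet, path: str) -> None:
    arrays = {f"p{i}": p for i, (p, _) in enumerate(net.parameters())}
    meta = json.dumps({"version": CHECKPOINT_VERSION,
                       "depth": net.config.depth,
                       "base_channels": net.config.base_channels,
                       "n_classes": net.config.n_classes,
                       "input_channels": net.config.input_channels})
    np.savez(path, __meta__=meta, **arrays)


def load_checkpoint(path: str) -> UNet:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
    net = UNet(UNetConfig(depth=meta["depth"], base_channels=meta["base_channels"],
                          n_classes=meta["n_classes"],
                          input_channels=meta["input_channels"]))
    for i, (p, _) in enumerate(net.parameters()):
        p[...] = data[f"p{i}"]
    return net
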