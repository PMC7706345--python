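"""The modified U-shaped fully convolutional root segmenter.

Encoder-decoder with skip connections ("U" architecture) adapted for
trench-profile tiles: zero-padded 3x3 convolutions keep the spatial
size, batch normalization follows every convolution and every up/down
sampling step, and the head is a single-channel sigmoid map (one class:
root vs. soil).  Training uses Adam (default learning rate 0.001) over
augmented tile pairs, one pass over all pairs per epoch; segmentation
quality is gauged with the Dice coefficient

    Dice = 2 |T ∩ P| / (|T| + |P|)

between the manual label T and the binarized prediction P.

Full-image prediction splits the normalized image into its disjoint
tile grid, runs each tile through the network, and reassembles the
probability tiles in the original order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .augment import AugmentConfig, IDENTITY_AUGMENT, make_epoch
from .raster_io import FrameSpec, RootMask, TrenchImage
from .tiling import assemble_tiles, split_tiles, TileGrid

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedModel",
    "UNet",
    "build_model",
    "train",
    "predict_image",
    "binarize",
    "dice_coefficient",
    "save_model",
    "load_model",
    "TEST_SCALE_MODEL",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``levels`` encoder/decoder stages halve/double the spatial size, so
    ``input_px`` must divide by 2**levels.  Full-scale default: 4 levels,
    64 base channels, 256 px tiles.
    """

    levels: int = 4
    base_channels: int = 64
    input_px: int = 256
    in_channels: int = 3
    out_channels: int = 1
    batch_norm: bool = True
    padding: str = "zero"

    def __post_init__(self) -> None:
        if self.input_px % (2 ** self.levels):
            raise ValueError(
                f"input_px={self.input_px} not divisible by 2^levels={2 ** self.levels}"
            )
        if self.out_channels != 1:
            raise ValueError("single-channel output only")
        if self.padding != "zero":
            raise ValueError("only zero padding is supported")


#: Desk-scale preset used throughout the test battery: 64 px tiles.
TEST_SCALE_MODEL = ModelConfig(levels=3, base_channels=8, input_px=64)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 500
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    batch_size: int = 4
    loss: str = "bce"  # "bce" | "dice"
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate > 0")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold in (0,1)")
        if self.optimizer != "adam":
            raise ValueError("only adam is supported")
        if self.loss not in ("bce", "dice"):
            raise ValueError("loss must be 'bce' or 'dice'")


class UNet:
    """Contracting path + expansive path with concatenating skips."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = [cfg.base_channels * 2 ** i for i in range(cfg.levels + 1)]
        self.encoders = [nn.double_conv(cfg.in_channels if i == 0 else ch[i - 1], ch[i], rng)
                         for i in range(cfg.levels)]
        self.pools = [nn.MaxPool2() for _ in range(cfg.levels)]
        self.bottleneck = nn.double_conv(ch[cfg.levels - 1], ch[cfg.levels], rng)
        # decoder, deepest level first; upsampling followed by batch norm
        self.ups = [nn.Upsample2() for _ in range(cfg.levels)]
        self.up_bns = [nn.BatchNorm2d(ch[i + 1]) for i in reversed(range(cfg.levels))]
        self.decoders = [nn.double_conv(ch[i + 1] + ch[i], ch[i], rng)
                         for i in reversed(range(cfg.levels))]
        self.head = nn.Conv2d(ch[0], cfg.out_channels, rng, k=1)
        self._modules: list[nn.Layer] = (
            self.encoders + [self.bottleneck] + self.up_bns + self.decoders + [self.head]
        )

    def params(self) -> list[nn.Param]:
        return [p for m in self._modules for p in m.params()]

    def buffers(self) -> list[np.ndarray]:
        return [b for m in self._modules for b in m.buffers()]

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        skips = []
        h = x
        for enc, pool in zip(self.encoders, self.pools):
            h = enc.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        h = self.bottleneck.forward(h, training)
        self._skip_channels = []
        for up, bn, dec, skip in zip(self.ups, self.up_bns, self.decoders, reversed(skips)):
            h = up.forward(h, training)
            h = bn.forward(h, training)
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = dec.forward(h, training)
        return self.head.forward(h, training)

    def backward(self, grad: np.ndarray) -> None:
        grad = self.head.backward(grad)
        skip_grads = []
        for bn, up, dec, c_skip in zip(reversed(self.up_bns), reversed(self.ups),
                                       reversed(self.decoders), reversed(self._skip_channels)):
            grad = dec.backward(grad)
            skip_grads.append(grad[:, :c_skip])
            grad = bn.backward(grad[:, c_skip:])
            grad = up.backward(grad)
        grad = self.bottleneck.backward(grad)
        # skip_grads[0] is the shallowest level; walk encoders deepest-first
        for enc, pool, gskip in zip(reversed(self.encoders), reversed(self.pools),
                                    reversed(skip_grads)):
            grad = pool.backward(grad)
            grad = enc.backward(grad + gskip)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities in (0,1) for a batch (N,C,H,W)."""
        return nn.sigmoid(self.forward_logits(x, training=False))


def build_model(cfg: ModelConfig, seed: int = 0) -> UNet:
    """Seeded construction of an untrained network."""
    return UNet(cfg, seed)


@dataclass
class TrainedModel:
    net: UNet
    model_config: ModelConfig
    train_config: TrainConfig
    history: list[dict] = field(default_factory=list)


def dice_coefficient(truth: RootMask | np.ndarray, pred: RootMask | np.ndarray) -> float:
    """2|T∩P| / (|T|+|P|); 1.0 when both masks are empty."""
    t = truth.pixels if isinstance(truth, RootMask) else np.asarray(truth)
    p = pred.pixels if isinstance(pred, RootMask) else np.asarray(pred)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch {t.shape} vs {p.shape}")
    for a in (t, p):
        if not np.all(np.isin(np.unique(a), (0, 1))):
            raise ValueError("masks must be binary")
    t = t.astype(bool)
    p = p.astype(bool)
    denom = int(t.sum()) + int(p.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((t & p).sum()) / denom


def binarize(prob: np.ndarray, threshold: float = 0.5,
             frame: FrameSpec | None = None) -> RootMask | np.ndarray:
    """Pixel = 1 iff probability strictly exceeds the threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0,1)")
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0,1]")
    mask = (prob > threshold).astype(np.uint8)
    return mask if frame is None else RootMask(mask, frame)


def _to_batch(images: list[np.ndarray]) -> np.ndarray:
    """uint8 HWC tiles -> float32 NCHW in [0,1]."""
    arr = np.stack([im.astype(np.float32) / 255.0 for im in images])
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def train(model: UNet, pairs: list[tuple[np.ndarray, np.ndarray]],
          tcfg: TrainConfig, acfg: AugmentConfig | None = None,
          checkpoint: str | Path | None = None,
          log_every: int | None = None) -> TrainedModel:
    """Train on (image tile, binary mask tile) pairs.

    One pass over all pairs per epoch (augmented anew each epoch);
    history records per-epoch mean loss and aggregate training Dice.
    Deterministic given ``tcfg.seed``/``acfg.seed``.
    """
    if not pairs:
        raise ValueError("empty dataset")
    for _, m in pairs:
        if not np.all(np.isin(np.unique(m), (0, 1))):
            raise ValueError("masks must be binary")
    if acfg is None:
        acfg = IDENTITY_AUGMENT
    loss_fn = nn.bce_with_logits if tcfg.loss == "bce" else nn.soft_dice_loss
    opt = nn.Adam(model.params(), lr=tcfg.learning_rate)
    order_rng = np.random.default_rng((tcfg.seed, 0xA5))
    history: list[dict] = []
    for epoch in range(tcfg.epochs):
        stream = list(make_epoch(pairs, acfg, epoch))
        order_rng.shuffle(stream)
        losses = []
        inter = 0
        sizes = 0
        for i in range(0, len(stream), tcfg.batch_size):
            chunk = stream[i:i + tcfg.batch_size]
            x = _to_batch([im for im, _ in chunk])
            y = np.stack([m for _, m in chunk]).astype(np.float32)[:, None]
            opt.zero_grad()
            z = model.forward_logits(x, training=True)
            loss, dz = loss_fn(z, y)
            model.backward(dz)
            opt.step()
            losses.append(loss)
            pred = nn.sigmoid(z) > tcfg.threshold
            inter += int((pred & (y > 0.5)).sum())
            sizes += int(pred.sum()) + int((y > 0.5).sum())
        dice = 1.0 if sizes == 0 else 2.0 * inter / sizes
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "dice": dice})
        if log_every and (epoch + 1) % log_every == 0:
            print(f"epoch {epoch + 1}/{tcfg.epochs}  loss={history[-1]['loss']:.4f}  "
                  f"dice={dice:.3f}")
    trained = TrainedModel(model, model.cfg, tcfg, history)
    if checkpoint is not None:
        save_model(trained, checkpoint)
    return trained


def predict_tiles(model: UNet, tiles: list[np.ndarray], batch_size: int = 8) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for i in range(0, len(tiles), batch_size):
        x = _to_batch(tiles[i:i + batch_size])
        p = model.predict_proba(x)  # (n, 1, h, w)
        out.extend(np.asarray(p[j, 0], dtype=np.float32) for j in range(p.shape[0]))
    return out


def predict_image(model: TrainedModel | UNet, image: TrenchImage | np.ndarray) -> np.ndarray:
    """Tile -> per-tile forward pass -> reassemble, returning a
    probability raster in [0,1] with the image's spatial shape."""
    net = model.net if isinstance(model, TrainedModel) else model
    px = image.pixels if isinstance(image, TrenchImage) else np.asarray(image)
    tile_px = net.cfg.input_px
    grid = split_tiles(px, tile_px)
    probs = predict_tiles(net, grid.tiles)
    return assemble_tiles(TileGrid(probs, tile_px, grid.grid, grid.provenance))


# ---------------------------------------------------------------- checkpoints

_FORMAT_VERSION = 1


def save_model(trained: TrainedModel, path: str | Path) -> None:
    """Single-archive checkpoint: weights + buffers + configs + version."""
    net = trained.net
    arrays = {f"param_{i}": p.value for i, p in enumerate(net.params())}
    arrays |= {f"buffer_{i}": b for i, b in enumerate(net.buffers())}
    meta = json.dumps({
        "format_version": _FORMAT_VERSION,
        "model_config": asdict(trained.model_config),
        "train_config": asdict(trained.train_config),
        "history": trained.history,
        "init_seed": 0,
    })
    with open(path, "wb") as fh:  # file handle so np.savez keeps the exact name
        np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    """Reload a checkpoint; predictions are bit-identical to the saved
    model's."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta["format_version"] != _FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        mcfg = ModelConfig(**meta["model_config"])
        tcfg = TrainConfig(**meta["train_config"])
        net = UNet(mcfg, seed=meta.get("init_seed", 0))
        for i, p in enumerate(net.params()):
            val = npz[f"param_{i}"]
            if val.shape != p.value.shape:
                raise ValueError("checkpoint/model shape mismatch")
            p.value = val.astype(np.float32)
        for i, b in enumerate(net.buffers()):
            b[...] = npz[f"buffer_{i}"]
    return TrainedModel(net, mcfg, tcfg, meta["history"])
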