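"""Paired augmentation of (image, mask) training tiles.

Each draw applies one random geometric transform chain — horizontal
flip, rotation, isotropic scale — identically to the photograph and its
label mask (nearest-neighbor for the mask so labels stay binary), then
photometric jitter — intensity, gamma, chroma — to the photograph only.
Transforms are drawn once per pair in the fixed order
flip -> rotate -> scale -> intensity -> gamma -> chroma, and photometric
operations act in [0, 1] normalized space, clipped back to [0, 1].

The epoch stream is fully deterministic given (seed, epoch_index).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import rescale, rotate

__all__ = ["AugmentConfig", "augment_pair", "make_epoch", "IDENTITY_AUGMENT"]


@dataclass(frozen=True)
class AugmentConfig:
    """Ranges for the per-pair random transforms.

    Defaults are conservative: rotation within +/-15 degrees, scale
    0.9-1.1, horizontal flips allowed, brightness 0.8-1.2x, gamma
    0.7-1.4, saturation 0.8-1.2x.  All overridable via the YAML config.
    """

    rotation_deg_range: tuple[float, float] = (-15.0, 15.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    flip_horizontal: bool = True
    intensity_range: tuple[float, float] = (0.8, 1.2)
    gamma_range: tuple[float, float] = (0.7, 1.4)
    chroma_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rotation_deg_range", "scale_range", "intensity_range",
                     "gamma_range", "chroma_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lo > hi")
        if self.scale_range[0] <= 0 or self.gamma_range[0] <= 0:
            raise ValueError("scale and gamma must be strictly positive")


#: Degenerate config: every range collapsed to the identity transform.
IDENTITY_AUGMENT = AugmentConfig(
    rotation_deg_range=(0.0, 0.0), scale_range=(1.0, 1.0), flip_horizontal=False,
    intensity_range=(1.0, 1.0), gamma_range=(1.0, 1.0), chroma_range=(1.0, 1.0),
)


def _center_fit(arr: np.ndarray, h: int, w: int) -> np.ndarray:
    """Center-crop or zero-pad a raster to (h, w)."""
    ah, aw = arr.shape[:2]
    # crop
    r0 = max((ah - h) // 2, 0)
    c0 = max((aw - w) // 2, 0)
    arr = arr[r0:r0 + min(ah, h), c0:c0 + min(aw, w)]
    ah, aw = arr.shape[:2]
    if ah == h and aw == w:
        return arr
    pad = [( (h - ah) // 2, h - ah - (h - ah) // 2),
           ( (w - aw) // 2, w - aw - (w - aw) // 2)]
    if arr.ndim == 3:
        pad.append((0, 0))
    return np.pad(arr, pad)


def augment_pair(image: np.ndarray, mask: np.ndarray, cfg: AugmentConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One augmented draw of a (tile image, tile mask) pair.

    Output shapes equal input shapes; the mask stays binary; identity
    ranges return the inputs bit-exactly.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(f"shape mismatch: image {image.shape[:2]} vs mask {mask.shape[:2]}")
    h, w = image.shape[:2]

    flip = bool(cfg.flip_horizontal and rng.random() < 0.5)
    angle = float(rng.uniform(*cfg.rotation_deg_range))
    scale = float(rng.uniform(*cfg.scale_range))
    intensity = float(rng.uniform(*cfg.intensity_range))
    gamma = float(rng.uniform(*cfg.gamma_range))
    chroma = float(rng.uniform(*cfg.chroma_range))

    img = image.astype(np.float32) / 255.0 if image.dtype == np.uint8 else image.astype(np.float32)
    msk = mask.astype(np.float32)

    if flip:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    if angle != 0.0:
        img = rotate(img, angle, resize=False, order=1, mode="constant", cval=0, preserve_range=True)
        msk = rotate(msk, angle, resize=False, order=0, mode="constant", cval=0, preserve_range=True)
    if scale != 1.0:
        cax = 2 if img.ndim == 3 else None
        img = rescale(img, scale, order=1, preserve_range=True, channel_axis=cax,
                      anti_aliasing=scale < 1)
        msk = rescale(msk, scale, order=0, preserve_range=True, anti_aliasing=False)
        img = _center_fit(img, h, w)
        msk = _center_fit(msk, h, w)

    if intensity != 1.0:
        img = img * intensity
    if gamma != 1.0:
        img = np.clip(img, 0.0, 1.0) ** gamma
    if chroma != 1.0 and img.ndim == 3:
        hsv = rgb2hsv(np.clip(img, 0.0, 1.0))
        hsv[..., 1] = np.clip(hsv[..., 1] * chroma, 0.0, 1.0)
        img = hsv2rgb(hsv)
    img = np.clip(img, 0.0, 1.0)

    if image.dtype == np.uint8:
        out_img = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    else:
        out_img = img.astype(np.float32)
    out_msk = (msk > 0.5).astype(mask.dtype if mask.dtype != np.bool_ else np.uint8)
    return out_img, out_msk


def make_epoch(pairs: list[tuple[np.ndarray, np.ndarray]], cfg: AugmentConfig,
               epoch_index: int) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield one augmented draw of every pair, in order.

    Exactly ``len(pairs)`` pairs per epoch; the stream is a pure function
    of (cfg.seed, epoch_index).
    """
    if not pairs:
        raise ValueError("empty training pair list")
    rng = np.random.default_rng((cfg.seed, epoch_index))
    for image, mask in pairs:
        yield augment_pair(image, mask, cfg, rng)
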