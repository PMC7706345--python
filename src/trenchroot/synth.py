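"""Synthetic trench-profile images with pixel-exact ground truth.

Emulates a photographed profile wall: a brown-textured soil background
with a vertical illumination gradient and per-image exposure jitter
(field walls vary with sunlight and soil horizon), crossed by thin,
lighter root strokes that emanate from the hill point at the top center
and drift downward/outward.  Every sample carries

* the rendered photograph,
* a label mask built exactly like the manual annotation convention —
  centerlines dilated to a fixed pencil width (4 px by default)
  regardless of the rendered root width, and
* truth root-distribution parameters computed from the exact 1-px
  centerline raster through the phenotyping math itself (fold +
  cumulative quantiles), bypassing segmentation entirely.

Root maximum depths are drawn from an exponential law censored at the
frame depth, and each root contributes exactly one centerline pixel per
row it occupies; the depth distribution of centerline pixels is then a
truncated exponential, so Depth50 has a closed-form target:
median = -ln(1 - 0.5 (1 - exp(-lambda D))) / lambda.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter, zoom

from .phenotype import RootDistributionParams, phenotype_image
from .raster_io import (DEFAULT_FRAME, FrameSpec, RootMask, TrenchImage,
                        write_image, write_mask)

__all__ = ["SynthConfig", "generate_sample", "generate_dataset",
           "truncated_exponential_median"]

#: Soil palettes (RGB): dark humic topsoil loam vs red-brown subsoil clay loam.
SOIL_PALETTES = {
    "topsoil dark loam": (92, 70, 50),
    "subsoil red-brown": (128, 84, 58),
}

ROOT_COLOR = (208, 192, 160)  # pale, desaturated — roots read lighter than soil


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.

    ``depth_law`` controls the depth distribution of centerline pixels:
    ``{"kind": "truncated_exponential", "rate_per_cm": r}`` draws root
    maximum depths from Exp(r) censored at the frame depth;
    ``{"kind": "fixed_path", "depth_cm": d}`` grows every root straight
    down to depth d under the hill.  ``lateral_drift`` is the horizontal
    step (px) per row of descent; ``label_width_px`` is the annotation
    pencil width applied to centerlines irrespective of rendered width.
    """

    n_roots: int = 25
    root_width_px_range: tuple[int, int] = (2, 6)
    depth_law: dict = field(default_factory=lambda: {
        "kind": "truncated_exponential", "rate_per_cm": 0.1})
    lateral_drift: float = 0.5
    crown_spread_cm: float = 6.0
    min_separation_px: int = 6
    soil_palette: str = "topsoil dark loam"
    illumination_gradient: float = 0.25
    label_width_px: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roots < 1:
            raise ValueError("need at least one root")
        lo, hi = self.root_width_px_range
        if lo < 1 or lo > hi:
            raise ValueError("invalid root width range")
        if self.label_width_px < 1:
            raise ValueError("label_width_px >= 1")
        if self.min_separation_px < 0:
            raise ValueError("min_separation_px >= 0")
        kind = self.depth_law.get("kind")
        if kind == "truncated_exponential":
            if self.depth_law.get("rate_per_cm", 0) <= 0:
                raise ValueError("rate_per_cm must be positive")
        elif kind == "fixed_path":
            if self.depth_law.get("depth_cm", 0) <= 0:
                raise ValueError("depth_cm must be positive")
        else:
            raise ValueError(f"unknown depth law {kind!r}")
        if self.soil_palette not in SOIL_PALETTES:
            raise ValueError(f"unknown palette {self.soil_palette!r}")


def truncated_exponential_median(rate_per_cm: float, depth_cm: float) -> float:
    """Closed-form median of Exp(rate) truncated to [0, depth_cm]."""
    return -np.log(1.0 - 0.5 * (1.0 - np.exp(-rate_per_cm * depth_cm))) / rate_per_cm


def _root_depths_px(cfg: SynthConfig, frame: FrameSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-root maximum depth in rows (>=1)."""
    h = frame.depth_px
    kind = cfg.depth_law["kind"]
    if kind == "fixed_path":
        d_px = int(round(cfg.depth_law["depth_cm"] * frame.resolution_px_per_cm))
        return np.full(cfg.n_roots, min(max(d_px, 1), h), dtype=int)
    rate = cfg.depth_law["rate_per_cm"]
    # Exp(rate) censored at the frame depth: the surviving fraction of
    # roots passes any depth x with probability e^(-rate x), which makes
    # the *pixel* depth law truncated-exponential.  Depths are drawn by
    # jittered stratification (one uniform per equal-probability
    # stratum), so the realized pixel histogram tracks the law with
    # O(1/n) error instead of O(1/sqrt(n)) sampling noise.
    n = cfg.n_roots
    u = (rng.permutation(n) + rng.random(n)) / n
    d_cm = -np.log1p(-u) / rate
    d_px = np.minimum(np.round(d_cm * frame.resolution_px_per_cm).astype(int), h)
    return np.maximum(d_px, 1)


def _centerlines(cfg: SynthConfig, frame: FrameSpec,
                 rng: np.random.Generator) -> tuple[np.ndarray, list[np.ndarray]]:
    """Render 1-px centerlines: one pixel per occupied row per root.

    Roots lie side by side on the wall, never on top of each other: a
    pixel whose (row, distance-from-hill) slot is already taken — on
    either side, since the phenotyping fold ORs the two halves — is
    nudged to the nearest free distance.  The folded centerline raster
    therefore keeps exactly one pixel per root per occupied row, so the
    depth distribution of root pixels follows the configured law
    exactly (up to integer-row rounding).

    Returns the combined centerline raster and per-root (row, col) paths.
    """
    h, w = frame.shape
    hill = frame.hill_column_px
    max_dist = max(hill, w - 1 - hill)
    gap = cfg.min_separation_px
    raster = np.zeros((h, w), dtype=np.uint8)
    taken = np.zeros((h, max_dist + 1), dtype=bool)  # folded occupancy
    paths = []
    depths = _root_depths_px(cfg, frame, rng)
    spread_px = cfg.crown_spread_cm * frame.resolution_px_per_cm

    def free(r: int, dist: int) -> bool:
        return not taken[r, max(dist - gap, 0):dist + gap + 1].any()

    for d in depths:
        side = rng.choice((-1.0, 1.0))
        col = float(hill) + side * rng.uniform(0.0, spread_px)
        steps = rng.normal(side * cfg.lateral_drift, cfg.lateral_drift, size=d)
        path = np.empty((d, 2), dtype=int)
        for r in range(d):
            dist = int(round(col)) - hill
            sign = 1 if dist >= 0 else -1
            dist = min(abs(dist), max_dist)
            if not free(r, dist):
                for off in range(1, max_dist + 1):  # nearest well-separated slot
                    if dist + off <= max_dist and free(r, dist + off):
                        dist = dist + off
                        break
                    if dist - off >= 0 and free(r, dist - off):
                        dist = dist - off
                        break
            taken[r, dist] = True
            c = int(np.clip(hill + sign * dist, 0, w - 1))
            raster[r, c] = 1
            path[r] = (r, c)
            col = float(c) + steps[r]  # the walk continues from the placed pixel
        paths.append(path)
    return raster, paths


def _square(width: int) -> np.ndarray:
    return np.ones((width, width), dtype=bool)


def _dilated_stroke(path: np.ndarray, shape: tuple[int, int], width: int) -> np.ndarray:
    """Boolean stroke raster: path pixels dilated to ``width``, computed
    on the path's bounding box for speed."""
    h, w = shape
    r0, c0 = path.min(axis=0)
    r1, c1 = path.max(axis=0)
    m = width  # margin
    r0, c0 = max(r0 - m, 0), max(c0 - m, 0)
    r1, c1 = min(r1 + m, h - 1), min(c1 + m, w - 1)
    box = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    box[path[:, 0] - r0, path[:, 1] - c0] = True
    if width > 1:
        box = binary_dilation(box, structure=_square(width))
    out = np.zeros(shape, dtype=bool)
    out[r0:r1 + 1, c0:c1 + 1] = box
    return out


def _render_image(cfg: SynthConfig, frame: FrameSpec, paths: list[np.ndarray],
                  rng: np.random.Generator) -> np.ndarray:
    h, w = frame.shape
    base = np.array(SOIL_PALETTES[cfg.soil_palette], dtype=np.float32) / 255.0
    # low-frequency correlated soil texture, rendered coarse then upsampled
    coarse = gaussian_filter(rng.normal(0.0, 1.0, size=(h // 8 + 2, w // 8 + 2)),
                             sigma=max(h, w) / 320.0)
    texture = zoom(coarse, 8, order=1)[:h, :w]
    texture = 1.0 + 0.35 * texture / (np.abs(texture).max() + 1e-9)
    fine = 1.0 + 0.04 * rng.normal(0.0, 1.0, size=(h, w))
    rows = np.linspace(-0.5, 0.5, h)[:, None]
    illum = 1.0 + cfg.illumination_gradient * rows
    exposure = rng.uniform(0.8, 1.2)  # sunlight / exposure jitter per image
    img = (base[None, None, :] * (texture * fine * illum * exposure)[..., None]).astype(np.float32)

    root_base = np.array(ROOT_COLOR, dtype=np.float32) / 255.0
    lo, hi = cfg.root_width_px_range
    for path in paths:
        width = int(rng.integers(lo, hi + 1))
        shade = np.clip(root_base * rng.uniform(0.85, 1.1), 0, 1)
        alpha = rng.uniform(0.75, 0.95)  # roots partly soiled, never pure white
        stroke = _dilated_stroke(path, (h, w), width)
        img[stroke] = (1 - alpha) * img[stroke] + alpha * shade
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def generate_sample(cfg: SynthConfig, frame: FrameSpec = DEFAULT_FRAME,
                    ) -> tuple[TrenchImage, RootMask, RootDistributionParams]:
    """One synthetic (photograph, truth mask, truth parameters) sample.

    Bit-identical for identical (cfg, frame); the truth mask is exactly
    the centerline raster dilated to ``label_width_px`` (no
    anti-aliasing), and truth parameters come from the centerline raster
    via the phenotyping math (fold + quantiles; no thinning needed on a
    1-px raster).
    """
    rng = np.random.default_rng((cfg.seed, 0x5EED))
    centerline, paths = _centerlines(cfg, frame, rng)
    mask_px = binary_dilation(centerline.astype(bool), structure=_square(cfg.label_width_px)) \
        if cfg.label_width_px > 1 else centerline.astype(bool)
    image = _render_image(cfg, frame, paths, rng)
    truth = phenotype_image(centerline, frame=frame,
                            hill_column=frame.hill_column_px, skeletonized=True)
    return (TrenchImage(image, frame),
            RootMask(mask_px.astype(np.uint8), frame),
            truth)


def generate_dataset(cfg: SynthConfig, n_images: int, out_dir: str | Path,
                     split: tuple[int, int] | None = None,
                     frame: FrameSpec = DEFAULT_FRAME,
                     rate_per_cm_range: tuple[float, float] | None = (0.03, 0.14),
                     ) -> Path:
    """Write a reproducible directory of images, masks and truth values.

    Layout: ``out/images/img_NNN.png``, ``out/masks/img_NNN.png`` and
    ``out/truth.csv`` with per-image split tag, Depth50, Width50 and
    root length.  ``split=(n_train, n_val)`` must sum to ``n_images``.

    When the depth law is truncated-exponential, per-image rates are
    log-spaced across ``rate_per_cm_range`` (then shuffled), emulating a
    panel of varieties whose median rooting depths span roughly 5-23 cm;
    pass ``rate_per_cm_range=None`` to keep one rate for every image.
    """
    if n_images < 2:
        raise ValueError("need n_images >= 2")
    if split is None:
        n_val = max(n_images // 6, 1)
        split = (n_images - n_val, n_val)
    if split[0] + split[1] != n_images or min(split) < 0:
        raise ValueError(f"split {split} does not partition {n_images} images")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    vary_rate = (rate_per_cm_range is not None
                 and cfg.depth_law["kind"] == "truncated_exponential")
    if vary_rate:
        rates = np.geomspace(rate_per_cm_range[0], rate_per_cm_range[1], n_images)
        rates = np.random.default_rng((cfg.seed, 0xD1CE)).permutation(rates)
    rows = []
    for i in range(n_images):
        overrides: dict = {"seed": _image_seed(cfg.seed, i)}
        if vary_rate:
            overrides["depth_law"] = {"kind": "truncated_exponential",
                                      "rate_per_cm": float(rates[i])}
        sub_cfg = SynthConfig(**{**cfg.__dict__, **overrides})
        image, mask, truth = generate_sample(sub_cfg, frame)
        name = f"img_{i:03d}.png"
        write_image(image.pixels, out / "images" / name)
        write_mask(mask, out / "masks" / name)
        rows.append({
            "image": name,
            "split": "train" if i < split[0] else "val",
            "depth50_cm": f"{truth.depth50_cm:.4f}",
            "width50_cm": f"{truth.width50_cm:.4f}",
            "root_length_cm": f"{truth.total_root_length_cm:.4f}",
        })
    with open(out / "truth.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return out


def _image_seed(seed: int, index: int) -> int:
    """Stable per-image sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2 ** 31))
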