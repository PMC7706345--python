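"""Raster I/O and frame normalization for trench-profile photographs.

A trench-profile photograph shows a flushed vertical soil wall next to a
rice hill.  All downstream analysis happens in a *normalized frame*: a
crop of fixed physical extent (60 cm deep x 60 cm wide by default) at a
fixed resolution (25.6 px/cm, i.e. 256 dots per 10 cm), with the soil
surface on row 0 and the hill at a known column.  Raw photographs are
mapped into that frame by rotation, rescaling from the in-image scale
bar, and cropping; the per-image geometry is supplied as a
:class:`FrameAnnotation` sidecar (no automatic scale-bar detection).

Lens distortion is assumed corrected upstream; inputs are treated as
rectilinear.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import rescale, rotate

__all__ = [
    "FrameSpec",
    "FrameAnnotation",
    "TrenchImage",
    "RootMask",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "normalize_frame",
    "read_annotations",
]


@dataclass(frozen=True)
class FrameSpec:
    """Geometry of the normalized trench frame.

    Defaults encode 256 dots per 10 cm (25.6 px/cm) over a 60 cm x 60 cm
    wall, i.e. a 1536 x 1536 raster, with the hill at the center column.
    """

    resolution_px_per_cm: float = 25.6
    width_cm: float = 60.0
    depth_cm: float = 60.0
    hill_column_px: int | None = None

    def __post_init__(self) -> None:
        if self.resolution_px_per_cm <= 0:
            raise ValueError("resolution must be positive")
        w = self.resolution_px_per_cm * self.width_cm
        d = self.resolution_px_per_cm * self.depth_cm
        if abs(w - round(w)) > 1e-9 or abs(d - round(d)) > 1e-9:
            raise ValueError("resolution x extent must give integer pixel dimensions")
        if self.hill_column_px is None:
            object.__setattr__(self, "hill_column_px", self.width_px // 2)
        if not 0 <= self.hill_column_px < self.width_px:
            raise ValueError("hill_column_px outside frame")

    @property
    def width_px(self) -> int:
        return int(round(self.resolution_px_per_cm * self.width_cm))

    @property
    def depth_px(self) -> int:
        return int(round(self.resolution_px_per_cm * self.depth_cm))

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) = (depth, width) in pixels."""
        return (self.depth_px, self.width_px)

    @property
    def cm_per_px(self) -> float:
        return 1.0 / self.resolution_px_per_cm


#: Test-scale frame: same 60 cm x 60 cm wall at 6.4 px/cm -> 384 x 384 px,
#: which still tiles into a 6 x 6 grid of 64 px tiles.
TEST_FRAME = FrameSpec(resolution_px_per_cm=6.4)

DEFAULT_FRAME = FrameSpec()


@dataclass(frozen=True)
class FrameAnnotation:
    """Per-image manual normalization geometry.

    ``rotation_deg`` is the counterclockwise correction applied first;
    ``scale_px_per_cm_raw`` is the raw resolution measured on the scale
    bar; ``crop_origin_px`` is the (row, col) of the soil-surface /
    left-edge corner *after* rotation and rescaling to the target
    resolution; ``hill_column_raw_px`` is unused by the geometry (the
    hill column in the normalized frame lives on :class:`FrameSpec`).
    """

    rotation_deg: float = 0.0
    scale_px_per_cm_raw: float = 25.6
    crop_origin_px: tuple[int, int] = (0, 0)
    hill_column_raw_px: int | None = None

    def __post_init__(self) -> None:
        if self.scale_px_per_cm_raw <= 0:
            raise ValueError("scale_px_per_cm_raw must be positive")


@dataclass
class TrenchImage:
    """RGB raster in the normalized frame (row 0 = soil surface)."""

    pixels: np.ndarray
    frame: FrameSpec = field(default_factory=FrameSpec)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected 3 channels, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError("expected 8-bit pixels")
        if px.shape[:2] != self.frame.shape:
            raise ValueError(
                f"raster shape {px.shape[:2]} does not match frame {self.frame.shape}"
            )
        self.pixels = px


@dataclass
class RootMask:
    """Binary root raster in the normalized frame; holds either a manual
    label (truth) or a model prediction."""

    pixels: np.ndarray
    frame: FrameSpec = field(default_factory=FrameSpec)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be single-channel")
        vals = np.unique(px)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, got {vals[:10]}")
        if px.shape != self.frame.shape:
            raise ValueError(
                f"mask shape {px.shape} does not match frame {self.frame.shape}"
            )
        self.pixels = px.astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF photograph as an 8-bit RGB array (H, W, 3)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected 3 channels, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"expected 8-bit image, got {arr.dtype}")
    return arr


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.dtype != np.uint8:
        raise ValueError("expected 8-bit RGB array")
    Image.fromarray(pixels, mode="RGB").save(path)


def read_mask(path: str | Path, frame: FrameSpec | None = None) -> RootMask | np.ndarray:
    """Read an 8-bit single-channel mask PNG; values > 127 map to 1.

    Returns a bare array if ``frame`` is None, else a :class:`RootMask`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"expected single-channel mask, got shape {arr.shape}")
    binary = (arr > 127).astype(np.uint8)
    if frame is None:
        return binary
    return RootMask(binary, frame)


def write_mask(mask: RootMask | np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    px = mask.pixels if isinstance(mask, RootMask) else np.asarray(mask)
    vals = np.unique(px)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask must be binary, got values {vals[:10]}")
    Image.fromarray((px * 255).astype(np.uint8), mode="L").save(path)


def _normalize(raw: np.ndarray, ann: FrameAnnotation, frame: FrameSpec, order: int) -> np.ndarray:
    """Rotate -> rescale to target resolution -> crop, with the given
    interpolation order (1 = bilinear for photos, 0 = nearest for masks)."""
    zoom = frame.resolution_px_per_cm / ann.scale_px_per_cm_raw
    out = np.asarray(raw)
    was_int = np.issubdtype(out.dtype, np.integer)
    if ann.rotation_deg != 0.0:
        out = rotate(out, ann.rotation_deg, resize=True, order=order,
                     preserve_range=True, mode="constant", cval=0)
    if zoom != 1.0:
        channel_axis = 2 if out.ndim == 3 else None
        out = rescale(out, zoom, order=order, preserve_range=True,
                      channel_axis=channel_axis, anti_aliasing=(order > 0 and zoom < 1))
    r0, c0 = ann.crop_origin_px
    h, w = frame.shape
    if r0 < 0 or c0 < 0 or r0 + h > out.shape[0] or c0 + w > out.shape[1]:
        raise ValueError(
            f"crop window ({r0}:{r0 + h}, {c0}:{c0 + w}) exceeds rotated/scaled "
            f"raster of shape {out.shape[:2]}"
        )
    out = out[r0:r0 + h, c0:c0 + w]
    if was_int:
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out


def normalize_frame(raw: np.ndarray, ann: FrameAnnotation, frame: FrameSpec = DEFAULT_FRAME) -> TrenchImage:
    """Map a raw photograph into the normalized frame.

    Rotation is applied first, then rescaling so that the target
    resolution holds, then a half-open crop window of exactly
    ``frame.shape`` starting at ``ann.crop_origin_px``.  Bilinear
    resampling.
    """
    raw = np.asarray(raw)
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError("expected 3-channel raw image")
    return TrenchImage(_normalize(raw, ann, frame, order=1), frame)


def normalize_mask(raw: np.ndarray, ann: FrameAnnotation, frame: FrameSpec = DEFAULT_FRAME) -> RootMask:
    """Same geometry as :func:`normalize_frame` but nearest-neighbor, so
    labels stay binary."""
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise ValueError("expected single-channel mask")
    out = _normalize(raw.astype(np.uint8), ann, frame, order=0)
    return RootMask((out > 0).astype(np.uint8), frame)


def read_annotations(path: str | Path) -> dict[str, FrameAnnotation]:
    """Read a sidecar CSV with columns
    image,rotation_deg,scale_px_per_cm,crop_row,crop_col,hill_col."""
    out: dict[str, FrameAnnotation] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["image"]] = FrameAnnotation(
                rotation_deg=float(row["rotation_deg"]),
                scale_px_per_cm_raw=float(row["scale_px_per_cm"]),
                crop_origin_px=(int(row["crop_row"]), int(row["crop_col"])),
                hill_column_raw_px=int(row["hill_col"]) if row.get("hill_col") else None,
            )
    return out
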