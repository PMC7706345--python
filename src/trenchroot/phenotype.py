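"""Root-distribution phenotyping: fold, skeletonize, Depth50/Width50.

A binary root mask of the trench wall is folded in half about the hill
column (left and right halves combined by logical OR), thinned to 1-px
centerlines, and summarized by cumulative-length quantiles:

* ``Depth50`` — the depth (cm from the soil surface) above which 50% of
  the total skeletonized root length lies; the vertical centroid-quantile
  of the root distribution.
* ``Width50`` — the horizontal distance from the hill within which 50%
  of the total root length lies, measured on the folded raster.

One skeleton pixel corresponds to one pixel edge of root length:
1/25.6 cm ~ 0.39 mm at the full-scale frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import skeletonize

from .raster_io import FrameSpec, RootMask

__all__ = [
    "Skeleton",
    "CumulativeProfile",
    "RootDistributionParams",
    "fold_half",
    "skeletonize_mask",
    "root_length_cm",
    "cumulative_profile",
    "quantile_distance",
    "phenotype_image",
]


@dataclass
class Skeleton:
    """1-px-wide binary raster after folding + thinning.

    Rows are the depth axis; columns are distance from the hill."""

    pixels: np.ndarray
    frame: FrameSpec

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass
class CumulativeProfile:
    """Cumulative root-length fraction along one axis, in 1-px bins."""

    axis: str  # "depth" | "width"
    bin_cm: float
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        if self.axis not in ("depth", "width"):
            raise ValueError("axis must be 'depth' or 'width'")
        c = np.asarray(self.cumulative, dtype=float)
        if np.any(np.diff(c) < -1e-12):
            raise ValueError("cumulative profile must be non-decreasing")
        self.cumulative = c


@dataclass
class RootDistributionParams:
    depth50_cm: float
    width50_cm: float
    total_root_length_cm: float


def fold_half(mask: RootMask | np.ndarray, hill_column: int | None = None) -> np.ndarray:
    """Fold a mask about the hill column, OR-ing the halves.

    Output column ``d`` holds pixels at horizontal distance ``d`` from
    the hill on either side; width = max(left, right) extent.  Roots
    overlapping after the fold merge (OR, not sum) — the folded object is
    still a binary image that is subsequently skeletonized.
    """
    if isinstance(mask, RootMask):
        px = mask.pixels
        hill = mask.frame.hill_column_px if hill_column is None else hill_column
    else:
        px = np.asarray(mask)
        if hill_column is None:
            hill = px.shape[1] // 2
        else:
            hill = hill_column
    h, w = px.shape
    if not 0 <= hill < w:
        raise ValueError(f"hill column {hill} outside raster of width {w}")
    left = px[:, hill::-1]          # distance 0 .. hill
    right = px[:, hill:]            # distance 0 .. w-1-hill
    out_w = max(left.shape[1], right.shape[1])
    folded = np.zeros((h, out_w), dtype=np.uint8)
    folded[:, :left.shape[1]] |= left.astype(np.uint8)
    folded[:, :right.shape[1]] |= right.astype(np.uint8)
    return folded


def skeletonize_mask(mask: np.ndarray, frame: FrameSpec | None = None) -> Skeleton:
    """Thin a binary raster to its 1-px-wide medial axis."""
    px = np.asarray(mask)
    vals = np.unique(px)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be binary")
    sk = skeletonize(px.astype(bool))
    return Skeleton(sk, frame if frame is not None else FrameSpec())


def root_length_cm(sk: Skeleton) -> float:
    """Skeleton pixel count x pixel size: 256 px span 10 cm at full scale,
    so one pixel ~ 0.39 mm of root length."""
    return sk.n_pixels * sk.frame.cm_per_px


def cumulative_profile(sk: Skeleton, axis: str) -> CumulativeProfile:
    """Per-bin pixel counts along ``axis``, cumulatively normalized."""
    if axis not in ("depth", "width"):
        raise ValueError("axis must be 'depth' or 'width'")
    total = sk.n_pixels
    if total == 0:
        raise ValueError("no roots detected")
    counts = sk.pixels.sum(axis=1 if axis == "depth" else 0)
    cum = np.cumsum(counts) / total
    return CumulativeProfile(axis, sk.frame.cm_per_px, cum)


def quantile_distance(profile: CumulativeProfile, q: float) -> float:
    """Smallest distance (cm) at which the cumulative fraction reaches
    ``q``, linearly interpolated inside the crossing bin."""
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    cum = profile.cumulative
    i = int(np.searchsorted(cum, q))
    if i >= len(cum):  # numerical guard; last value is 1 by construction
        i = len(cum) - 1
    prev = cum[i - 1] if i > 0 else 0.0
    step = cum[i] - prev
    frac = 1.0 if step <= 0 else (q - prev) / step
    return (i + frac) * profile.bin_cm


def phenotype_image(mask: RootMask | np.ndarray,
                    frame: FrameSpec | None = None,
                    hill_column: int | None = None,
                    skeletonized: bool = False) -> RootDistributionParams:
    """Full phenotyping pipeline: fold -> skeletonize -> quantiles.

    ``skeletonized=True`` skips thinning (input already 1-px centerlines,
    e.g. the synthetic generator's exact centerline raster).
    """
    if isinstance(mask, RootMask):
        frame = mask.frame
    elif frame is None:
        raise ValueError("frame required for bare arrays")
    folded = fold_half(mask, hill_column)
    if not folded.any():
        raise ValueError("no roots detected")
    sk = Skeleton(folded.astype(bool), frame) if skeletonized else skeletonize_mask(folded, frame)
    depth50 = quantile_distance(cumulative_profile(sk, "depth"), 0.5)
    width50 = quantile_distance(cumulative_profile(sk, "width"), 0.5)
    return RootDistributionParams(depth50, width50, root_length_cm(sk))
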