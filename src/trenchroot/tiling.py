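"""Disjoint tiling of normalized trench rasters.

The network consumes fixed-size square tiles; a normalized image is split
into a 6 x 6 grid of 256 x 256 px tiles (10 x 10 cm each) at full scale,
predicted tile by tile, and reassembled in the original row-major order.
Tiles are disjoint and cover the raster exactly — no overlap, padding or
seam blending.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TileGrid", "split_tiles", "assemble_tiles", "TILE_PX_FULL"]

#: Tile edge at the full-scale frame: 10 cm at 25.6 px/cm.
TILE_PX_FULL = 256


@dataclass
class TileGrid:
    """Row-major list of disjoint square tiles covering one raster."""

    tiles: list[np.ndarray]
    tile_px: int
    grid: tuple[int, int]
    provenance: str | None = None

    def __post_init__(self) -> None:
        rows, cols = self.grid
        if len(self.tiles) != rows * cols:
            raise ValueError(
                f"grid {self.grid} needs {rows * cols} tiles, got {len(self.tiles)}"
            )
        for t in self.tiles:
            if t.shape[:2] != (self.tile_px, self.tile_px):
                raise ValueError(
                    f"tile shape {t.shape[:2]} inconsistent with tile_px={self.tile_px}"
                )


def split_tiles(raster: np.ndarray, tile_px: int = TILE_PX_FULL,
                provenance: str | None = None) -> TileGrid:
    """Split a raster (H, W[, C]) into disjoint tiles in row-major order."""
    raster = np.asarray(raster)
    h, w = raster.shape[:2]
    if h % tile_px or w % tile_px:
        raise ValueError(f"dimensions {h}x{w} not divisible by tile size {tile_px}")
    rows, cols = h // tile_px, w // tile_px
    tiles = [
        raster[r * tile_px:(r + 1) * tile_px, c * tile_px:(c + 1) * tile_px]
        for r in range(rows)
        for c in range(cols)
    ]
    return TileGrid(tiles, tile_px, (rows, cols), provenance)


def assemble_tiles(grid: TileGrid) -> np.ndarray:
    """Reassemble tiles into the source raster; exact inverse of
    :func:`split_tiles`."""
    rows, cols = grid.grid
    t = grid.tile_px
    band = [np.concatenate(grid.tiles[r * cols:(r + 1) * cols], axis=1)
            for r in range(rows)]
    return np.concatenate(band, axis=0)
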