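"""Tile-based area-fraction heatmaps.

The field is partitioned into a grid of squares whose edge is
``floor(width_px / n_tiles_per_row)``; the area fraction of each tile is
computed exactly as for the whole field.  Remainder pixels on the right and
bottom edges form partial tiles with their own (smaller) pixel counts
rather than being discarded, so the pixel-count-weighted mean of the tile
values reproduces the global area fraction exactly — a conservation
identity the tests rely on.

Tile size is a display choice and should be adapted to magnification and
sample; rendering normalizes colors to the per-image maximum by default,
with an optional fixed scale for cross-image comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from vasquant.preprocess import BinaryMask


@dataclass(frozen=True)
class HeatmapGrid:
    """Per-tile area fractions plus the tile pixel counts needed to
    reconstruct the exact global area fraction."""

    tile_values: np.ndarray  # fractions in [0, 1]
    tile_pixel_counts: np.ndarray
    tile_edge_px: int
    image_shape: tuple[int, int]
    pixel_size_um: float

    @property
    def n_rows_tiles(self) -> int:
        return self.tile_values.shape[0]

    @property
    def n_cols_tiles(self) -> int:
        return self.tile_values.shape[1]

    @property
    def weighted_mean(self) -> float:
        """Pixel-count-weighted mean tile value == global area fraction."""
        return float(
            (self.tile_values * self.tile_pixel_counts).sum() / self.tile_pixel_counts.sum()
        )

    def tile_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Row and column start offsets of each tile in image pixels."""
        h, w = self.image_shape
        return np.arange(0, h, self.tile_edge_px), np.arange(0, w, self.tile_edge_px)


def compute_heatmap(mask: BinaryMask, n_tiles_per_row: int) -> HeatmapGrid:
    """Partition the mask into square tiles and measure each tile's
    area fraction.

    ``n_tiles_per_row`` sets the nominal number of tiles across the image
    width; it must be at least 1 and no larger than the smaller image edge.
    """
    h, w = mask.shape
    if n_tiles_per_row < 1 or n_tiles_per_row > min(h, w):
        raise ValueError(
            f"n_tiles_per_row must be in [1, {min(h, w)}], got {n_tiles_per_row}"
        )
    edge = w // n_tiles_per_row
    row_starts = np.arange(0, h, edge)
    col_starts = np.arange(0, w, edge)
    fg = mask.pixels.astype(np.int64)
    rows = np.add.reduceat(fg, row_starts, axis=0)
    sums = np.add.reduceat(rows, col_starts, axis=1)
    rh = np.minimum(row_starts + edge, h) - row_starts
    cw = np.minimum(col_starts + edge, w) - col_starts
    counts = np.outer(rh, cw)
    values = sums / counts
    return HeatmapGrid(values, counts, edge, (h, w), mask.pixel_size_um)


def render_heatmap(
    grid: HeatmapGrid,
    output_path: str | Path,
    colormap_name: str = "inferno",
    vmax: float | None = None,
) -> None:
    """Write the heatmap as a PNG (one uniform color per tile) and the
    tile values as a CSV next to it.

    Colors map each tile value over ``[0, vmax]``; ``vmax`` defaults to the
    maximum tile value of this grid.  The CSV (same stem, ``.csv`` suffix)
    has one row per tile: row, col, value, pixel_count — re-reading it
    reproduces ``tile_values`` exactly.
    """
    import imageio.v3 as iio
    import matplotlib
    import pandas as pd

    output_path = Path(output_path)
    cmap = matplotlib.colormaps[colormap_name]
    top = vmax if vmax is not None else float(grid.tile_values.max())
    norm = grid.tile_values / top if top > 0 else np.zeros_like(grid.tile_values)
    rgba = (cmap(np.clip(norm, 0, 1)) * 255).astype(np.uint8)

    h, w = grid.image_shape
    e = grid.tile_edge_px
    out = np.zeros((h, w, 4), dtype=np.uint8)
    row_starts, col_starts = grid.tile_bounds()
    for i, r0 in enumerate(row_starts):
        for j, c0 in enumerate(col_starts):
            out[r0 : min(r0 + e, h), c0 : min(c0 + e, w)] = rgba[i, j]
    iio.imwrite(output_path, out)

    rows = [
        {
            "row": i,
            "col": j,
            "value": grid.tile_values[i, j],
            "pixel_count": int(grid.tile_pixel_counts[i, j]),
        }
        for i in range(grid.n_rows_tiles)
        for j in range(grid.n_cols_tiles)
    ]
    pd.DataFrame(rows).to_csv(output_path.with_suffix(".csv"), index=False)
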