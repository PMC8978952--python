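"""Spatial pixel-grid maps (cluster labels, scores) as PNG."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .demux import PixelMatrix


def _grid_image(matrix: PixelMatrix, values: np.ndarray) -> np.ndarray:
    n_rows = max(p.row for p in matrix.pixel_index)
    n_cols = max(p.col for p in matrix.pixel_index)
    img = np.full((n_rows, n_cols), np.nan)
    for p, v in zip(matrix.pixel_index, values):
        img[p.row - 1, p.col - 1] = v
    return img


def spatial_map(
    matrix: PixelMatrix,
    values: np.ndarray,
    path: str,
    title: str = "",
    categorical: bool = False,
) -> None:
    """Render per-pixel values on the tissue grid and save as PNG."""
    img = _grid_image(matrix, np.asarray(values, dtype=float))
    fig, ax = plt.subplots(figsize=(5, 5))
    cmap = "tab10" if categorical else "viridis"
    im = ax.imshow(img, cmap=cmap, interpolation="nearest", origin="upper")
    ax.set_xlabel("column (barcode B)")
    ax.set_ylabel("row (barcode A)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
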