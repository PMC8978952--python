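"""Per-modality normalization of pixel count matrices.

Protein (ADT) counts are compositional — staining efficiency and pixel
cell content scale all tags together — so they get the centered log
ratio (CLR) transform, computed across features within each pixel. RNA
counts get library-size log-normalization with a documented scale
factor, followed by optional highly-variable-gene selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demux import PixelMatrix


@dataclass
class NormalizedMatrix:
    """Dense normalized pixels x features matrix, co-indexed with its parent."""

    values: np.ndarray
    method: str  # "CLR" | "LOG_NORM"
    parent: PixelMatrix
    zero_pixels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def pixel_index(self):
        return self.parent.pixel_index

    @property
    def feature_index(self):
        return self.parent.feature_index

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def clr_normalize(matrix: PixelMatrix) -> NormalizedMatrix:
    """Centered log ratio across features within each pixel.

    CLR(x_j) = ln(x_j + 1) - mean_f ln(x_f + 1), natural log, pseudocount
    1. Every output row sums to zero, including all-zero pixels (which map
    to all-zero rows).
    """
    x = matrix.dense().astype(float)
    logged = np.log1p(x)
    values = logged - logged.mean(axis=1, keepdims=True)
    zero = np.asarray(matrix.counts.sum(axis=1)).ravel() == 0
    return NormalizedMatrix(values, "CLR", matrix, zero)


def log_normalize(matrix: PixelMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """v_ij = ln(1 + scale * x_ij / total_i); zero-total pixels stay zero
    rows and are flagged in ``zero_pixels``."""
    x = matrix.dense().astype(float)
    totals = x.sum(axis=1, keepdims=True)
    zero = totals.ravel() == 0
    safe = np.where(totals == 0, 1.0, totals)
    values = np.log1p(scale * x / safe)
    values[zero, :] = 0.0
    return NormalizedMatrix(values, "LOG_NORM", matrix, zero)


def select_hvgs(norm: NormalizedMatrix, n_top: int = 2000) -> list[str]:
    """Rank features by variance of standardized counts and keep the top.

    Counts are centered and scaled by the Poisson-expected standard
    deviation sqrt(mean), then clipped at sqrt(n_pixels) to guard single
    outlier pixels; the variance of that standardized value is ~1 for
    features at technical noise and grows with biological overdispersion.
    With fewer features than ``n_top`` all are kept.
    """
    x = norm.parent.dense().astype(float)
    n = x.shape[0]
    mu = x.mean(axis=0)
    sd_expected = np.sqrt(np.where(mu == 0, 1.0, mu))
    z = np.clip((x - mu) / sd_expected, -np.sqrt(n), np.sqrt(n))
    dispersion = z.var(axis=0)
    order = np.argsort(-dispersion, kind="stable")
    keep = sorted(order[:n_top])
    return [norm.feature_index[i] for i in keep]


def subset_features(norm: NormalizedMatrix, features: list[str]) -> np.ndarray:
    idx = {f: i for i, f in enumerate(norm.feature_index)}
    cols = [idx[f] for f in features]
    return norm.values[:, cols]
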