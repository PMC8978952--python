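"""MatrixMarket + TSV serialization of pixel matrices."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .chip import ChipDesign, PixelAddress, pixel_to_micron
from .demux import PixelMatrix


def write_matrix(matrix: PixelMatrix, outdir: str, design: ChipDesign | None = None) -> str:
    """Write matrix.mtx + features.tsv + pixels.tsv under outdir/<modality>/.

    pixels.tsv carries the pixel label, grid indices, and physical
    coordinates in micrometers (when the chip design is available).
    """
    d = os.path.join(outdir, matrix.modality)
    os.makedirs(d, exist_ok=True)
    spio.mmwrite(os.path.join(d, "matrix.mtx"), sparse.coo_matrix(matrix.counts))
    with open(os.path.join(d, "features.tsv"), "w") as fh:
        for f in matrix.feature_index:
            fh.write(f"{f}\n")
    rows = []
    for p in matrix.pixel_index:
        if design is not None:
            x, y = pixel_to_micron(p, design)
        else:
            x = y = float("nan")
        rows.append((p.label, p.row, p.col, x, y))
    pd.DataFrame(rows, columns=["pixel", "row", "col", "x_um", "y_um"]).to_csv(
        os.path.join(d, "pixels.tsv"), sep="\t", index=False
    )
    return d


def read_matrix(outdir: str, modality: str) -> PixelMatrix:
    d = os.path.join(outdir, modality)
    counts = sparse.csr_matrix(spio.mmread(os.path.join(d, "matrix.mtx"))).astype(np.int64)
    with open(os.path.join(d, "features.tsv")) as fh:
        features = [line.strip() for line in fh if line.strip()]
    pix = pd.read_csv(os.path.join(d, "pixels.tsv"), sep="\t")
    pixels = [PixelAddress(int(r), int(c)) for r, c in zip(pix["row"], pix["col"])]
    return PixelMatrix(counts, pixels, features, modality)
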