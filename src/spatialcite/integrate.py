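"""Reference-based pixel annotation and marker signature scoring.

Label transfer assigns each spatial pixel a cell type from a labeled
scRNA-seq reference via nearest type-centroid in a shared PC space, then
applies the cluster-majority rule: every pixel in a spatial cluster
receives that cluster's modal predicted type. Signature scores average
per-feature z-scored normalized expression over a small marker set, e.g.
the peripheral helper T cell (Tph) signature LAG3 / PD-1 / CXCR6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import sparse
from sklearn.decomposition import PCA

from .cluster import ClusterAssignment
from .normalize import NormalizedMatrix

#: protein name -> gene symbol aliases used when resolving signatures
FEATURE_ALIASES = {
    "PD-1": "PDCD1",
    "PD1": "PDCD1",
    "CD223": "LAG3",
    "CD279": "PDCD1",
}

#: Tph (peripheral helper T cell) marker signature
TPH_SIGNATURE = ("Tph", ["LAG3", "PDCD1", "CXCR6"])


@dataclass
class ReferenceAtlas:
    """Labeled cells x genes count matrix serving as annotation reference."""

    expression: sparse.csr_matrix
    gene_index: list[str]
    cell_types: list[str]

    def __post_init__(self) -> None:
        if len(self.cell_types) != self.expression.shape[0]:
            raise ValueError("one label per reference cell required")
        if not self.cell_types:
            raise ValueError("empty reference")


@dataclass
class SignatureDefinition:
    name: str
    features: list[str]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("empty signature")

    @classmethod
    def from_yaml(cls, path: str) -> "SignatureDefinition":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(cfg["name"], list(cfg["features"]))


def _log_norm_dense(x: np.ndarray, scale: float = 1e4) -> np.ndarray:
    totals = x.sum(axis=1, keepdims=True)
    safe = np.where(totals == 0, 1.0, totals)
    return np.log1p(scale * x / safe)


def transfer_labels(
    spatial_rna: NormalizedMatrix,
    ref: ReferenceAtlas,
    n_dims: int = 30,
    clusters: ClusterAssignment | None = None,
    min_shared_genes: int = 50,
) -> pd.DataFrame:
    """Annotate pixels with reference cell types by nearest centroid.

    Procedure: intersect gene spaces; log-normalize both matrices;
    per-dataset center each gene (a light batch correction); fit a joint
    PCA on the stacked matrices; compute one centroid per reference cell
    type in PC space; assign each pixel its nearest centroid by cosine
    similarity, with confidence the softmax over negative cosine
    distances. If spatial ``clusters`` are given, a second column applies
    the cluster-majority rule (all pixels in a cluster get its modal
    type).
    """
    shared = [g for g in spatial_rna.feature_index if g in set(ref.gene_index)]
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} genes shared between spatial data and reference "
            f"(need >= {min_shared_genes})"
        )
    types = sorted(set(ref.cell_types))
    if len(types) == 1:
        import warnings

        warnings.warn("reference contains a single cell type; transfer is degenerate")

    sp_idx = {g: i for i, g in enumerate(spatial_rna.feature_index)}
    rf_idx = {g: i for i, g in enumerate(ref.gene_index)}
    sp_counts = spatial_rna.parent.dense().astype(float)[:, [sp_idx[g] for g in shared]]
    rf_counts = np.asarray(ref.expression.todense()).astype(float)[:, [rf_idx[g] for g in shared]]

    sp = _log_norm_dense(sp_counts)
    rf = _log_norm_dense(rf_counts)
    sp = sp - sp.mean(axis=0, keepdims=True)
    rf = rf - rf.mean(axis=0, keepdims=True)

    stacked = np.vstack([rf, sp])
    n_dims = max(1, min(n_dims, stacked.shape[1] - 1, stacked.shape[0] - 1))
    pca = PCA(n_components=n_dims, svd_solver="full", random_state=0)
    emb = pca.fit_transform(stacked)
    rf_emb, sp_emb = emb[: rf.shape[0]], emb[rf.shape[0] :]

    type_arr = np.asarray(ref.cell_types)
    centroids = np.vstack([rf_emb[type_arr == t].mean(axis=0) for t in types])

    def _unit(m: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(m, axis=1, keepdims=True)
        return m / np.where(norms == 0, 1.0, norms)

    cos = _unit(sp_emb) @ _unit(centroids).T  # pixels x types
    cos_dist = 1.0 - cos
    best = np.argmax(cos, axis=1)
    expd = np.exp(-cos_dist - (-cos_dist).max(axis=1, keepdims=True))
    conf = expd / expd.sum(axis=1, keepdims=True)

    out = pd.DataFrame(
        {
            "pixel": [p.label for p in spatial_rna.pixel_index],
            "predicted_type": [types[b] for b in best],
            "confidence": conf[np.arange(len(best)), best],
        }
    )
    if clusters is not None:
        out["cluster"] = clusters.labels
        out["smoothed_type"] = cluster_majority_smooth(
            out["predicted_type"].to_numpy(), clusters.labels
        )
    return out


def cluster_majority_smooth(predicted: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Every pixel in a spatial cluster receives the cluster's modal type;
    ties break alphabetically for determinism."""
    smoothed = np.asarray(predicted, dtype=object).copy()
    for c in np.unique(labels):
        mask = labels == c
        vals, counts = np.unique(predicted[mask], return_counts=True)
        smoothed[mask] = sorted(vals[counts == counts.max()])[0]
    return smoothed


def signature_score(norm: NormalizedMatrix, sig: SignatureDefinition) -> np.ndarray:
    """Mean over signature features of per-feature z-scored expression.

    The z-score is across pixels; a zero-variance feature contributes 0.
    Feature names resolve through the protein/gene alias table; any
    feature still missing from the matrix raises an error naming it.
    """
    available = set(norm.feature_index)
    resolved, missing = [], []
    for f in sig.features:
        if f in available:
            resolved.append(f)
        elif FEATURE_ALIASES.get(f) in available:
            resolved.append(FEATURE_ALIASES[f])
        else:
            missing.append(f)
    if missing:
        raise KeyError(f"signature {sig.name!r} features not in matrix: {missing}")
    idx = {f: i for i, f in enumerate(norm.feature_index)}
    sub = norm.values[:, [idx[f] for f in resolved]]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    # guard float noise: a feature whose spread is negligible relative to
    # its magnitude is constant and contributes 0, not NaN or +-1
    zero = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    z = np.where(zero, 0.0, (sub - mu) / np.where(zero, 1.0, sd))
    return z.mean(axis=1)


def load_reference(matrix_dir: str) -> ReferenceAtlas:
    """Load a reference from MTX + cells.tsv (cell, type) + genes.tsv."""
    import os

    from scipy import io as spio

    expr = sparse.csr_matrix(spio.mmread(os.path.join(matrix_dir, "matrix.mtx")))
    with open(os.path.join(matrix_dir, "genes.tsv")) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    cells = pd.read_csv(os.path.join(matrix_dir, "cells.tsv"), sep="\t")
    return ReferenceAtlas(expr, genes, list(cells["type"]))


def save_reference(ref: ReferenceAtlas, matrix_dir: str) -> None:
    import os

    from scipy import io as spio

    os.makedirs(matrix_dir, exist_ok=True)
    spio.mmwrite(os.path.join(matrix_dir, "matrix.mtx"), sparse.coo_matrix(ref.expression))
    with open(os.path.join(matrix_dir, "genes.tsv"), "w") as fh:
        for g in ref.gene_index:
            fh.write(g + "\n")
    pd.DataFrame(
        {"cell": [f"cell{i}" for i in range(len(ref.cell_types))], "type": ref.cell_types}
    ).to_csv(os.path.join(matrix_dir, "cells.tsv"), sep="\t", index=False)
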