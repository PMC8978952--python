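"""Unsupervised spatial pixel clustering and differential features.

The pipeline mirrors the standard single-cell graph-clustering recipe:
per-feature z-scaling (clipped), PCA, a k-nearest-neighbor graph in PC
space re-weighted by shared-nearest-neighbor (Jaccard) overlap, and
Leiden modularity optimization at a configurable resolution. Cluster
markers come from a per-feature two-sided Wilcoxon rank-sum test of
in-cluster vs rest, with Benjamini-Hochberg correction within cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .normalize import NormalizedMatrix

#: Jaccard overlap below which SNN edges are pruned (Seurat-style cutoff).
SNN_PRUNE = 1.0 / 15.0


@dataclass
class ClusterAssignment:
    """Per-pixel integer cluster ids, contiguous from 0, largest first."""

    labels: np.ndarray
    params: dict
    modality: str

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def scale_features(values: np.ndarray, clip: float = 10.0) -> np.ndarray:
    """Per-feature z-score with symmetric clipping; constant features -> 0."""
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    return np.clip((values - mu) / sd, -clip, clip)


def pca_embed(scaled: np.ndarray, n_dims: int, seed: int = 0) -> np.ndarray:
    n_dims = min(n_dims, scaled.shape[1] - 1, scaled.shape[0] - 1)
    n_dims = max(n_dims, 1)
    return PCA(n_components=n_dims, svd_solver="full", random_state=seed).fit_transform(scaled)


def snn_graph(embedding: np.ndarray, n_neighbors: int = 20) -> igraph.Graph:
    """kNN graph (Euclidean) re-weighted by shared-neighbor Jaccard overlap.

    Each point's neighborhood includes itself; edges whose neighborhoods
    overlap less than ``SNN_PRUNE`` are dropped.
    """
    n = embedding.shape[0]
    if n <= n_neighbors:
        raise ValueError(f"need more than n_neighbors={n_neighbors} pixels, got {n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neigh = [set(row) | {i} for i, row in enumerate(idx)]
    edges, weights = [], []
    seen = set()
    for i, row in enumerate(idx):
        for j in row:
            j = int(j)
            if i == j or (min(i, j), max(i, j)) in seen:
                continue
            seen.add((min(i, j), max(i, j)))
            shared = len(neigh[i] & neigh[j])
            jac = shared / len(neigh[i] | neigh[j])
            if jac >= SNN_PRUNE:
                edges.append((i, j))
                weights.append(jac)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_pixels(
    norm: NormalizedMatrix,
    n_dims: int = 30,
    resolution: float = 0.5,
    n_neighbors: int = 20,
    seed: int = 0,
) -> ClusterAssignment:
    """Scale -> PCA -> SNN graph -> Leiden; deterministic given seed.

    Cluster ids are relabeled by decreasing size so id 0 is always the
    largest cluster regardless of graph traversal order.
    """
    scaled = scale_features(norm.values)
    if np.allclose(scaled, 0.0):
        labels = np.zeros(scaled.shape[0], dtype=int)
    else:
        emb = pca_embed(scaled, n_dims, seed)
        g = snn_graph(emb, n_neighbors)
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=-1,
        )
        labels = np.asarray(part.membership)
        labels = _relabel_by_size(labels)
    params = {
        "n_dims": n_dims,
        "resolution": resolution,
        "n_neighbors": n_neighbors,
        "seed": seed,
    }
    return ClusterAssignment(labels, params, norm.parent.modality)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    return np.asarray([remap[v] for v in labels], dtype=int)


def differential_features(
    norm: NormalizedMatrix,
    assignment: ClusterAssignment,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """Per-cluster marker table: rank-sum p, BH FDR, and log fold change.

    For every cluster, each feature's normalized values in-cluster are
    compared against all other pixels with a two-sided Wilcoxon rank-sum
    (Mann-Whitney) test; FDR is Benjamini-Hochberg within cluster; the
    fold change is the difference of group means on the normalized
    (log-like) scale.
    """
    labels = assignment.labels
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("differential features need at least 2 clusters")
    rows = []
    for c in clusters:
        mask = labels == c
        if mask.sum() < min_cluster_size:
            warnings.warn(f"cluster {c} has fewer than {min_cluster_size} pixels; skipped")
            continue
        a = norm.values[mask]
        b = norm.values[~mask]
        with np.errstate(all="ignore"):
            res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
        pvals = np.atleast_1d(res.pvalue).astype(float)
        pvals[np.isnan(pvals)] = 1.0  # constant feature in both groups
        fdr = _bh_adjust(pvals)
        lfc = a.mean(axis=0) - b.mean(axis=0)
        for j, feat in enumerate(norm.feature_index):
            rows.append((int(c), feat, float(lfc[j]), float(pvals[j]), float(fdr[j])))
    df = pd.DataFrame(rows, columns=["cluster", "feature", "log_fold_change", "p", "fdr"])
    return df.sort_values(["cluster", "p", "feature"], kind="stable").reset_index(drop=True)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
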