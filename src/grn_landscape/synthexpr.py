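"""Synthetic expression matrices standing in for the bulk RNA-seq
comparison: multi-state mixtures over three gene groups, group-wise PCA
reduction to three coordinates, clustering, and matching of cluster centers
to landscape basin positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

__all__ = [
    "ExpressionMatrix",
    "Embedding",
    "MatchReport",
    "default_gene_groups",
    "generate_expression",
    "groupwise_pca",
    "cluster_embedding",
    "compare_to_landscape",
]

GROUPS = ("cancer", "EMT", "stemness")
# 40 genes total; 18 in the cancer (P53-downstream) group, 11 in each of the
# EMT and stemness groups.
DEFAULT_GROUP_SIZES = {"cancer": 18, "EMT": 11, "stemness": 11}


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame          # samples x genes, non-negative
    gene_groups: pd.Series        # gene -> group name
    state_labels: np.ndarray      # ground-truth latent state per sample

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class Embedding:
    coords: np.ndarray            # samples x 3, one column per group PC1
    group_order: tuple[str, ...] = GROUPS
    explained_variance_ratio: tuple[float, ...] = ()


@dataclass
class MatchReport:
    n_clusters: int
    matched: dict[int, str]       # cluster id -> basin label
    unmatched: list[int]
    cluster_centers: np.ndarray   # standardized, clusters x 3
    cluster_labels: np.ndarray    # per-sample cluster assignment


def default_gene_groups(sizes: dict[str, int] | None = None) -> pd.Series:
    sizes = sizes or DEFAULT_GROUP_SIZES
    names, groups = [], []
    for g in GROUPS:
        for i in range(sizes[g]):
            names.append(f"{g}_g{i:02d}")
            groups.append(g)
    return pd.Series(groups, index=pd.Index(names, name="gene"), name="group")


def generate_expression(
    state_centers: np.ndarray,
    n_per_state: int,
    noise: float = 0.1,
    seed: int = 0,
    gene_groups: pd.Series | None = None,
    loadings: dict[str, np.ndarray] | None = None,
) -> ExpressionMatrix:
    """Draw samples around per-state 3-coordinate centers, mapped into gene
    space through per-group loading vectors plus Gaussian noise.

    state_centers: (n_states, 3) mean coordinate per latent state on the
    (cancer, EMT, stemness) axes.  Noise is relative to the coordinate scale;
    non-negativity is enforced by truncation.
    """
    centers = np.asarray(state_centers, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 3:
        raise ValueError("state_centers must be (n_states, 3)")
    if len(np.unique(centers, axis=0)) != len(centers):
        raise ValueError("state centers must be distinct")
    if n_per_state < 2:
        raise ValueError("need n >= 2 samples per state")
    gene_groups = gene_groups if gene_groups is not None else default_gene_groups()
    rng = np.random.default_rng(seed)
    scale = max(np.abs(centers).max(), 1.0)
    n_states = len(centers)
    rows, labels = [], []
    gene_names = list(gene_groups.index)
    group_of = gene_groups.to_dict()
    if loadings is None:
        loadings = {}
        for g in GROUPS:
            k = sum(1 for v in group_of.values() if v == g)
            loadings[g] = 0.5 + rng.random(k)  # positive loadings
    for s in range(n_states):
        for _ in range(n_per_state):
            coord = centers[s] + rng.normal(0.0, noise * scale, size=3)
            row = np.empty(len(gene_names))
            offset = {g: 0 for g in GROUPS}
            for j, gene in enumerate(gene_names):
                g = group_of[gene]
                gi = offset[g]
                offset[g] += 1
                d = GROUPS.index(g)
                row[j] = coord[d] * loadings[g][gi] + rng.normal(
                    0.0, noise * scale
                )
            rows.append(np.clip(row, 0.0, None))
            labels.append(s)
    values = pd.DataFrame(
        np.array(rows),
        columns=pd.Index(gene_names, name="gene"),
        index=pd.RangeIndex(n_states * n_per_state, name="sample"),
    )
    return ExpressionMatrix(values, gene_groups, np.array(labels))


def groupwise_pca(matrix: ExpressionMatrix) -> Embedding:
    """First principal component of each gene group's submatrix.

    The PC sign is fixed so each score correlates positively with the
    group's mean expression, making the embedding deterministic.
    """
    coords = np.empty((matrix.n_samples, len(GROUPS)))
    evr = []
    for d, g in enumerate(GROUPS):
        genes = matrix.gene_groups.index[matrix.gene_groups == g]
        if len(genes) < 2:
            raise ValueError(f"group {g!r} needs >= 2 genes")
        sub = matrix.values[genes].to_numpy()
        if matrix.n_samples < 3:
            raise ValueError("need >= 3 samples")
        if np.allclose(sub.std(axis=0), 0.0):
            raise ValueError(f"group {g!r} has zero variance")
        pca = PCA(n_components=1)
        scores = pca.fit_transform(sub)[:, 0]
        mean_expr = sub.mean(axis=1)
        if np.corrcoef(scores, mean_expr)[0, 1] < 0:
            scores = -scores
        coords[:, d] = scores
        evr.append(float(pca.explained_variance_ratio_[0]))
    return Embedding(coords, GROUPS, tuple(evr))


def cluster_embedding(
    embedding: Embedding, k_range: range = range(2, 9), seed: int = 0
) -> tuple[np.ndarray, int]:
    """K-means with silhouette-selected cluster count over ``k_range``."""
    X = embedding.coords
    best = None
    for k in k_range:
        if k >= len(X):
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        score = silhouette_score(X, km.labels_)
        if best is None or score > best[0]:
            best = (score, k, km.labels_)
    if best is None:
        raise ValueError("no viable cluster count in range")
    return best[2], best[1]


def compare_to_landscape(
    embedding: Embedding,
    basin_coords: dict[str, np.ndarray],
    seed: int = 0,
    cluster_labels: np.ndarray | None = None,
) -> MatchReport:
    """Match silhouette-selected k-means clusters to basin positions by
    nearest-center assignment after per-axis standardization.

    ``basin_coords`` maps basin label -> 3-coordinate position on axes
    corresponding to the embedding's group order.
    """
    X = embedding.coords
    if cluster_labels is None:
        cluster_labels, _ = cluster_embedding(embedding, seed=seed)
    ids = np.unique(cluster_labels)
    centers = np.array([X[cluster_labels == i].mean(axis=0) for i in ids])

    labels = list(basin_coords)
    B = np.array([np.asarray(basin_coords[l], dtype=float) for l in labels])

    # standardize each set onto its own per-axis z-scale so copy-number and
    # PC units are comparable
    def z(A):
        sd = A.std(axis=0)
        sd[sd == 0] = 1.0
        return (A - A.mean(axis=0)) / sd

    Cz, Bz = z(centers), z(B)
    matched: dict[int, str] = {}
    unmatched: list[int] = []
    taken: set[str] = set()
    # greedy nearest-pair assignment
    d = np.linalg.norm(Cz[:, None, :] - Bz[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for ci, bi in order:
        ci, bi = int(ci), int(bi)
        if int(ids[ci]) in matched or labels[bi] in taken:
            continue
        matched[int(ids[ci])] = labels[bi]
        taken.add(labels[bi])
    for i in ids:
        if int(i) not in matched:
            unmatched.append(int(i))
    return MatchReport(len(ids), matched, unmatched, centers, cluster_labels)
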