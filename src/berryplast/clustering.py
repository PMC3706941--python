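"""Correlation dendrograms and k-means profile clustering.

Sample (or gene) similarity uses Pearson's r converted to the distance
d = 1 - r; agglomeration under complete/average/Ward linkage defines the
dendrogram height scale.  Gene-profile k-means uses correlation distance
via the standard trick of z-scoring each profile, under which squared
Euclidean distance is proportional to 1 - r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .core_data import ExpressionMatrix

__all__ = [
    "pearson_distance_matrix",
    "Dendrogram",
    "hierarchical_dendrogram",
    "ProfileClusters",
    "kmeans_profiles",
]


def pearson_distance_matrix(m: ExpressionMatrix | np.ndarray, axis: str = "samples") -> np.ndarray:
    """All-pairs 1 - Pearson r over samples (columns) or genes (rows).

    Raises on zero-variance vectors (r undefined), naming the offender.
    """
    if isinstance(m, ExpressionMatrix):
        X = m.values
        names = m.sample_names if axis == "samples" else m.gene_ids
    else:
        X = np.asarray(m, dtype=float)
        names = None
    if axis == "samples":
        X = X.T
    elif axis != "genes":
        raise ValueError("axis must be 'samples' or 'genes'")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 vectors")
    sd = X.std(axis=1)
    if (sd == 0).any():
        i = int(np.nonzero(sd == 0)[0][0])
        name = names[i] if names else f"index {i}"
        raise ValueError(f"zero-variance vector: {name}")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


@dataclass
class Dendrogram:
    """Agglomerative merge tree: scipy linkage matrix plus leaf labels."""

    linkage_matrix: np.ndarray          # (n-1) x 4 scipy format
    leaf_labels: list[str]
    linkage: str = "average"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        """(node_a, node_b, height) per merge; nodes >= n are prior merges."""
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix]

    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def cut(self, n_clusters: int) -> np.ndarray:
        """Leaf cluster labels (1..n_clusters) at the highest merges."""
        return hierarchy.fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.leaf_labels[i] for i in range(n)}
        for j, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node[n + j] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + j] = h
        return node[n + len(self.linkage_matrix) - 1] + ";"


def hierarchical_dendrogram(
    d: np.ndarray,
    linkage: str = "average",
    labels: list[str] | None = None,
) -> Dendrogram:
    """Agglomerate a square distance matrix under the chosen linkage."""
    if linkage not in ("complete", "average", "ward"):
        raise ValueError("linkage must be complete, average or ward")
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    n = d.shape[0]
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    if labels is None:
        labels = [f"L{i}" for i in range(n)]
    return Dendrogram(Z, list(labels), linkage)


@dataclass
class ProfileClusters:
    """k-means partition of gene expression profiles."""

    k: int
    assignment: dict[str, int]
    centroids: np.ndarray               # k x n_samples (standardized space)
    metric: str
    monotonicity: list[str]             # per cluster: up | down | other
    inertia: float
    warnings: list[str] = field(default_factory=list)

    def genes_in(self, cluster: int) -> frozenset[str]:
        return frozenset(g for g, c in self.assignment.items() if c == cluster)

    def monotone_clusters(self, direction: str) -> list[int]:
        return [c for c, lab in enumerate(self.monotonicity) if lab == direction]


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, flat


def kmeans_profiles(
    m: ExpressionMatrix,
    k: int,
    metric: str = "pearson",
    seed: int = 0,
    restarts: int = 10,
) -> ProfileClusters:
    """Cluster gene profiles with k-means under correlation distance.

    With ``metric="pearson"`` each profile is z-scored first (1 - r is then
    proportional to squared Euclidean distance), centroids are means of
    member z-profiles.  Constant-profile genes have no defined correlation;
    they fall back to Euclidean treatment (zero vector) and are listed in
    ``warnings``.  Per-cluster monotonicity compares centroid stage means:
    strictly increasing over stages is ``up``, strictly decreasing ``down``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if m.n_genes < k:
        raise ValueError("fewer genes than clusters")
    X = m.values
    warns: list[str] = []
    if metric == "pearson":
        Xs, flat = _standardize_rows(X)
        for g in np.nonzero(flat)[0]:
            warns.append(f"gene {m.gene_ids[g]}: constant profile, Euclidean fallback")
    elif metric == "euclidean":
        Xs = X
    else:
        raise ValueError("metric must be pearson or euclidean")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = km.fit_predict(Xs)
    centroids = np.vstack([
        Xs[labels == c].mean(axis=0) if (labels == c).any() else np.zeros(Xs.shape[1])
        for c in range(k)
    ])
    stages = sorted({s.stage for s in m.samples})
    stage_idx = {t: [i for i, s in enumerate(m.samples) if s.stage == t] for t in stages}
    mono = []
    for c in range(k):
        means = np.array([centroids[c, stage_idx[t]].mean() for t in stages])
        if len(stages) >= 2 and np.all(np.diff(means) > 0):
            mono.append("up")
        elif len(stages) >= 2 and np.all(np.diff(means) < 0):
            mono.append("down")
        else:
            mono.append("other")
    return ProfileClusters(
        k=k,
        assignment=dict(zip(m.gene_ids, labels.tolist())),
        centroids=centroids,
        metric=metric,
        monotonicity=mono,
        inertia=float(km.inertia_),
        warnings=warns,
    )
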