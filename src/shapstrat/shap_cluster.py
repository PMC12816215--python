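"""Patient clustering in SHAP space.

The SHAP attribution matrix is reduced by PCA (components retained up to a
cumulative explained-variance target, floor of 2), a k-nearest-neighbour
graph is built in the embedding with k chosen dynamically from the cohort
size (clamped to [5, 50]), pairwise similarity is the shared-neighbour count
(SNN), and patients are partitioned by normalized spectral clustering of the
SNN graph. Clusters can be refined recursively (the pipeline re-runs on one
cluster's embedding rows), and conventional baselines (Pearson-distance
complete-linkage hierarchical clustering, k-means) are provided for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from sklearn.cluster import KMeans

from .attrib_model import ShapMatrix
from .cohort_io import ExpressionMatrix


@dataclass
class Embedding:
    """Principal-component scores of the SHAP matrix."""

    scores: np.ndarray  # N x m
    explained_var: np.ndarray  # length m, non-increasing
    m: int
    sample_ids: list[str]

    def subset(self, rows: np.ndarray) -> "Embedding":
        ids = [self.sample_ids[i] for i in np.flatnonzero(rows)] if rows.dtype == bool else [
            self.sample_ids[i] for i in rows
        ]
        return Embedding(self.scores[rows], self.explained_var, self.m, ids)


@dataclass
class SNNGraph:
    """Symmetric shared-neighbour-count similarity; diagonal = k by convention."""

    similarity: np.ndarray
    k_used: int

    def __post_init__(self) -> None:
        s = np.asarray(self.similarity)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("similarity must be square")
        if not np.array_equal(s, s.T):
            raise ValueError("similarity must be symmetric")
        if s.min() < 0 or s.max() > self.k_used:
            raise ValueError("similarity entries must lie in [0, k]")
        self.similarity = s


@dataclass
class ClusterAssignment:
    """Per-sample top-level labels (1..k, size-ordered) with sub-cluster paths."""

    sample_ids: list[str]
    labels: np.ndarray
    hierarchy_path: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels must align with sample_ids")
        if not self.hierarchy_path:
            self.hierarchy_path = [[int(l)] for l in self.labels]

    @property
    def k(self) -> int:
        return len(np.unique(self.labels))

    @property
    def path_names(self) -> list[str]:
        return ["-".join(str(p) for p in path) for path in self.hierarchy_path]

    @property
    def flat_labels(self) -> np.ndarray:
        """Distinct integer per hierarchy path (paths ordered lexicographically)."""
        names = self.path_names
        order = {name: i + 1 for i, name in enumerate(sorted(set(names), key=lambda s: [int(x) for x in s.split("-")]))}
        return np.array([order[n] for n in names])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "label": self.labels, "hierarchy_path": self.path_names}
        )

    def subset(self, sample_ids: list[str]) -> "ClusterAssignment":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return ClusterAssignment(
            list(sample_ids), self.labels[rows], [list(self.hierarchy_path[i]) for i in rows]
        )


# ---------------------------------------------------------------------------


def pca_reduce(shap: ShapMatrix | np.ndarray, var_target: float = 0.8, m_min: int = 2,
               sample_ids: list[str] | None = None, scale: bool = False) -> Embedding:
    """Center columns of the SHAP matrix and project onto leading PCs.

    Retains the smallest component count whose cumulative explained variance
    reaches ``var_target`` (never fewer than ``m_min``). With ``scale=True``
    columns are additionally divided by their standard deviation
    (correlation-mode PCA): attribution magnitudes scale with a gene's effect
    on the classifier margin, so without scaling a few strong genes dominate
    the embedding and weak-but-consistent co-varying gene sets become
    invisible.
    """
    if isinstance(shap, ShapMatrix):
        x = shap.phi
        sample_ids = list(shap.sample_ids)
    else:
        x = np.asarray(shap, dtype=float)
        sample_ids = sample_ids or [f"row{i}" for i in range(x.shape[0])]
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for PCA")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features for PCA")
    centered = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = centered.std(axis=0, ddof=0)
        centered = centered / np.where(sd == 0, 1.0, sd)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / (n - 1)
    total = var.sum()
    if total <= 0:
        raise ValueError("SHAP matrix has no variance; cannot embed")
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(vt.shape[0]):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    rank = int((s > s[0] * 1e-12).sum())
    cum = np.cumsum(var) / total
    m = int(np.searchsorted(cum, var_target) + 1)
    m = max(m, m_min)
    m = min(m, max(rank, m_min), len(s))
    scores = u[:, :m] * s[:m]
    return Embedding(scores=scores, explained_var=var[:m], m=m, sample_ids=sample_ids)


def dynamic_k(n: int, fraction: float = 0.05, k_min: int = 5, k_max: int = 50) -> int:
    """Neighbour count: round(fraction * n), clamped to [k_min, min(k_max, n-1)]."""
    if n <= k_min:
        raise ValueError(f"need more than {k_min} samples (got {n})")
    k = int(round(fraction * n))
    return int(np.clip(k, k_min, min(k_max, n - 1)))


def knn_neighbors(emb: Embedding | np.ndarray, k: int) -> np.ndarray:
    """Euclidean k-nearest neighbours (self excluded, ties broken by index)."""
    scores = emb.scores if isinstance(emb, Embedding) else np.asarray(emb, dtype=float)
    n = scores.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the sample count {n}")
    dist = cdist(scores, scores)
    np.fill_diagonal(dist, np.inf)
    idx = np.arange(n)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        order = np.lexsort((idx, dist[i]))  # distance first, index breaks ties
        out[i] = order[:k]
    return out


def snn_similarity(neighbors: np.ndarray, k: int) -> SNNGraph:
    """Shared-neighbour counts |kNN(i) ∩ kNN(j)|; diagonal set to k."""
    neighbors = np.asarray(neighbors)
    if neighbors.ndim != 2 or neighbors.shape[1] != k:
        raise ValueError(f"neighbor lists must be N x {k}")
    n = neighbors.shape[0]
    member = np.zeros((n, n), dtype=np.int64)
    rows = np.repeat(np.arange(n), k)
    member[rows, neighbors.ravel()] = 1
    sim = member @ member.T
    np.fill_diagonal(sim, k)
    return SNNGraph(similarity=sim, k_used=k)


def _laplacian_eigen(similarity: np.ndarray):
    """Symmetric normalized Laplacian eigendecomposition (zero diagonal)."""
    s = np.asarray(similarity, dtype=float).copy()
    np.fill_diagonal(s, 0.0)
    deg = s.sum(axis=1)
    isolated = deg == 0
    with np.errstate(divide="ignore"):
        dinv = np.where(isolated, 0.0, 1.0 / np.sqrt(np.where(isolated, 1.0, deg)))
    lap = np.eye(len(s)) - dinv[:, None] * s * dinv[None, :]
    vals, vecs = np.linalg.eigh((lap + lap.T) / 2.0)
    return vals, vecs, isolated


def spectral_partition(
    graph: SNNGraph, k_clusters: int, seed: int, sample_ids: list[str] | None = None
) -> ClusterAssignment:
    """Normalized spectral clustering of the SNN graph.

    Bottom-k eigenvectors of L_sym = I - D^{-1/2} S D^{-1/2} are
    row-normalized and partitioned by k-means (10 restarts, seeded); labels
    are renumbered 1..k in descending cluster size. Isolated vertices
    (no shared neighbours) become their own singleton clusters with a
    warning.
    """
    s = np.asarray(graph.similarity, dtype=float)
    n = s.shape[0]
    if sample_ids is None:
        sample_ids = [f"row{i}" for i in range(n)]
    if k_clusters < 1:
        raise ValueError("k_clusters must be >= 1")
    if k_clusters > n:
        raise ValueError(f"k_clusters={k_clusters} exceeds sample count {n}")
    vals, vecs, isolated = _laplacian_eigen(s)
    core = ~isolated
    n_core = int(core.sum())
    labels = np.zeros(n, dtype=int)
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated vertices assigned singleton clusters",
            RuntimeWarning,
            stacklevel=2,
        )
    if k_clusters == 1:
        labels[core] = 1
    else:
        sub = s[np.ix_(core, core)]
        vals_c, vecs_c, _ = _laplacian_eigen(sub)
        k_eff = min(k_clusters, n_core)
        emb = vecs_c[:, :k_eff]
        norms = np.linalg.norm(emb, axis=1, keepdims=True)
        emb = emb / np.where(norms == 0, 1.0, norms)
        km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed)
        labels[core] = km.fit_predict(emb) + 1
    # size-ordered relabeling; singletons appended after clustered labels
    order = _size_order(labels[core])
    relabel = {old: new for new, old in enumerate(order, start=1)}
    labels[core] = [relabel[l] for l in labels[core]]
    next_label = len(order) + 1
    for i in np.flatnonzero(isolated):
        labels[i] = next_label
        next_label += 1
    return ClusterAssignment(sample_ids=list(sample_ids), labels=labels)


def _size_order(labels: np.ndarray) -> list[int]:
    uniq, counts = np.unique(labels, return_counts=True)
    return [int(l) for l in uniq[np.lexsort((uniq, -counts))]]


def choose_k_eigengap(graph: SNNGraph, k_range: tuple[int, int] = (2, 10)) -> int:
    """Cluster count at the largest gap in ascending Laplacian eigenvalues.

    A degenerate spectrum (no gap above numerical noise) falls back to the
    range minimum with a warning.
    """
    n = graph.similarity.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to choose k")
    vals, _, _ = _laplacian_eigen(graph.similarity)
    lo, hi = k_range
    hi = min(hi, n - 1)
    gaps = {k: vals[k] - vals[k - 1] for k in range(lo, hi + 1)}
    best_k = max(gaps, key=lambda k: (gaps[k], -k))
    if gaps[best_k] <= 1e-8:
        warnings.warn("weak eigengap: degenerate spectrum, returning k_range minimum",
                      RuntimeWarning, stacklevel=2)
        return lo
    return best_k


def cluster_embedding(
    emb: Embedding,
    k_clusters: int | str = "auto",
    seed: int = 0,
    fraction: float = 0.05,
    k_min: int = 5,
    k_max: int = 50,
    k_range: tuple[int, int] = (2, 10),
):
    """dynamic_k -> kNN -> SNN -> spectral convenience; returns (assignment, graph, k_nn)."""
    k_nn = dynamic_k(len(emb.sample_ids), fraction=fraction, k_min=k_min, k_max=k_max)
    graph = snn_similarity(knn_neighbors(emb, k_nn), k_nn)
    if k_clusters == "auto":
        k_clusters = choose_k_eigengap(graph, k_range=k_range)
    assign = spectral_partition(graph, int(k_clusters), seed=seed, sample_ids=emb.sample_ids)
    return assign, graph, k_nn


def subcluster(
    assign: ClusterAssignment,
    target_label: int,
    emb: Embedding,
    k_sub: int = 2,
    seed: int = 0,
    fraction: float = 0.05,
    k_min: int = 5,
    k_max: int = 50,
) -> ClusterAssignment:
    """Re-run the SNN/spectral pipeline inside one cluster; others unchanged."""
    if emb.sample_ids != assign.sample_ids:
        raise ValueError("embedding and assignment sample ids differ")
    rows = np.flatnonzero(assign.labels == target_label)
    if len(rows) < max(2 * k_sub, k_min + 1):
        raise ValueError(
            f"cluster {target_label} too small to split ({len(rows)} samples)"
        )
    sub_emb = emb.subset(rows)
    sub_assign, _, _ = cluster_embedding(
        sub_emb, k_clusters=k_sub, seed=seed, fraction=fraction, k_min=k_min, k_max=k_max
    )
    out = ClusterAssignment(
        list(assign.sample_ids),
        assign.labels.copy(),
        [list(p) for p in assign.hierarchy_path],
    )
    for local_i, global_i in enumerate(rows):
        out.hierarchy_path[global_i] = [target_label, int(sub_assign.labels[local_i])]
    return out


def hierarchical_baseline(
    expr_subset: ExpressionMatrix, k: int = 2, method: str = "hierarchical", seed: int = 0
) -> ClusterAssignment:
    """Conventional baseline on expression profiles.

    'hierarchical': Pearson distance (1 - r) with complete linkage, cut at k.
    'kmeans': k-means on the sample profiles (seeded).
    """
    profiles = expr_subset.values.T  # samples x genes
    n = profiles.shape[0]
    if k > n:
        raise ValueError("k exceeds sample count")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        raw = km.fit_predict(profiles) + 1
    elif method == "hierarchical":
        sd = profiles.std(axis=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            names = [expr_subset.sample_ids[i] for i in flat[:5]]
            raise ValueError(f"zero-variance sample profiles: {names}")
        corr = np.corrcoef(profiles)
        dist = 1.0 - corr
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="complete")
        raw = fcluster(z, t=k, criterion="maxclust")
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    order = _size_order(np.asarray(raw))
    relabel = {old: new for new, old in enumerate(order, start=1)}
    labels = np.array([relabel[l] for l in raw])
    return ClusterAssignment(sample_ids=list(expr_subset.sample_ids), labels=labels)
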