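"""Cell clustering on the learned embedding.

Rows of the embedding H are compared with either a correlation distance
(1 - Pearson correlation of row-centered embedding rows) or an L1 distance,
then grouped by agglomerative hierarchical clustering (average linkage by
default, which is valid for the non-Euclidean correlation distance). The
cluster number is chosen automatically: mean silhouette width for small
datasets, the variance-ratio (Calinski-Harabasz) criterion for large ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

#: sample-size threshold separating the silhouette regime (n <= threshold)
#: from the variance-ratio regime
SMALL_SAMPLE_THRESHOLD = 500

DEFAULT_CANDIDATES = tuple(range(2, 11))


@dataclass
class ClusteringResult:
    """Labels plus the cluster-number selection trail."""

    labels: np.ndarray
    k: int
    criterion_used: str | None = None
    criterion_scores: dict[int, float] = field(default_factory=dict)


def _as_embedding(H) -> np.ndarray:
    H = np.asarray(getattr(H, "values", H), dtype=float)
    if H.ndim != 2:
        raise ValueError("embedding must be 2-D")
    if not np.all(np.isfinite(H)):
        raise ValueError("embedding contains non-finite entries")
    return H


def correlation_distance(H) -> np.ndarray:
    """Pairwise 1 - Pearson correlation of embedding rows.

    Symmetric with zero diagonal and entries in [0, 2]. A constant row has
    undefined correlation; its distance to every other cell is set to 1
    with a warning.
    """
    H = _as_embedding(H)
    if H.shape[1] < 2:
        raise ValueError("correlation distance needs at least 2 embedding columns")
    constant = H.std(axis=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        D = squareform(pdist(H, metric="correlation"))
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant embedding row(s); correlation "
            "distance to them set to 1",
            stacklevel=2,
        )
        D[constant, :] = 1.0
        D[:, constant] = 1.0
    D = np.nan_to_num(D, nan=1.0)
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, 2.0)


def l1_distance(H) -> np.ndarray:
    """Pairwise L1 (cityblock) distance between embedding rows."""
    H = _as_embedding(H)
    return squareform(pdist(H, metric="cityblock"))


def distance_matrix(H, metric: str = "correlation") -> np.ndarray:
    if metric == "correlation":
        return correlation_distance(H)
    if metric == "l1":
        return l1_distance(H)
    raise ValueError(f"unknown distance {metric!r}")


def hierarchical_cluster(D: np.ndarray, k: int, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of a precomputed distance matrix, cut at k.

    Returns integer labels 0..k-1 (deterministic given D).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    Z = linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return labels.astype(int)


def mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width over all cells on a precomputed distance matrix.

    Cells in singleton clusters contribute 0 (standard convention).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return float(np.mean(silhouette_samples(D, labels, metric="precomputed")))


def variance_ratio(H, labels: np.ndarray) -> float:
    """Variance-ratio (Calinski-Harabasz) criterion on the embedding.

    Between-cluster scatter / (k - 1) over within-cluster scatter / (n - k),
    both as traces of scatter matrices. Perfectly compact clusters (zero
    within-cluster scatter) score +inf.
    """
    H = _as_embedding(H)
    labels = np.asarray(labels)
    n = H.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2 or k >= n:
        raise ValueError("variance ratio needs 2 <= k < n")
    grand = H.mean(axis=0)
    between = 0.0
    within = 0.0
    for q in uniq:
        block = H[labels == q]
        cq = block.mean(axis=0)
        between += len(block) * float(np.sum((cq - grand) ** 2))
        within += float(np.sum((block - cq) ** 2))
    if within == 0.0:
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


def _cluster_all_k(D: np.ndarray, candidates, method: str) -> dict[int, np.ndarray]:
    n = D.shape[0]
    Z = linkage(squareform(np.asarray(D, dtype=float), checks=False), method=method)
    out = {}
    for k in candidates:
        if not 2 <= k <= n - 1:
            raise ValueError(f"candidate k={k} outside [2, n-1] for n={n}")
        out[k] = (fcluster(Z, t=k, criterion="maxclust") - 1).astype(int)
    return out


def select_k_silhouette(
    D: np.ndarray, candidates=DEFAULT_CANDIDATES, method: str = "average"
) -> tuple[int, dict[int, float]]:
    """Pick the candidate k maximizing the mean silhouette width."""
    candidates = sorted(set(int(k) for k in candidates))
    if not candidates:
        raise ValueError("empty candidate set")
    labelings = _cluster_all_k(D, candidates, method)
    scores = {}
    for k, labels in labelings.items():
        if len(np.unique(labels)) < 2:
            scores[k] = -np.inf  # degenerate cut (tie in the dendrogram)
        else:
            scores[k] = mean_silhouette(D, labels)
    best = max(candidates, key=lambda k: (scores[k], -k))
    return best, scores


def select_k_variance_ratio(
    H, candidates=DEFAULT_CANDIDATES, D: np.ndarray | None = None, method: str = "average"
) -> tuple[int, dict[int, float]]:
    """Pick the candidate k maximizing the variance-ratio criterion.

    Clustering runs on the distance matrix D (computed from H with the
    correlation distance when omitted); the criterion is evaluated on H.
    """
    H = _as_embedding(H)
    candidates = sorted(set(int(k) for k in candidates))
    if not candidates:
        raise ValueError("empty candidate set")
    if D is None:
        D = correlation_distance(H)
    labelings = _cluster_all_k(D, candidates, method)
    scores = {}
    for k, labels in labelings.items():
        if len(np.unique(labels)) < 2:
            scores[k] = -np.inf
        else:
            scores[k] = variance_ratio(H, labels)
    best = max(candidates, key=lambda k: (scores[k], -k))
    return best, scores


def cluster(
    H,
    n_clusters: int | None = None,
    candidates=DEFAULT_CANDIDATES,
    distance: str = "correlation",
    method: str = "average",
    criterion: str = "auto",
) -> ClusteringResult:
    """Cluster embedding rows, selecting the cluster number if not given.

    ``criterion="auto"`` uses the silhouette criterion when
    n <= SMALL_SAMPLE_THRESHOLD and the variance ratio otherwise.
    """
    H = _as_embedding(H)
    D = distance_matrix(H, distance)
    if n_clusters is not None:
        labels = hierarchical_cluster(D, int(n_clusters), method)
        return ClusteringResult(labels=labels, k=int(n_clusters))
    n = H.shape[0]
    if criterion == "auto":
        criterion = "silhouette" if n <= SMALL_SAMPLE_THRESHOLD else "variance_ratio"
    if criterion == "silhouette":
        k_star, scores = select_k_silhouette(D, candidates, method)
    elif criterion == "variance_ratio":
        k_star, scores = select_k_variance_ratio(H, candidates, D=D, method=method)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    labels = hierarchical_cluster(D, k_star, method)
    return ClusteringResult(
        labels=labels, k=k_star, criterion_used=criterion, criterion_scores=scores
    )
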