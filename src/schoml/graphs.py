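"""Neighborhood graphs and normalized Laplacians, per modality and order.

For each modality a k-nearest-neighbor Gaussian affinity graph is built
(order 1), and a second-order graph is derived from it: two cells are
similar at order 2 when their order-1 neighborhood profiles (rows of the
adjacency matrix) are close and they share at least one neighbor. Each
adjacency matrix W yields the symmetric normalized Laplacian
L = I - D^{-1/2} W D^{-1/2}, a PSD matrix with spectrum in [0, 2] whose
small eigenvectors embed the graph's cluster structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .io import ModalityMatrix, as_modality


def default_k(n_cells: int) -> int:
    """Neighbor count: 10 for small datasets, 100 for large ones."""
    return 10 if n_cells <= 2000 else 100


@dataclass
class GraphConfig:
    """Graph construction settings.

    k : int or None
        Neighbors per cell; None picks :func:`default_k` at build time.
    sigma_mode : {"sample_std", "fixed"}
        Gaussian kernel width: the standard deviation of all entries of the
        (preprocessed) modality matrix, or a fixed value.
    sigma_value : float
        Kernel width when ``sigma_mode="fixed"``.
    max_order : int
        Number of adjacency orders (the optimizer consumes exactly 2).
    symmetrize : {"union", "mutual"}
        Keep an edge when either (union) or both (mutual) directed KNN
        relations hold.
    """

    k: int | None = None
    sigma_mode: str = "sample_std"
    sigma_value: float | None = None
    max_order: int = 2
    symmetrize: str = "union"

    def __post_init__(self) -> None:
        if self.sigma_mode not in ("sample_std", "fixed"):
            raise ValueError(f"unknown sigma_mode {self.sigma_mode!r}")
        if self.sigma_mode == "fixed":
            if self.sigma_value is None or self.sigma_value <= 0:
                raise ValueError("fixed sigma_mode requires sigma_value > 0")
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        if self.symmetrize not in ("union", "mutual"):
            raise ValueError(f"unknown symmetrize {self.symmetrize!r}")


def resolve_sigma(X: np.ndarray, cfg: GraphConfig) -> float:
    """Kernel width for one modality matrix."""
    if cfg.sigma_mode == "fixed":
        return float(cfg.sigma_value)
    sigma = float(np.std(X))
    if sigma == 0:
        raise ValueError("constant modality matrix: sample-std kernel width is zero")
    return sigma


def build_knn_affinity(
    X: np.ndarray, cfg: GraphConfig | None = None, sigma: float | None = None
) -> np.ndarray:
    """Order-1 KNN Gaussian affinity matrix.

    Entry (j, k) is exp(-||x_j - x_k||^2 / (2 sigma^2)) when the pair is
    connected under the configured symmetrization, else 0; the diagonal is
    zero and the matrix is symmetric.
    """
    cfg = cfg or GraphConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (cells x features)")
    if np.isnan(X).any():
        raise ValueError("X contains NaN entries")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    k = cfg.k if cfg.k is not None else default_k(n)
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n={n}")
    if sigma is None:
        sigma = resolve_sigma(X, cfg)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    directed = np.zeros((n, n), dtype=bool)
    for j in range(n):
        neigh = [t for t in idx[j] if t != j][:k]
        directed[j, neigh] = True
    connected = directed | directed.T if cfg.symmetrize == "union" else directed & directed.T

    d2 = cdist(X, X, metric="sqeuclidean")
    W = np.where(connected, np.exp(-d2 / (2.0 * sigma**2)), 0.0)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def build_high_order_adjacency(
    W_prev: np.ndarray, sigma: float, cfg: GraphConfig | None = None
) -> np.ndarray:
    """Next-order adjacency from the rows of the previous-order adjacency.

    w_jk = exp(-||w_j - w_k||^2 / (2 sigma^2)) when j != k and rows j, k
    share at least one index with positive weight; else 0. The shared-support
    test runs over all indices (including j and k themselves); the diagonal
    is forced to zero afterwards.
    """
    W_prev = np.asarray(W_prev, dtype=float)
    n = W_prev.shape[0]
    if W_prev.shape != (n, n):
        raise ValueError("W_prev must be square")
    if not np.allclose(W_prev, W_prev.T):
        raise ValueError("W_prev must be symmetric")
    support = W_prev > 0
    share = (support.astype(float) @ support.astype(float).T) > 0
    d2 = cdist(W_prev, W_prev, metric="sqeuclidean")
    W = np.where(share, np.exp(-d2 / (2.0 * sigma**2)), 0.0)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def normalized_laplacian(W: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian I - D^{-1/2} W D^{-1/2}.

    Isolated vertices (zero degree) get an identity row/column, the limit of
    the normalized form, so the result stays PSD with spectrum in [0, 2].
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    deg = W.sum(axis=1)
    isolated = deg <= 0
    inv_sqrt = np.where(isolated, 0.0, 1.0 / np.sqrt(np.where(isolated, 1.0, deg)))
    L = -W * np.outer(inv_sqrt, inv_sqrt)
    np.fill_diagonal(L, 1.0)
    return (L + L.T) / 2.0


@dataclass
class LaplacianStack:
    """Per-modality, per-order normalized Laplacians.

    ``laplacians[p][i]`` is the order-(i+1) Laplacian of modality p; all are
    n x n. ``sigmas[p]`` is the kernel width used for modality p.
    """

    laplacians: list[list[np.ndarray]]
    sigmas: list[float]

    def __post_init__(self) -> None:
        if not self.laplacians or not self.laplacians[0]:
            raise ValueError("empty Laplacian stack")
        n = self.laplacians[0][0].shape[0]
        orders = len(self.laplacians[0])
        for mats in self.laplacians:
            if len(mats) != orders:
                raise ValueError("ragged Laplacian stack")
            for L in mats:
                if L.shape != (n, n):
                    raise ValueError("all Laplacians must be n x n")

    @property
    def n_cells(self) -> int:
        return self.laplacians[0][0].shape[0]

    @property
    def n_modalities(self) -> int:
        return len(self.laplacians)

    @property
    def n_orders(self) -> int:
        return len(self.laplacians[0])

    def mixed(self, order: int, mu: np.ndarray) -> np.ndarray:
        """Modality mixture sum_p mu_p * L_p at the given order (1-based)."""
        mats = [self.laplacians[p][order - 1] for p in range(self.n_modalities)]
        return sum(m * L for m, L in zip(mu, mats))


def build_laplacian_stack(
    modalities: list[ModalityMatrix | np.ndarray], cfg: GraphConfig | None = None
) -> LaplacianStack:
    """All U x V normalized Laplacians for V modalities and U orders.

    The kernel width is resolved per modality (order >= 2 graphs reuse the
    modality's order-1 width).
    """
    cfg = cfg or GraphConfig()
    mms = [as_modality(m, name=f"modality_{p + 1}") for p, m in enumerate(modalities)]
    n = mms[0].n_cells
    for mm in mms[1:]:
        if mm.n_cells != n:
            raise ValueError(
                f"modalities disagree on cell count: {n} vs {mm.n_cells}; align cells first"
            )
    laplacians: list[list[np.ndarray]] = []
    sigmas: list[float] = []
    for mm in mms:
        sigma = resolve_sigma(mm.values, cfg)
        sigmas.append(sigma)
        W = build_knn_affinity(mm.values, cfg, sigma=sigma)
        mats = [normalized_laplacian(W)]
        for _ in range(1, cfg.max_order):
            W = build_high_order_adjacency(W, sigma, cfg)
            mats.append(normalized_laplacian(W))
        laplacians.append(mats)
    return LaplacianStack(laplacians=laplacians, sigmas=sigmas)
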