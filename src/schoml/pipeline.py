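"""End-to-end estimator: preprocessing, graphs, fusion, clustering.

:class:`SCHoML` is a scikit-learn-style clusterer whose ``fit`` takes a list
of cell-matched modality matrices (each cells x features). It z-scores and
PCA-reduces each modality, builds order-1 and order-2 KNN Laplacians,
optimizes the fused-Laplacian embedding, and clusters cells hierarchically,
selecting the cluster number automatically unless it is given.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .clustering import DEFAULT_CANDIDATES, cluster
from .fusion import HighOrderLaplacianFusion
from .graphs import GraphConfig, build_laplacian_stack
from .io import ModalityMatrix, align_cells, as_modality
from .preprocess import PreprocessConfig, preprocess_modality


class SCHoML(ClusterMixin, BaseEstimator):
    """Joint clustering of parallel multi-omics single-cell data.

    Parameters
    ----------
    n_clusters : int or None
        Final cluster number. None triggers automatic selection over
        ``k_candidates`` (silhouette for small n, variance ratio for large).
    n_components : int or None
        Embedding dimension c; defaults to ``n_clusters`` when that is set,
        otherwise to the largest candidate cluster number.
    k_neighbors : int or None
        KNN graph size; None uses 10 for n <= 2000 and 100 above.
    sigma_mode : {"sample_std", "fixed"}, sigma_value : float
        Gaussian kernel width per modality.
    symmetrize : {"union", "mutual"}
        KNN edge symmetrization.
    normalize : {"zscore", "none"}, pca_components : int or "auto"
        Per-modality preprocessing.
    distance : {"correlation", "l1"}, linkage : str
        Embedding distance and agglomerative linkage.
    k_candidates : iterable of int
        Candidate cluster numbers for automatic selection.
    criterion : {"auto", "silhouette", "variance_ratio"}
    max_iter, tol : optimizer stopping rule.
    init : {"spectral", "random"}, random_state : int or None
        Optimizer initialization.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
    n_clusters_ : int
    embedding_ : ndarray of shape (n, c)
    mu_ : modality weights; lambda_weight_ : order weight
    objective_trace_ : list of float
    criterion_used_, criterion_scores_ : selection trail (None if k given)
    cell_ids_, sigmas_ : bookkeeping from the fitted data.
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        n_components: int | None = None,
        k_neighbors: int | None = None,
        sigma_mode: str = "sample_std",
        sigma_value: float | None = None,
        symmetrize: str = "union",
        normalize: str = "zscore",
        pca_components: int | str = "auto",
        distance: str = "correlation",
        linkage: str = "average",
        k_candidates=DEFAULT_CANDIDATES,
        criterion: str = "auto",
        max_iter: int = 100,
        tol: float = 1e-6,
        init: str = "spectral",
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.n_components = n_components
        self.k_neighbors = k_neighbors
        self.sigma_mode = sigma_mode
        self.sigma_value = sigma_value
        self.symmetrize = symmetrize
        self.normalize = normalize
        self.pca_components = pca_components
        self.distance = distance
        self.linkage = linkage
        self.k_candidates = k_candidates
        self.criterion = criterion
        self.max_iter = max_iter
        self.tol = tol
        self.init = init
        self.random_state = random_state

    def _resolve_c(self) -> int:
        if self.n_components is not None:
            return int(self.n_components)
        if self.n_clusters is not None:
            return int(self.n_clusters)
        return int(max(self.k_candidates))

    def fit(self, X, y=None) -> "SCHoML":
        """Fit on a list of cell-matched modality matrices.

        X may be a list of arrays (cells x features, rows aligned across
        modalities) or of :class:`~schoml.io.ModalityMatrix` (aligned by
        cell id when ids differ in order).
        """
        if isinstance(X, (np.ndarray, ModalityMatrix)):
            X = [X]
        mms = [as_modality(m, name=f"modality_{p + 1}") for p, m in enumerate(X)]
        if len({mm.n_cells for mm in mms}) > 1 or any(
            not np.array_equal(mm.cell_ids, mms[0].cell_ids) for mm in mms
        ):
            mms = align_cells(mms)
        self.cell_ids_ = mms[0].cell_ids

        pre_cfg = PreprocessConfig(normalize=self.normalize, pca_components=self.pca_components)
        processed = [preprocess_modality(mm, pre_cfg) for mm in mms]

        graph_cfg = GraphConfig(
            k=self.k_neighbors,
            sigma_mode=self.sigma_mode,
            sigma_value=self.sigma_value,
            max_order=2,
            symmetrize=self.symmetrize,
        )
        stack = build_laplacian_stack(processed, graph_cfg)
        self.sigmas_ = list(stack.sigmas)

        fusion = HighOrderLaplacianFusion(
            n_components=self._resolve_c(),
            max_iter=self.max_iter,
            tol=self.tol,
            init=self.init,
            random_state=self.random_state,
        ).fit(stack)
        self.fusion_ = fusion
        self.embedding_ = fusion.embedding_
        self.mu_ = fusion.mu_
        self.lambda_weight_ = fusion.lambda_
        self.objective_trace_ = fusion.objective_trace_

        result = cluster(
            self.embedding_,
            n_clusters=self.n_clusters,
            candidates=self.k_candidates,
            distance=self.distance,
            method=self.linkage,
            criterion=self.criterion,
        )
        self.labels_ = result.labels
        self.n_clusters_ = result.k
        self.criterion_used_ = result.criterion_used
        self.criterion_scores_ = result.criterion_scores
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
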