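"""Per-modality normalization and dimension reduction.

Each modality is z-scored per feature and projected onto its top principal
components before any graph is built. Low-dimensional modalities (fewer
features than the requested number of components) skip PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .io import ModalityMatrix, as_modality


@dataclass
class PreprocessConfig:
    """Normalization/reduction settings.

    normalize : {"zscore", "none"}
    pca_components : int or "auto"
        "auto" keeps min(50, n_cells - 1, n_features) components.
    """

    normalize: str = "zscore"
    pca_components: int | str = "auto"

    def __post_init__(self) -> None:
        if self.normalize not in ("zscore", "none"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")
        if self.pca_components != "auto" and int(self.pca_components) < 1:
            raise ValueError("pca_components must be positive or 'auto'")


def zscore_normalize(mm: ModalityMatrix | np.ndarray) -> ModalityMatrix:
    """Center and scale each feature to mean 0, sd 1.

    Zero-variance features are set to all-zero with a warning rather than
    dividing by zero.
    """
    mm = as_modality(mm)
    X = mm.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    # constant up to floating-point error in the mean
    zero = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} constant feature(s) in '{mm.name}' set to zero",
            stacklevel=2,
        )
    sd_safe = np.where(zero, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, zero] = 0.0
    return ModalityMatrix(Z, mm.cell_ids, mm.feature_ids, mm.name)


def pca_reduce(mm: ModalityMatrix | np.ndarray, n_components: int | str = "auto") -> ModalityMatrix:
    """Project cells onto the top principal components.

    Uses a full deterministic SVD with sklearn's sign convention. When the
    modality has no more features than the requested dimension, the matrix
    is returned unchanged (nothing to reduce).
    """
    mm = as_modality(mm)
    n, d = mm.values.shape
    if n_components == "auto":
        q = min(50, n - 1, d)
    else:
        q = int(n_components)
        if q > n:
            raise ValueError(f"pca_components={q} exceeds the cell count n={n}")
    if d <= q:
        return mm
    pca = PCA(n_components=q, svd_solver="full")
    scores = pca.fit_transform(mm.values)
    feat = np.array([f"PC{j + 1}" for j in range(q)], dtype=object)
    return ModalityMatrix(scores, mm.cell_ids, feat, mm.name)


def preprocess_modality(
    mm: ModalityMatrix | np.ndarray, cfg: PreprocessConfig | None = None
) -> ModalityMatrix:
    """Apply the configured normalization then PCA to one modality."""
    cfg = cfg or PreprocessConfig()
    mm = as_modality(mm)
    if cfg.normalize == "zscore":
        mm = zscore_normalize(mm)
    return pca_reduce(mm, cfg.pca_components)
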