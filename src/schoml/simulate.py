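"""Synthetic paired-modality single-cell datasets with known cell types.

Both generators build each modality as a block factor model X = W H: W maps
features to cell-type signatures (block indicator plus Gaussian factor noise
shared by all cells of a type), H assigns cells to types. The data are then
degraded the way sparse single-cell assays are: per-type Bernoulli zeroing
("dropout") followed by additive Gaussian noise, and — for the chromatin
modality of the second dataset — thresholding to a binary matrix.

Dataset 1: 200 cells, 3 cell types (70/60/70), modalities with 5000 and
2000 features; additive-noise levels are swept over a grid.

Dataset 2: 500 cells, 4 cell types (125 each), 5000/2000 features. The
transcriptome factor has only 3 distinct block signatures while the
epigenome factor has K2, so some epigenome-defined groups are not visible
as distinct transcriptome blocks.

Dropout convention: within cell type i with mean ground-truth signal x_i,
an entry is retained with probability exp(-lambda * x_i^2) and zeroed
otherwise. At the default rates this zeroes roughly 5% (modality 1) and
2.5% (modality 2) of entries on top of the structural zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .io import ModalityMatrix, save_modality

SIM1_N_CELLS = 200
SIM1_SIZES = (70, 60, 70)
SIM1_D1 = 5000
SIM1_D2 = 2000
#: feature blocks (start, stop) per cell type, modality 1 (5000 features)
SIM1_BLOCKS_1 = ((0, 500), (1000, 1500), (3000, 3800))
#: feature blocks per cell type, modality 2 (2000 features)
SIM1_BLOCKS_2 = ((0, 100), (150, 300), (500, 800))

SIM2_N_CELLS = 500
SIM2_N_TYPES = 4
SIM2_D1 = 5000
SIM2_D2 = 2000
SIM2_BLOCK_ROWS_1 = 200  # rows per transcriptome signature block
SIM2_RANK_1 = 3  # distinct transcriptome signatures


@dataclass
class Sim1Config:
    """Settings for simulation dataset 1 (noise-grid benchmark)."""

    rho_factor: float = 0.5
    rho1_grid: tuple = (3.0, 3.5, 4.0, 4.5, 5.0)
    rho2_grid: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    lambda1: float = 0.05
    lambda2: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho_factor < 0 or min(self.rho1_grid) < 0 or min(self.rho2_grid) < 0:
            raise ValueError("noise levels must be nonnegative")


@dataclass
class Sim2Config:
    """Settings for simulation dataset 2 (mixed-resolution modalities)."""

    K2: int = 4
    lambda1: float = 0.05
    lambda2: float = 0.025
    rho1: float = 2.0
    rho2: float = 1.0
    binarize_threshold: float = 0.7
    rho_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 3 <= self.K2 <= 7:
            raise ValueError("K2 must be in 3..7")


@dataclass
class SimulatedDataset:
    """Paired modality matrices with ground-truth cell types."""

    X1: ModalityMatrix
    X2: ModalityMatrix
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X1.n_cells != self.X2.n_cells:
            raise ValueError("modalities disagree on cell count")
        if len(self.labels) != self.X1.n_cells:
            raise ValueError("labels length must equal cell count")

    @property
    def modalities(self) -> list[ModalityMatrix]:
        return [self.X1, self.X2]


def _block_labels(sizes) -> np.ndarray:
    return np.repeat(np.arange(len(sizes)), sizes)


def _indicator_from_blocks(n_rows: int, blocks) -> np.ndarray:
    W = np.zeros((n_rows, len(blocks)))
    for j, (start, stop) in enumerate(blocks):
        W[start:stop, j] = 1.0
    return W


def _apply_dropout(
    X: np.ndarray, truth: np.ndarray, labels: np.ndarray, lam: float, rng
) -> np.ndarray:
    """Zero entries per cell type; retention probability exp(-lam * x^2)
    with x the type's mean ground-truth signal."""
    out = X.copy()
    for t in np.unique(labels):
        cells = labels == t
        x_mean = float(truth[cells].mean())
        p_keep = float(np.exp(-lam * x_mean**2))
        mask = rng.random(out[cells].shape) < p_keep
        out[cells] *= mask
    return out


def _corrupt(
    signal_fc: np.ndarray,
    labels: np.ndarray,
    lam: float,
    rho: float,
    rng,
) -> np.ndarray:
    """Dropout then additive Gaussian noise; input/output cells x features."""
    X = _apply_dropout(signal_fc, signal_fc, labels, lam, rng)
    if rho > 0:
        X = X + rho * rng.standard_normal(X.shape)
    return X


def _as_dataset(X1, X2, labels, provenance) -> SimulatedDataset:
    n = X1.shape[0]
    cells = np.array([f"cell_{i}" for i in range(n)], dtype=object)
    mm1 = ModalityMatrix(
        X1, cells, np.array([f"g{j}" for j in range(X1.shape[1])], dtype=object), "modality_1"
    )
    mm2 = ModalityMatrix(
        X2, cells, np.array([f"r{j}" for j in range(X2.shape[1])], dtype=object), "modality_2"
    )
    return SimulatedDataset(X1=mm1, X2=mm2, labels=np.asarray(labels), provenance=provenance)


def generate_sim1(
    cfg: Sim1Config | None = None,
    rho1: float = 3.0,
    rho2: float = 0.2,
    noise: bool = True,
    dropout: bool = True,
) -> SimulatedDataset:
    """Simulation dataset 1 at one (rho1, rho2) additive-noise grid point.

    ``noise=False`` / ``dropout=False`` expose the clean block construction
    for inspection and testing.
    """
    cfg = cfg or Sim1Config()
    if rho1 < 0 or rho2 < 0:
        raise ValueError("rho1, rho2 must be nonnegative")
    rng = np.random.default_rng(cfg.seed)
    labels = _block_labels(SIM1_SIZES)
    H = np.zeros((3, SIM1_N_CELLS))
    H[labels, np.arange(SIM1_N_CELLS)] = 1.0

    Xs = []
    for d, blocks, lam, rho in (
        (SIM1_D1, SIM1_BLOCKS_1, cfg.lambda1, rho1),
        (SIM1_D2, SIM1_BLOCKS_2, cfg.lambda2, rho2),
    ):
        W = _indicator_from_blocks(d, blocks)
        if noise:
            W = W + cfg.rho_factor * rng.standard_normal(W.shape)
        truth = (W @ H).T  # cells x features
        if dropout:
            X = _apply_dropout(truth, truth, labels, lam, rng)
        else:
            X = truth.copy()
        if noise and rho > 0:
            X = X + rho * rng.standard_normal(X.shape)
        Xs.append(X)

    prov = {"generator": "sim1", "rho1": float(rho1), "rho2": float(rho2), **asdict(cfg)}
    return _as_dataset(Xs[0], Xs[1], labels, prov)


def _sim2_cell_blocks(n: int, K2: int) -> np.ndarray:
    """Generative cell-block index per cell: K2 equal consecutive blocks,
    the last absorbing the remainder."""
    size = n // K2
    blocks = np.minimum(np.arange(n) // size, K2 - 1)
    return blocks


def generate_sim2(
    cfg: Sim2Config | None = None, noise: bool = True, dropout: bool = True
) -> SimulatedDataset:
    """Simulation dataset 2: 500 cells, 4 ground-truth cell types.

    The transcriptome factor W1 has K2 columns over disjoint 200-row blocks
    but only 3 distinct block patterns (column j uses pattern min(j, 3)),
    while the epigenome factor W2 has K2 distinct 500-row blocks; the
    epigenome modality is binarized after corruption.
    """
    cfg = cfg or Sim2Config()
    rng = np.random.default_rng(cfg.seed)
    n, K2 = SIM2_N_CELLS, cfg.K2
    gen_blocks = _sim2_cell_blocks(n, K2)
    H = np.zeros((K2, n))
    H[gen_blocks, np.arange(n)] = 1.0
    # ground-truth cell types: 4 equal groups
    labels = _sim2_cell_blocks(n, SIM2_N_TYPES)

    # transcriptome factor: K2 columns, only SIM2_RANK_1 distinct patterns
    W1 = np.zeros((SIM2_D1, K2))
    for j in range(K2):
        g = min(j, SIM2_RANK_1 - 1)
        W1[g * SIM2_BLOCK_ROWS_1 : (g + 1) * SIM2_BLOCK_ROWS_1, j] = 1.0
    # epigenome factor: K2 disjoint blocks fitted into the feature range
    b2 = min(500, SIM2_D2 // K2)
    W2 = np.zeros((SIM2_D2, K2))
    for j in range(K2):
        W2[j * b2 : (j + 1) * b2, j] = 1.0

    if noise:
        W1 = W1 + cfg.rho_factor * rng.standard_normal(W1.shape)
        W2 = W2 + cfg.rho_factor * rng.standard_normal(W2.shape)

    truth1 = (W1 @ H).T
    truth2 = (W2 @ H).T
    X1 = _apply_dropout(truth1, truth1, gen_blocks, cfg.lambda1, rng) if dropout else truth1.copy()
    X2 = _apply_dropout(truth2, truth2, gen_blocks, cfg.lambda2, rng) if dropout else truth2.copy()
    if noise:
        if cfg.rho1 > 0:
            X1 = X1 + cfg.rho1 * rng.standard_normal(X1.shape)
        if cfg.rho2 > 0:
            X2 = X2 + cfg.rho2 * rng.standard_normal(X2.shape)
    X2 = (X2 > cfg.binarize_threshold).astype(float)

    prov = {"generator": "sim2", **asdict(cfg)}
    return _as_dataset(X1, X2, labels, prov)


def write_dataset(ds: SimulatedDataset, outdir, format: str = "csv") -> dict[str, Path]:
    """Write X1, X2, labels and provenance to a directory.

    Returns the paths written. CSV round-trips bit exactly through
    :func:`schoml.io.load_modality`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"csv": "csv", "tsv": "tsv", "mtx": "mtx"}[format]
    paths = {}
    for key, mm in (("X1", ds.X1), ("X2", ds.X2)):
        path = outdir / f"{key}.{ext}"
        save_modality(mm, path, format=format)
        paths[key] = path
    labels_path = outdir / "labels.csv"
    with open(labels_path, "w") as fh:
        fh.write("cell_id,label\n")
        for cid, lab in zip(ds.X1.cell_ids, ds.labels):
            fh.write(f"{cid},{lab}\n")
    paths["labels"] = labels_path
    prov_path = outdir / "provenance.yaml"
    prov_path.write_text(yaml.safe_dump(ds.provenance, sort_keys=True))
    paths["provenance"] = prov_path
    return paths
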