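"""File input/output for modality matrices.

Two on-disk formats are supported:

* dense CSV/TSV — cells in rows, header row of feature names, first column
  of cell identifiers;
* MatrixMarket ``.mtx`` with plain-text sidecar files ``<stem>_rows.txt``
  and ``<stem>_cols.txt`` carrying row and column names, one per line.

Matrices are always oriented cells x features in memory; a ``transpose``
flag handles files stored the other way around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


@dataclass
class ModalityMatrix:
    """One modality's cells x features expression matrix with identifiers."""

    values: np.ndarray
    cell_ids: np.ndarray
    feature_ids: np.ndarray
    name: str = "modality"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("modality values must be a 2-D matrix")
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        n, d = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.feature_ids) != d:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {d} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"modality '{self.name}' contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(cls, values, name: str = "modality") -> "ModalityMatrix":
        values = np.asarray(values, dtype=float)
        n, d = values.shape
        return cls(
            values=values,
            cell_ids=np.array([f"cell_{i}" for i in range(n)], dtype=object),
            feature_ids=np.array([f"feat_{j}" for j in range(d)], dtype=object),
            name=name,
        )


def as_modality(obj, name: str = "modality") -> ModalityMatrix:
    """Coerce an array or ModalityMatrix into a ModalityMatrix."""
    if isinstance(obj, ModalityMatrix):
        return obj
    return ModalityMatrix.from_array(np.asarray(obj, dtype=float), name=name)


def _read_sidecar(path: Path) -> np.ndarray | None:
    if path.exists():
        names = [line.strip() for line in path.read_text().splitlines() if line.strip()]
        return np.asarray(names, dtype=object)
    return None


def load_modality(
    path,
    format: str | None = None,
    transpose: bool = False,
    name: str | None = None,
) -> ModalityMatrix:
    """Load a modality matrix from CSV/TSV or MatrixMarket.

    Parameters
    ----------
    path : str or Path
        File to read. Format is inferred from the suffix unless given.
    format : {"csv", "tsv", "mtx"}, optional
    transpose : bool
        Set when the file stores features in rows.
    name : str, optional
        Modality name; defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"csv": "csv", "tsv": "tsv", "txt": "tsv", "mtx": "mtx"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path}")
    name = name or path.stem

    if format in ("csv", "tsv"):
        df = pd.read_csv(
            path,
            sep="," if format == "csv" else "\t",
            index_col=0,
            float_precision="round_trip",
        )
        values = df.to_numpy(dtype=float)
        row_ids = df.index.to_numpy(dtype=object)
        col_ids = df.columns.to_numpy(dtype=object)
    elif format == "mtx":
        mat = spio.mmread(path)
        values = mat.toarray() if sparse.issparse(mat) else np.asarray(mat, dtype=float)
        stem = path.with_suffix("")
        row_ids = _read_sidecar(Path(f"{stem}_rows.txt"))
        col_ids = _read_sidecar(Path(f"{stem}_cols.txt"))
        if row_ids is None:
            row_ids = np.array([f"row_{i}" for i in range(values.shape[0])], dtype=object)
        if col_ids is None:
            col_ids = np.array([f"col_{j}" for j in range(values.shape[1])], dtype=object)
        if len(row_ids) != values.shape[0] or len(col_ids) != values.shape[1]:
            raise ValueError("sidecar name files do not match matrix shape")
    else:
        raise ValueError(f"unknown format {format!r}")

    if transpose:
        values = values.T
        row_ids, col_ids = col_ids, row_ids

    if np.isnan(values).any():
        raise ValueError(f"{path} contains NaN entries")
    return ModalityMatrix(values=values, cell_ids=row_ids, feature_ids=col_ids, name=name)


def save_modality(mm: ModalityMatrix, path, format: str = "csv") -> None:
    """Write a modality matrix to CSV/TSV or MatrixMarket plus sidecars."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format in ("csv", "tsv"):
        df = pd.DataFrame(mm.values, index=mm.cell_ids, columns=mm.feature_ids)
        # repr-precision floats so a round trip is bit exact
        df.to_csv(path, sep="," if format == "csv" else "\t", float_format="%.17g")
    elif format == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(mm.values))
        stem = path.with_suffix("")
        Path(f"{stem}_rows.txt").write_text("\n".join(map(str, mm.cell_ids)) + "\n")
        Path(f"{stem}_cols.txt").write_text("\n".join(map(str, mm.feature_ids)) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def align_cells(modalities: list[ModalityMatrix]) -> list[ModalityMatrix]:
    """Reorder all modalities to their common cells, in a shared order.

    The order follows the first modality's cell ids. An error is raised if
    fewer than two cells are shared.
    """
    if not modalities:
        raise ValueError("no modalities given")
    common = set(modalities[0].cell_ids)
    for mm in modalities[1:]:
        common &= set(mm.cell_ids)
    if len(common) < 2:
        raise ValueError("fewer than 2 cells shared across modalities")
    order = [cid for cid in modalities[0].cell_ids if cid in common]
    if any(len(order) < mm.n_cells for mm in modalities):
        warnings.warn(
            f"cells reduced to the {len(order)}-cell intersection across modalities",
            stacklevel=2,
        )
    aligned = []
    for mm in modalities:
        pos = {cid: i for i, cid in enumerate(mm.cell_ids)}
        idx = np.array([pos[cid] for cid in order])
        aligned.append(
            ModalityMatrix(
                values=mm.values[idx],
                cell_ids=np.asarray(order, dtype=object),
                feature_ids=mm.feature_ids,
                name=mm.name,
            )
        )
    return aligned
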