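"""Core containers: expression matrices, gene signatures, spatial samples.

An :class:`ExpressionMatrix` is a gene x entity matrix (entities are cells
or spatial bins) carrying ordered gene and entity identifiers and a layer
tag distinguishing raw counts from log-normalized values.  Matrices are
stored dense or sparse (CSR); all operations accept either.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "SpatialSample",
    "read_expression",
    "write_expression",
    "read_signatures",
    "write_signatures",
]


def _check_unique(ids: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if len(set(arr)) != len(arr):
        dup = pd.Series(arr).value_counts()
        dup = dup[dup > 1].index.tolist()[:5]
        raise FormatError(f"duplicate {what} identifiers: {dup}")
    return arr


@dataclass
class ExpressionMatrix:
    """Gene x entity expression values with identifiers attached.

    Parameters
    ----------
    values
        ``(n_genes, n_entities)`` array or sparse matrix.  Raw counts must
        be non-negative.
    gene_ids, entity_ids
        Ordered, unique identifiers matching the matrix dimensions.
    layer_tag
        ``"counts"`` for raw UMI counts, ``"lognorm"`` for log-normalized
        values.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: np.ndarray
    entity_ids: np.ndarray
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.entity_ids = _check_unique(self.entity_ids, "entity")
        n_g, n_e = self.values.shape
        if n_g != len(self.gene_ids) or n_e != len(self.entity_ids):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.entity_ids)} entities"
            )
        if self.layer_tag not in ("counts", "lognorm"):
            raise FormatError(f"unknown layer_tag {self.layer_tag!r}")
        if self.layer_tag == "counts" and self.min() < 0:
            raise FormatError("counts layer contains negative values")

    # -- basic properties ------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_entities(self) -> int:
        return self.values.shape[1]

    def min(self) -> float:
        v = self.values
        if v.shape[0] == 0 or v.shape[1] == 0:
            return 0.0
        return float(v.min())

    def dense(self) -> np.ndarray:
        """Return values as a dense float array (copy if sparse)."""
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v, dtype=float)

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index().get_indexer(list(genes))
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise FormatError(f"genes not in matrix: {missing[:5]}")
        vals = self.values[idx, :]
        return replace(self, values=vals, gene_ids=self.gene_ids[idx])

    def subset_entities(self, entities: Sequence[str]) -> "ExpressionMatrix":
        pos = pd.Index(self.entity_ids).get_indexer(list(entities))
        if (pos < 0).any():
            missing = [e for e, i in zip(entities, pos) if i < 0]
            raise FormatError(f"entities not in matrix: {missing[:5]}")
        vals = self.values[:, pos]
        return replace(self, values=vals, entity_ids=self.entity_ids[pos])

    def row(self, gene: str) -> np.ndarray:
        i = int(np.flatnonzero(self.gene_ids == gene)[0])
        v = self.values[i, :]
        return v.toarray().ravel() if sp.issparse(v) else np.asarray(v, dtype=float).ravel()


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene list with a provenance tag."""

    name: str
    genes: tuple[str, ...]
    source_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) == 0:
            raise FormatError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, gene_ids: Sequence[str]) -> tuple[str, ...]:
        present = set(gene_ids)
        return tuple(g for g in self.genes if g in present)


@dataclass
class SpatialSample:
    """A binned spatial transcriptomics sample.

    ``matrix`` holds expression over bins; ``coords`` maps every bin to
    integer grid coordinates ``(x, y)``; ``sample_label`` identifies the
    tissue section (e.g. ``"CR"`` / ``"NR"``).
    """

    matrix: ExpressionMatrix
    coords: pd.DataFrame  # index bin_id, columns x, y
    sample_label: str = ""

    def __post_init__(self) -> None:
        if not {"x", "y"}.issubset(self.coords.columns):
            raise FormatError("coords must have columns x, y")
        missing = set(self.matrix.entity_ids) - set(self.coords.index)
        if missing:
            raise FormatError(f"bins without coordinates: {sorted(missing)[:5]}")
        xy = list(zip(self.coords["x"], self.coords["y"]))
        if len(set(xy)) != len(xy):
            raise FormatError("duplicate bin coordinates")
        # align coordinate order to matrix entity order
        self.coords = self.coords.loc[list(self.matrix.entity_ids)]


# ---------------------------------------------------------------------------
# I/O


def _read_id_column(path: Path, what: str) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return _check_unique(df.iloc[:, 0].to_numpy(), what)


def read_expression(path: str | os.PathLike, format: str = "auto",
                    layer_tag: str = "counts") -> ExpressionMatrix:
    """Read an expression matrix from MTX triplet or dense CSV.

    ``mtx``: *path* is a directory containing ``matrix.mtx`` (MatrixMarket
    coordinate, genes x entities), ``genes.tsv`` and ``barcodes.tsv``.
    ``csv``: a dense table whose header row holds entity ids and whose
    first column holds gene ids.
    """
    path = Path(path)
    if format == "auto":
        format = "mtx" if path.is_dir() else "csv"
    if format == "mtx":
        mtx_path = path / "matrix.mtx"
        for p in (mtx_path, path / "genes.tsv", path / "barcodes.tsv"):
            if not p.exists():
                raise FormatError(f"missing file: {p}")
        values = sp.csr_matrix(scipy.io.mmread(mtx_path))
        genes = _read_id_column(path / "genes.tsv", "gene")
        barcodes = _read_id_column(path / "barcodes.tsv", "entity")
        if values.shape != (len(genes), len(barcodes)):
            raise FormatError(
                f"matrix.mtx shape {values.shape} does not match "
                f"{len(genes)} genes / {len(barcodes)} barcodes"
            )
        return ExpressionMatrix(values, genes, barcodes, layer_tag)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            df.index.astype(str).to_numpy(),
            df.columns.astype(str).to_numpy(),
            layer_tag,
        )
    raise FormatError(f"unknown format {format!r}")


def write_expression(matrix: ExpressionMatrix, path: str | os.PathLike,
                     format: str = "mtx") -> None:
    """Write a matrix as MTX triplet (to a directory) or dense CSV."""
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(matrix.values))
        pd.Series(matrix.gene_ids).to_csv(path / "genes.tsv", sep="\t",
                                          index=False, header=False)
        pd.Series(matrix.entity_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                            index=False, header=False)
    elif format == "csv":
        pd.DataFrame(matrix.dense(), index=matrix.gene_ids,
                     columns=matrix.entity_ids).to_csv(path)
    else:
        raise FormatError(f"unknown format {format!r}")


def read_signatures(path: str | os.PathLike,
                    source_tag: str = "") -> dict[str, GeneSignature]:
    """Read signatures from a two-column TSV (set_name, gene)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set_name", "gene"],
                     dtype=str, comment="#")
    out = {}
    for name, grp in df.groupby("set_name", sort=False):
        out[name] = GeneSignature(name, tuple(grp["gene"]), source_tag)
    return out


def write_signatures(signatures: Sequence[GeneSignature],
                     path: str | os.PathLike) -> None:
    rows = [(s.name, g) for s in signatures for g in s.genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
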