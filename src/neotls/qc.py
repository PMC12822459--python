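"""Cell quality control and normalization.

Cells are removed on three median-absolute-deviation (MAD) criteria
computed on raw counts:

1. mitochondrial fraction exceeding ``median + 5 * MAD`` (one-sided),
2. total UMI count deviating from the median by more than ``3 * MAD``
   (two-sided),
3. detected-gene count deviating from the median by more than ``3 * MAD``
   (two-sided).

MAD here is the raw median of absolute deviations from the median, with
no consistency constant.  When every cell has the same metric value the
MAD is zero and no cell deviates, so none is removed on that metric.
Thresholds are computed per sample when a sample assignment is supplied,
otherwise globally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import FormatError
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["QCConfig", "mad", "mad_filter", "lognormalize"]


@dataclass(frozen=True)
class QCConfig:
    """MAD multipliers and the mitochondrial gene prefix."""

    mito_mad_mult: float = 5.0
    umi_mad_mult: float = 3.0
    gene_mad_mult: float = 3.0
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        for f in ("mito_mad_mult", "umi_mad_mult", "gene_mad_mult"):
            if getattr(self, f) <= 0:
                raise FormatError(f"{f} must be positive")


def mad(x: np.ndarray) -> float:
    """Median absolute deviation from the median, no consistency constant."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def _cell_metrics(matrix: ExpressionMatrix, mito_prefix: str) -> pd.DataFrame:
    v = matrix.values
    if sp.issparse(v):
        v = sp.csc_matrix(v)
        umi = np.asarray(v.sum(axis=0)).ravel()
        n_genes = np.asarray((v > 0).sum(axis=0)).ravel()
        mito_rows = np.array([g.startswith(mito_prefix) for g in matrix.gene_ids])
        mito = np.asarray(v[mito_rows, :].sum(axis=0)).ravel() if mito_rows.any() else np.zeros_like(umi)
    else:
        v = np.asarray(v, dtype=float)
        umi = v.sum(axis=0)
        n_genes = (v > 0).sum(axis=0)
        mito_rows = np.array([g.startswith(mito_prefix) for g in matrix.gene_ids])
        mito = v[mito_rows, :].sum(axis=0) if mito_rows.any() else np.zeros_like(umi)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(umi > 0, 100.0 * mito / umi, 0.0)
    return pd.DataFrame(
        {"umi": umi, "n_genes": n_genes.astype(float), "mito_pct": mito_pct},
        index=pd.Index(matrix.entity_ids, name="cell_id"),
    )


def mad_filter(
    matrix: ExpressionMatrix,
    qc: QCConfig | None = None,
    samples: pd.Series | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the three MAD criteria to a counts matrix.

    Parameters
    ----------
    matrix
        Raw counts, genes x cells.
    qc
        Threshold multipliers; defaults to (5, 3, 3).
    samples
        Optional cell -> sample assignment; when given, medians and MADs
        are computed within each sample.

    Returns
    -------
    kept : ndarray of kept cell ids (matrix order preserved)
    table : per-cell QC table with the three metrics, the per-metric
        removal flags, and the final decision (``keep``).
    """
    if qc is None:
        qc = QCConfig()
    if matrix.layer_tag != "counts":
        raise FormatError("mad_filter requires the counts layer")
    if matrix.n_entities == 0:
        raise FormatError("empty matrix")

    table = _cell_metrics(matrix, qc.mito_gene_prefix)
    if samples is None:
        groups = [(None, table.index)]
    else:
        samples = samples.reindex(table.index)
        if samples.isna().any():
            raise FormatError("samples missing for some cells")
        groups = [(s, idx) for s, idx in table.groupby(samples, sort=False).groups.items()]

    for col in ("fail_mito", "fail_umi", "fail_genes"):
        table[col] = False
    for _, idx in groups:
        sub = table.loc[idx]
        m_mito, d_mito = np.median(sub["mito_pct"]), mad(sub["mito_pct"])
        m_umi, d_umi = np.median(sub["umi"]), mad(sub["umi"])
        m_g, d_g = np.median(sub["n_genes"]), mad(sub["n_genes"])
        table.loc[idx, "fail_mito"] = sub["mito_pct"] > m_mito + qc.mito_mad_mult * d_mito
        table.loc[idx, "fail_umi"] = np.abs(sub["umi"] - m_umi) > qc.umi_mad_mult * d_umi
        table.loc[idx, "fail_genes"] = np.abs(sub["n_genes"] - m_g) > qc.gene_mad_mult * d_g
    table["keep"] = ~(table["fail_mito"] | table["fail_umi"] | table["fail_genes"])
    kept = table.index[table["keep"]].to_numpy()
    return kept, table


def lognormalize(matrix: ExpressionMatrix, scale: float = 10_000.0) -> ExpressionMatrix:
    """Depth-normalize and log-transform counts.

    Each value becomes ``ln(1 + count / cell_total * scale)``; cells with
    zero total counts are left all-zero with a warning.  For every
    non-empty cell, ``sum(exp(value) - 1)`` over genes equals ``scale``.
    """
    if matrix.layer_tag != "counts":
        raise FormatError("lognormalize requires the counts layer")
    v = matrix.dense()
    totals = v.sum(axis=0)
    empty = totals == 0
    if empty.any():
        logger.warning("%d cell(s) have zero total counts; left as zeros", int(empty.sum()))
    safe = np.where(empty, 1.0, totals)
    out = np.log1p(v / safe * scale)
    out[:, empty] = 0.0
    return ExpressionMatrix(out, matrix.gene_ids.copy(), matrix.entity_ids.copy(), "lognorm")
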