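"""Gene-signature scoring, differential expression and derived signatures.

Two scoring schemes are provided:

* **module score** — mean log-normalized expression of the signature genes
  minus the mean over a pool of expression-matched control genes.  Genes
  are ranked by average expression across entities and cut into equal-size
  abundance bins; each signature gene contributes control genes drawn from
  its own bin, so the background matches the signature's abundance
  profile.  Scores are centred near zero for a random signature.
* **summed score** — the plain sum of the signature genes' values per
  entity, used for spatial TLS bin scoring where an absolute, monotone
  quantity is thresholded.

Differential expression uses the two-sided Wilcoxon rank-sum test with
Benjamini-Hochberg adjustment; a gene is significant when
``log2FC > 0.5`` and ``padj < 0.05`` (defaults).  Fold changes are
computed on depth-normalized scale via ``expm1`` of the log values with a
small pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, NeotlsError
from .matrix import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreTable",
    "DEResult",
    "module_score",
    "summed_score",
    "wilcoxon_de",
    "derive_treatment_signature",
    "top_ratio_markers",
    "score_ratio",
    "classify_msi",
]

EPS = 1e-9  # pseudocount inside fold-change logs


@dataclass
class ScoreTable:
    """Per-entity signature scores."""

    scores: pd.Series  # index entity_id
    method_tag: str  # "module" | "summed"
    signature_name: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise FormatError("scores contain non-finite values")
        if self.scores.index.has_duplicates:
            raise FormatError("duplicate entity ids in score table")

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.scores.rename("score").rename_axis("entity_id").to_csv(path, sep="\t")


@dataclass(frozen=True)
class DEResult:
    gene: str
    log2fc: float
    p: float
    padj: float
    significant: bool


def _present_genes(matrix: ExpressionMatrix, sig: GeneSignature) -> tuple[str, ...]:
    present = sig.intersect(matrix.gene_ids)
    if not present:
        raise NeotlsError(f"no gene of signature {sig.name!r} present in matrix")
    if len(present) < len(sig):
        logger.warning(
            "signature %s: %d of %d genes missing from matrix",
            sig.name, len(sig) - len(present), len(sig),
        )
    return present


def module_score(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int | np.random.Generator = 0,
) -> ScoreTable:
    """Control-matched module score per entity.

    All genes are ranked by mean expression and cut into ``n_bins``
    equal-size bins.  For every signature gene, ``n_ctrl`` control genes
    are drawn from its bin: the whole bin, deterministically, when the bin
    has at most ``n_ctrl`` members, otherwise a without-replacement sample
    of size ``n_ctrl``.  The score is the mean over signature genes minus
    the mean over the pooled control pool.  Deterministic under ``seed``.
    """
    if matrix.layer_tag != "lognorm":
        raise FormatError("module_score requires log-normalized values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    present = _present_genes(matrix, sig)

    dense = matrix.dense()
    gene_means = dense.mean(axis=1)
    # stable rank -> equal-size abundance bins
    order = np.argsort(gene_means, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    n_genes = len(gene_means)
    bins = np.minimum((ranks * n_bins) // n_genes, n_bins - 1)

    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    sig_idx = np.array([gene_pos[g] for g in present])
    bin_members: dict[int, np.ndarray] = {
        b: np.flatnonzero(bins == b) for b in np.unique(bins[sig_idx])
    }

    ctrl_idx_parts = []
    for gi in sig_idx:
        members = bin_members[int(bins[gi])]
        if len(members) <= n_ctrl:
            take = members  # exhaustive: the whole abundance bin
        else:
            take = rng.choice(members, size=n_ctrl, replace=False)
        ctrl_idx_parts.append(take)
    ctrl_idx = np.concatenate(ctrl_idx_parts)

    score = dense[sig_idx, :].mean(axis=0) - dense[ctrl_idx, :].mean(axis=0)
    return ScoreTable(pd.Series(score, index=pd.Index(matrix.entity_ids, name="entity_id")),
                      "module", sig.name)


def summed_score(matrix: ExpressionMatrix, sig: GeneSignature) -> ScoreTable:
    """Sum of the signature genes' values per entity; missing genes add 0."""
    present = _present_genes(matrix, sig)
    sub = matrix.subset_genes(present)
    v = sub.values
    total = np.asarray(v.sum(axis=0)).ravel() if sp.issparse(v) else np.asarray(v, float).sum(axis=0)
    return ScoreTable(pd.Series(total, index=pd.Index(matrix.entity_ids, name="entity_id")),
                      "summed", sig.name)


def _log2_mean_expm1(values: np.ndarray) -> np.ndarray:
    """log2 of depth-normalized group mean, recovered from log values."""
    return np.log2(np.expm1(values).mean(axis=1) + EPS)


def wilcoxon_de(
    matrix: ExpressionMatrix,
    group_a: list[str] | np.ndarray,
    group_b: list[str] | np.ndarray,
    log2fc_min: float = 0.5,
    alpha: float = 0.05,
) -> list[DEResult]:
    """Per-gene two-sided Wilcoxon rank-sum test of group A vs group B.

    p-values are BH-adjusted across the tested genes; ``log2fc`` is
    ``log2(mean expm1 A + eps) - log2(mean expm1 B + eps)``.  A constant
    gene gets ``p = 1`` by convention.
    """
    if matrix.layer_tag != "lognorm":
        raise FormatError("wilcoxon_de requires log-normalized values")
    if len(group_a) < 2 or len(group_b) < 2:
        raise FormatError("both groups need >= 2 entities")
    a = matrix.subset_entities(list(group_a)).dense()
    b = matrix.subset_entities(list(group_b)).dense()

    log2fc = _log2_mean_expm1(a) - _log2_mean_expm1(b)
    constant = (a.min(axis=1) == a.max(axis=1)) & (b.min(axis=1) == b.max(axis=1)) \
        & (a[:, 0] == b[:, 0])
    pvals = np.ones(matrix.n_genes)
    var_rows = np.flatnonzero(~constant)
    if len(var_rows):
        res = scipy.stats.mannwhitneyu(
            a[var_rows, :], b[var_rows, :], axis=1,
            alternative="two-sided", method="asymptotic",
        )
        pvals[var_rows] = np.minimum(res.pvalue, 1.0)
    padj = multipletests(pvals, method="fdr_bh")[1]
    sig = (log2fc > log2fc_min) & (padj < alpha)
    return [
        DEResult(g, float(fc), float(p), float(q), bool(s))
        for g, fc, p, q, s in zip(matrix.gene_ids, log2fc, pvals, padj, sig)
    ]


def derive_treatment_signature(
    published: GeneSignature,
    de_pre_post: list[DEResult],
    alpha: float = 0.05,
    require_direction: bool = False,
) -> GeneSignature | None:
    """Restrict a published TLS signature to treatment-responsive genes.

    Keeps the published genes whose pre-vs-post adjusted p-value is below
    ``alpha`` (direction is not filtered unless ``require_direction``).
    Order follows the published list.  Returns ``None`` with a warning if
    the intersection is empty.
    """
    keep = {r.gene for r in de_pre_post
            if r.padj < alpha and (not require_direction or r.log2fc > 0)}
    genes = tuple(g for g in published.genes if g in keep)
    if not genes:
        logger.warning("no published TLS gene is treatment-responsive; empty signature")
        return None
    return GeneSignature("neoCRT-TLS", genes, source_tag="neoCRT-TLS")


def top_ratio_markers(
    matrix: ExpressionMatrix,
    target: list[str] | np.ndarray,
    other: list[str] | np.ndarray,
    k: int = 20,
    log2fc_min: float = 0.5,
    alpha: float = 0.05,
) -> GeneSignature:
    """Top-k marker genes of *target* vs *other*, ranked by log2 expression ratio.

    Candidates are the significant upregulated DEGs (Wilcoxon + BH with the
    default thresholds); they are ranked by
    ``log2((mean expm1 target + eps)/(mean expm1 other + eps))`` and the
    ``k`` largest are returned (all candidates, with a warning, if fewer).
    """
    de = wilcoxon_de(matrix, list(target), list(other), log2fc_min, alpha)
    candidates = [r for r in de if r.significant and r.log2fc > 0]
    candidates.sort(key=lambda r: -r.log2fc)
    if len(candidates) < k:
        logger.warning("only %d candidate markers for top-%d request", len(candidates), k)
    chosen = candidates[:k]
    if not chosen:
        raise NeotlsError("no significant marker gene found")
    return GeneSignature("top-ratio-markers", tuple(r.gene for r in chosen),
                         source_tag="derived")


def score_ratio(
    numerator: ScoreTable,
    denominator: ScoreTable,
    eps: float = 1e-6,
    shift: float | None = None,
) -> ScoreTable:
    """Per-entity ratio of two score tables.

    Module scores can be negative, so by default both tables are shifted
    by ``-min(both) + eps`` before dividing, making the ratio finite and
    positive.  Pass ``shift=0`` to divide the raw scores.
    """
    if set(numerator.scores.index) != set(denominator.scores.index):
        raise FormatError("score tables cover different entities")
    num = numerator.scores
    den = denominator.scores.reindex(num.index)
    if shift is None:
        shift = max(0.0, -float(min(num.min(), den.min()))) + eps
    ratio = (num + shift) / (den + shift)
    if not np.isfinite(ratio.to_numpy()).all():
        raise NeotlsError("ratio not finite; increase eps or use the default shift")
    return ScoreTable(ratio, "ratio",
                      f"{numerator.signature_name}/{denominator.signature_name}")


def classify_msi(msi_score: float, cutoff: float = 3.5) -> str:
    """Classify microsatellite status from an MSI score.

    ``MSI`` iff the score strictly exceeds the cutoff; the boundary value
    is assigned to ``MSS``.
    """
    if msi_score < 0:
        raise NeotlsError("MSI score must be non-negative")
    return "MSI" if msi_score > cutoff else "MSS"
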