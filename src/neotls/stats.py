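"""Study-level statistics: correlations, two-group tests, BH adjustment,
and cell-composition summaries across group x timepoint strata."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, NeotlsError
from .scoring import ScoreTable

logger = logging.getLogger(__name__)

__all__ = ["CorrelationRecord", "pearson", "bh_adjust", "two_group_test",
           "composition_summary"]


@dataclass(frozen=True)
class CorrelationRecord:
    x_name: str
    y_name: str
    n: int
    r: float
    p: float


def pearson(x: ScoreTable, y: ScoreTable) -> CorrelationRecord:
    """Pearson correlation on the entity intersection of two score tables.

    Entities are matched by id, not order; missing entities are dropped
    with a logged count.  Raises on fewer than three shared entities or a
    zero-variance input.
    """
    shared = x.scores.index.intersection(y.scores.index)
    dropped = len(x.scores) + len(y.scores) - 2 * len(shared)
    if dropped:
        logger.info("pearson: dropped %d unmatched entities", dropped)
    if len(shared) < 3:
        raise NeotlsError("need >= 3 shared entities for a correlation")
    xv = x.scores.reindex(shared).to_numpy(dtype=float)
    yv = y.scores.reindex(shared).to_numpy(dtype=float)
    for name, v in ((x.signature_name or "x", xv), (y.signature_name or "y", yv)):
        if np.ptp(v) == 0:
            raise NeotlsError(f"zero variance in {name!r}; correlation undefined")
    res = scipy.stats.pearsonr(xv, yv)
    return CorrelationRecord(x.signature_name or "x", y.signature_name or "y",
                             len(shared), float(res.statistic), float(res.pvalue))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise FormatError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_group_test(a, b, test: str = "wilcoxon") -> dict:
    """Two-sided two-group comparison (Wilcoxon rank-sum or t-test).

    Direction is the sign of the (a - b) median difference for Wilcoxon,
    mean difference for t.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise NeotlsError("both groups need >= 2 values")
    if test == "wilcoxon":
        if np.ptp(np.r_[a, b]) == 0:
            return {"test": test, "statistic": float(len(a) * len(b) / 2),
                    "p": 1.0, "direction": 0}
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic")
        delta = float(np.median(a) - np.median(b))
    elif test == "t":
        res = scipy.stats.ttest_ind(a, b)
        delta = float(a.mean() - b.mean())
    else:
        raise FormatError(f"unknown test {test!r}")
    return {"test": test, "statistic": float(res.statistic),
            "p": float(res.pvalue), "direction": int(np.sign(delta))}


def composition_summary(
    cells: pd.DataFrame,
    type_col: str = "subtype",
    group_col: str = "group",
    time_col: str = "timepoint",
    pre_label: str = "pre",
    post_label: str = "post",
    per_sample: bool = False,
    sample_col: str = "sample",
) -> pd.DataFrame:
    """Cell-type fractions per (group, timepoint) stratum with pre->post change.

    By default every cell counts equally within its stratum (pooled
    fractions); with ``per_sample=True`` fractions are first computed per
    sample and then averaged, weighting patients equally.  The ``change``
    column is the signed post-minus-pre fraction difference within each
    group, attached to both timepoint rows of that group; it is absent
    when a group lacks one of the timepoints (warning logged).
    """
    for c in (type_col, group_col, time_col):
        if c not in cells.columns:
            raise FormatError(f"missing column {c!r}")
        if cells[c].isna().any():
            raise FormatError(f"missing labels in column {c!r}")

    if per_sample:
        if sample_col not in cells.columns:
            raise FormatError(f"per_sample=True requires column {sample_col!r}")
        per = (cells.groupby([group_col, time_col, sample_col, type_col], observed=True)
               .size().rename("count").reset_index())
        per["fraction"] = per.groupby([group_col, time_col, sample_col],
                                      observed=True)["count"].transform(lambda c: c / c.sum())
        out = (per.groupby([group_col, time_col, type_col], observed=True)
               .agg(count=("count", "sum"), fraction=("fraction", "mean"))
               .reset_index())
        # averaged fractions may miss types absent in some samples; renormalize
        out["fraction"] = out.groupby([group_col, time_col], observed=True)["fraction"] \
            .transform(lambda f: f / f.sum())
    else:
        counts = (cells.groupby([group_col, time_col, type_col], observed=True)
                  .size().rename("count").reset_index())
        counts["fraction"] = counts.groupby([group_col, time_col], observed=True)["count"] \
            .transform(lambda c: c / c.sum())
        out = counts

    wide = out.pivot_table(index=[group_col, type_col], columns=time_col,
                           values="fraction", fill_value=0.0, observed=True)
    changes = {}
    for grp in out[group_col].unique():
        have = set(out.loc[out[group_col] == grp, time_col])
        if {pre_label, post_label} <= have:
            sub = wide.loc[grp]
            changes[grp] = sub.get(post_label, 0.0) - sub.get(pre_label, 0.0)
        else:
            logger.warning("group %r lacks a timepoint; change omitted", grp)
    if changes:
        out["change"] = [
            changes[g].get(t, np.nan) if g in changes else np.nan
            for g, t in zip(out[group_col], out[type_col])
        ]
    return out
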