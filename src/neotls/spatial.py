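"""TLS region calling in binned spatial transcriptomics.

A tertiary lymphoid structure (TLS) is called where T-cell and B-cell
summed signature scores are jointly high.  Absolute score cutoffs are
calibrated as top-percentile thresholds — by default the top 23.9% for
the T score and the top 5.4% for the B score, matching the single-cell
T/B cell fractions of the cohort — and a bin is a TLS bin when both of
its scores reach their cutoffs.  Called bins are aggregated into
connected regions (8-connectivity, minimum size 2 by default) and the
per-sample TLS proportion is the fraction of all bins that belong to a
retained region.  An ROC/AUC over the summed TLS-signature score
validates how well the score separates TLS from non-TLS bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats

from .errors import FormatError, NeotlsError
from .matrix import GeneSignature, SpatialSample
from .scoring import ScoreTable, summed_score

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSpec",
    "TLSCallResult",
    "calibrate_thresholds",
    "call_tls_bins",
    "label_regions",
    "tls_proportion",
    "validate_roc",
    "call_tls",
]


@dataclass
class ThresholdSpec:
    """Top-fraction parameters and the derived absolute score cutoffs."""

    p_t: float = 0.239
    p_b: float = 0.054
    cutoff_t: float | None = None
    cutoff_b: float | None = None

    def __post_init__(self) -> None:
        for p in (self.p_t, self.p_b):
            if not 0 < p < 1:
                raise FormatError("top fractions must lie in (0, 1)")


@dataclass
class TLSCallResult:
    """Per-bin TLS calls, region labels and the sample-level proportion."""

    calls: pd.DataFrame  # bin_id index; t_score, b_score, is_tls, region_id
    region_sizes: dict[int, int]
    tls_proportion: float
    thresholds: ThresholdSpec
    sample_label: str = ""
    auc: float | None = None


def _top_fraction_cutoff(scores: np.ndarray, p: float) -> float:
    """Smallest cutoff such that the fraction of scores >= cutoff is >= p.

    With ``n`` scores the cutoff is the ``ceil(p * n)``-th largest value;
    ties can only enlarge the passing set, keeping the fraction >= p.
    """
    n = len(scores)
    k = max(1, math.ceil(p * n))
    return float(np.sort(scores)[::-1][k - 1])


def calibrate_thresholds(
    t_scores: ScoreTable,
    b_scores: ScoreTable,
    p_t: float = 0.239,
    p_b: float = 0.054,
    cell_fractions: tuple[float, float] | None = None,
) -> ThresholdSpec:
    """Derive absolute score cutoffs from top-fraction parameters.

    ``cell_fractions``, when given as (T fraction, B fraction) observed in
    matched single-cell data, overrides ``p_t``/``p_b`` — the top-percentile
    equals the cell-type fraction.  Constant scores trigger a warning and a
    cutoff equal to that constant (every bin passes).
    """
    if cell_fractions is not None:
        p_t, p_b = cell_fractions
    spec = ThresholdSpec(p_t, p_b)
    tv, bv = t_scores.values(), b_scores.values()
    for name, v in (("T", tv), ("B", bv)):
        if np.ptp(v) == 0:
            logger.warning("%s scores are constant; every bin passes that cutoff", name)
    spec.cutoff_t = _top_fraction_cutoff(tv, spec.p_t)
    spec.cutoff_b = _top_fraction_cutoff(bv, spec.p_b)
    return spec


def call_tls_bins(
    sample: SpatialSample,
    t_sig: GeneSignature,
    b_sig: GeneSignature,
    spec: ThresholdSpec,
) -> pd.DataFrame:
    """Per-bin conjunction call: both summed scores at or above cutoff."""
    if spec.cutoff_t is None or spec.cutoff_b is None:
        raise NeotlsError("thresholds not calibrated; run calibrate_thresholds first")
    t = summed_score(sample.matrix, t_sig).scores
    b = summed_score(sample.matrix, b_sig).scores
    return pd.DataFrame({
        "t_score": t,
        "b_score": b,
        "is_tls": (t >= spec.cutoff_t) & (b >= spec.cutoff_b),
    })


def label_regions(
    calls: pd.Series,
    coords: pd.DataFrame,
    connectivity: int = 8,
    min_size: int = 2,
) -> tuple[pd.Series, dict[int, int]]:
    """Group called bins into connected regions; demote undersized ones.

    Connected components of TLS bins under 4- or 8-adjacency on the
    integer grid; components smaller than ``min_size`` are demoted to
    non-TLS (region id -1).  Labels follow row-major discovery order.
    """
    if connectivity not in (4, 8):
        raise FormatError("connectivity must be 4 or 8")
    coords = coords.loc[calls.index]
    xs = coords["x"].to_numpy(dtype=int)
    ys = coords["y"].to_numpy(dtype=int)
    x0, y0 = xs.min(), ys.min()
    grid = np.zeros((ys.max() - y0 + 1, xs.max() - x0 + 1), dtype=bool)
    grid[ys - y0, xs - x0] = calls.to_numpy(dtype=bool)
    structure = np.ones((3, 3), dtype=bool) if connectivity == 8 else None
    labeled, n = scipy.ndimage.label(grid, structure=structure)
    per_bin = labeled[ys - y0, xs - x0]
    sizes = {int(lab): int((per_bin == lab).sum()) for lab in range(1, n + 1)}
    small = {lab for lab, sz in sizes.items() if sz < min_size}
    region = pd.Series(per_bin, index=calls.index)
    region[region.isin(small) | (region == 0)] = -1
    kept = sorted(set(region.unique()) - {-1})
    remap = {old: new for new, old in enumerate(kept, start=1)}
    region = region.map(lambda v: remap.get(v, -1))
    return region, {remap[lab]: sizes[lab] for lab in kept}


def tls_proportion(calls: pd.DataFrame) -> float:
    """Fraction of all bins in a retained TLS region."""
    if len(calls) == 0:
        raise FormatError("no bins")
    return float((calls["region_id"] > 0).mean())


def validate_roc(scores: ScoreTable, labels: pd.Series) -> tuple[float, pd.DataFrame]:
    """Rank-statistic AUC of a score against binary bin labels.

    The AUC is the probability that a random positive bin outscores a
    random negative bin, with ties given half credit — computed from the
    midrank sum, which equals the all-pairs average exactly.  Also returns
    the ROC curve points (FPR, TPR) at every distinct score cutoff.
    """
    s = scores.scores
    y = pd.Series(labels).reindex(s.index).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise NeotlsError("ROC needs both classes present")
    v = s.to_numpy(dtype=float)
    ranks = scipy.stats.rankdata(v)  # midranks
    auc = (ranks[y.to_numpy()].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-v, kind="stable")
    yy = y.to_numpy()[order]
    vv = v[order]
    tps = np.cumsum(yy)
    fps = np.cumsum(~yy)
    last = np.r_[vv[1:] != vv[:-1], True]  # curve point per distinct cutoff
    curve = pd.DataFrame({
        "cutoff": vv[last],
        "fpr": fps[last] / n_neg,
        "tpr": tps[last] / n_pos,
    })
    curve = pd.concat([pd.DataFrame({"cutoff": [np.inf], "fpr": [0.0], "tpr": [0.0]}),
                       curve], ignore_index=True)
    return float(auc), curve


def call_tls(
    sample: SpatialSample,
    t_sig: GeneSignature,
    b_sig: GeneSignature,
    spec: ThresholdSpec | None = None,
    connectivity: int = 8,
    min_size: int = 2,
    tls_sig: GeneSignature | None = None,
) -> TLSCallResult:
    """End-to-end TLS calling for one spatial sample.

    Calibrates cutoffs on the sample's own score distributions when
    ``spec`` carries no absolute cutoffs, calls bins, labels regions, and
    computes the TLS proportion.  When ``tls_sig`` is given, the AUC of
    its summed score against the final calls is reported as validation.
    """
    if spec is None:
        spec = ThresholdSpec()
    if spec.cutoff_t is None or spec.cutoff_b is None:
        t = summed_score(sample.matrix, t_sig)
        b = summed_score(sample.matrix, b_sig)
        spec = calibrate_thresholds(t, b, spec.p_t, spec.p_b)
    calls = call_tls_bins(sample, t_sig, b_sig, spec)
    region, sizes = label_regions(calls["is_tls"], sample.coords, connectivity, min_size)
    calls["region_id"] = region
    calls["is_tls"] = calls["region_id"] > 0  # after min-size demotion
    result = TLSCallResult(calls, sizes, tls_proportion(calls), spec,
                           sample.sample_label)
    if tls_sig is not None:
        result.auc, _ = validate_roc(summed_score(sample.matrix, tls_sig),
                                     calls["is_tls"])
    return result
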