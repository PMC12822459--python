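"""Exhausted-T-cell staging from a bimodal pseudotime distribution.

Exhausted T cells (Tex) along a differentiation trajectory show a
two-peaked pseudotime density; the stage split places the cut at the
antimode (the density minimum strictly between the two highest modes).
Cells at or below the split are *early-Tex*, cells above are
*terminal-Tex*.  Pseudotime is consumed as an input column: trajectory
inference itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .errors import FormatError, NeotlsError, UnimodalityError
from .scoring import ScoreTable

__all__ = ["StageAssignment", "split_bimodal", "compare_stages", "proportion_table"]

GRID_SIZE = 512
MIN_PEAK_PROMINENCE = 0.05  # of the density maximum; rejects KDE ripple


@dataclass
class StageAssignment:
    """Per-cell early/terminal stage labels plus split diagnostics."""

    stages: pd.Series  # cell_id -> "early" | "terminal"
    split_point: float
    peak_locations: tuple[float, float]
    diagnostics: dict = field(default_factory=dict)

    def ids(self, stage: str) -> np.ndarray:
        return self.stages.index[self.stages == stage].to_numpy()


def _kde_on_grid(x: np.ndarray, bandwidth: str | float) -> tuple[np.ndarray, np.ndarray, float]:
    if isinstance(bandwidth, str):
        if bandwidth != "silverman":
            raise FormatError(f"unknown bandwidth rule {bandwidth!r}")
        kde = scipy.stats.gaussian_kde(x, bw_method="silverman")
    else:
        if bandwidth <= 0:
            raise FormatError("bandwidth must be positive")
        kde = scipy.stats.gaussian_kde(x, bw_method=bandwidth / max(x.std(ddof=1), 1e-12))
    bw = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, GRID_SIZE)
    return grid, kde(grid), bw


def split_bimodal(
    pseudotime: pd.Series,
    bandwidth: str | float = "silverman",
) -> StageAssignment:
    """Split cells into early/terminal stages at the pseudotime antimode.

    A Gaussian KDE (Silverman bandwidth by default) is evaluated on a
    512-point grid; the two local maxima with the highest density are the
    peaks and the split point is the grid minimum strictly between them
    (midpoint on ties).  Maxima with prominence below 5% of the density
    maximum are ignored as estimation ripple.  Raises
    :class:`UnimodalityError` when fewer than two modes remain — the
    caller may then force a quantile split.
    """
    x = pd.Series(pseudotime).astype(float)
    if len(x) < 20:
        raise FormatError("need >= 20 cells for a density split")
    if not np.isfinite(x.to_numpy()).all():
        raise FormatError("pseudotime contains non-finite values")
    vals = x.to_numpy()

    grid, dens_raw, bw = _kde_on_grid(vals, bandwidth)
    dens = dens_raw / dens_raw.max()  # scale-free: tie detection is affine-invariant
    maxima, _ = scipy.signal.find_peaks(np.r_[0.0, dens, 0.0],
                                        prominence=MIN_PEAK_PROMINENCE)
    maxima -= 1  # undo the padding used to catch boundary modes
    diagnostics = {"bandwidth": bw, "n_maxima": int(len(maxima)),
                   "grid_range": (float(grid[0]), float(grid[-1]))}
    if len(maxima) < 2:
        raise UnimodalityError(
            f"pseudotime density has {len(maxima)} local maximum(s); "
            "expected a bimodal distribution", diagnostics)

    # the two highest-density maxima; ties broken toward wider separation
    order = np.argsort(dens[maxima], kind="stable")[::-1]
    second_density = dens[maxima[order[1]]]
    cands = maxima[np.isclose(dens[maxima], second_density) | (dens[maxima] > second_density)]
    lo, hi = max(((i, j) for i in cands for j in cands if i < j),
                 key=lambda ij: grid[ij[1]] - grid[ij[0]])

    between = dens[lo + 1:hi]
    if len(between) == 0:
        raise UnimodalityError("peaks are adjacent on the density grid", diagnostics)
    min_val = between.min()
    tie_pos = np.flatnonzero(np.isclose(between, min_val)) + lo + 1
    split = float(grid[tie_pos].mean()) if len(tie_pos) > 1 else float(grid[tie_pos[0]])

    stages = pd.Series(np.where(vals <= split, "early", "terminal"), index=x.index)
    diagnostics.update({
        "peak_densities": (float(dens_raw[lo]), float(dens_raw[hi])),
        "antimode_density": float(min_val * dens_raw.max()),
    })
    return StageAssignment(stages, split, (float(grid[lo]), float(grid[hi])), diagnostics)


def quantile_split(pseudotime: pd.Series, q: float = 0.5) -> StageAssignment:
    """Fallback stage split at a pseudotime quantile (no density model)."""
    x = pd.Series(pseudotime).astype(float)
    split = float(x.quantile(q))
    stages = pd.Series(np.where(x.to_numpy() <= split, "early", "terminal"), index=x.index)
    return StageAssignment(stages, split, (float("nan"), float("nan")),
                           {"method": "quantile", "q": q})


def compare_stages(
    scores: ScoreTable,
    stages: StageAssignment,
    test: str = "wilcoxon",
) -> dict:
    """Two-sided early-vs-terminal comparison of a score table.

    Returns a record with the test statistic, two-sided p-value and the
    direction: the sign of (early - terminal) medians for the Wilcoxon
    rank-sum test, means for the t-test.
    """
    s = scores.scores
    early = s.reindex(stages.ids("early")).dropna().to_numpy()
    terminal = s.reindex(stages.ids("terminal")).dropna().to_numpy()
    if len(early) < 2 or len(terminal) < 2:
        raise NeotlsError("both stages need >= 2 scored cells")
    if test == "wilcoxon":
        res = scipy.stats.mannwhitneyu(early, terminal, alternative="two-sided",
                                       method="asymptotic")
        delta = float(np.median(early) - np.median(terminal))
    elif test == "t":
        res = scipy.stats.ttest_ind(early, terminal)
        delta = float(early.mean() - terminal.mean())
    else:
        raise FormatError(f"unknown test {test!r}")
    return {
        "test": test,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "direction": int(np.sign(delta)),
        "n_early": len(early),
        "n_terminal": len(terminal),
    }


def proportion_table(
    cells: pd.DataFrame,
    subtype_col: str = "subtype",
    by: tuple[str, ...] = ("group", "timepoint"),
) -> pd.DataFrame:
    """Subtype fractions within each stratum of the ``by`` columns.

    Returns a long table with count and fraction per (stratum, subtype);
    fractions sum to 1 within every stratum.
    """
    missing = [c for c in (*by, subtype_col) if c not in cells.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    if cells[list(by) + [subtype_col]].isna().any().any():
        raise FormatError("unknown (missing) labels in cell table")
    counts = cells.groupby(list(by) + [subtype_col], observed=True).size().rename("count")
    totals = counts.groupby(level=list(range(len(by)))).transform("sum")
    out = counts.to_frame()
    out["fraction"] = counts / totals
    return out.reset_index()
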