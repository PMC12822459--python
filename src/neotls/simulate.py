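"""Synthetic cohorts and spatial grids with planted, ground-truthed structure.

The generator emulates the statistical shape of a neoadjuvant-therapy
single-cell study: negative-binomial UMI counts with subtype-specific
marker elevation, responder/non-responder x pre/post composition shifts,
a two-component pseudotime mixture for exhausted T cells, and binned
spatial grids containing contiguous discs where T- and B-signature genes
are jointly elevated over a common background.

Counts are drawn gene-wise negative binomial with a shared dispersion
(gamma-Poisson mixture); library-size variation enters through a
per-cell lognormal(0, 0.3) scaling factor.  All marker and region
elevations are log2 fold-changes.  A single seed drives one
:class:`numpy.random.SeedSequence`; per-stage substreams are spawned
deterministically, so identical config + seed gives byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import ExpressionMatrix, GeneSignature, SpatialSample

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PlantedRegion",
    "simulate_cohort",
    "simulate_spatial",
    "default_cohort_config",
    "default_spatial_config",
    "disc_bins",
    "write_cohort",
]

Stratum = tuple[str, str]  # (group, timepoint)

LIBSIZE_LOGNORMAL_SD = 0.3


@dataclass(frozen=True)
class PlantedRegion:
    """A disc of bins with jointly elevated T/B signature genes."""

    center: tuple[int, int]  # (x, y)
    radius: float
    t_elevation: float  # log2 fold
    b_elevation: float  # log2 fold

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ConfigurationError("region radius must be >= 1")
        if not (math.isfinite(self.t_elevation) and math.isfinite(self.b_elevation)):
            raise ConfigurationError("elevations must be finite")


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    ``subtype_table`` maps each cell subtype to its expected fraction per
    (group, timepoint) stratum (a bare float applies to every stratum);
    fractions must sum to 1 within each stratum.  ``marker_map`` maps a
    subtype to (gene indices, log2-fold elevation).  ``pseudotime_mix``
    holds (weight, mean, sd) for the early and terminal Tex components;
    ``tex_early_weight`` optionally overrides the early-component weight
    per stratum, modelling treatment-driven stage shifts.
    ``treatment_shift`` plants a post-timepoint log2-fold change on a set
    of genes in every cell, for differential-expression ground truth.
    """

    n_genes: int = 2000
    n_cells: int = 4000
    subtype_table: Mapping[str, float | Mapping[Stratum, float]] = field(
        default_factory=lambda: {"Tumor": 0.5, "Tex": 0.25, "B": 0.25})
    marker_map: Mapping[str, tuple[Sequence[int], float]] = field(default_factory=dict)
    nb_dispersion: float = 0.1
    depth_mean: float = 5000.0
    pseudotime_mix: tuple[tuple[float, float, float], ...] = ((0.5, 5.0, 1.0),
                                                             (0.5, 20.0, 1.0))
    tex_subtype: str = "Tex"
    tex_early_weight: Mapping[Stratum, float] | None = None
    treatment_shift: tuple[Sequence[int], float] | None = None
    groups: tuple[str, ...] = ("R", "NR")
    timepoints: tuple[str, ...] = ("pre", "post")
    n_mito_genes: int = 10
    grid_shape: tuple[int, int] = (60, 60)  # (rows, cols)
    planted_regions: tuple[PlantedRegion, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells <= 0:
            raise ConfigurationError("n_genes and n_cells must be positive")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be non-negative")
        if self.grid_shape[0] <= 0 or self.grid_shape[1] <= 0:
            raise ConfigurationError("grid_shape must be positive")
        w = sum(c[0] for c in self.pseudotime_mix)
        if abs(w - 1) > 1e-9:
            raise ConfigurationError("pseudotime mixture weights must sum to 1")
        for (g, t) in self.strata():
            tot = sum(self.fraction(s, (g, t)) for s in self.subtype_table)
            if abs(tot - 1) > 1e-9:
                raise ConfigurationError(
                    f"subtype fractions for stratum {(g, t)} sum to {tot}, not 1")
        for sub, (idx, fc) in self.marker_map.items():
            if sub not in self.subtype_table:
                raise ConfigurationError(f"marker_map subtype {sub!r} unknown")
            if not math.isfinite(fc):
                raise ConfigurationError("marker elevation must be finite")
            if max(idx, default=0) >= self.n_genes or min(idx, default=0) < 0:
                raise ConfigurationError("marker gene index out of range")
        rows, cols = self.grid_shape
        for reg in self.planted_regions:
            x, y = reg.center
            if not (0 <= x < cols and 0 <= y < rows):
                raise ConfigurationError(f"region center {reg.center} outside grid")
            if (x - reg.radius < 0 or x + reg.radius >= cols
                    or y - reg.radius < 0 or y + reg.radius >= rows):
                raise ConfigurationError(f"region at {reg.center} does not fit in grid")

    def strata(self) -> list[Stratum]:
        return [(g, t) for g in self.groups for t in self.timepoints]

    def fraction(self, subtype: str, stratum: Stratum) -> float:
        v = self.subtype_table[subtype]
        return float(v) if isinstance(v, (int, float)) else float(v[stratum])

    def gene_ids(self) -> np.ndarray:
        ids = [f"g{i:04d}" for i in range(self.n_genes)]
        for i in range(min(self.n_mito_genes, self.n_genes)):
            ids[i] = f"MT-{ids[i]}"
        return np.array(ids, dtype=object)


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    cell_subtype_labels: pd.Series | None = None
    tex_stage_labels: pd.Series | None = None  # Tex cells only
    tls_bin_mask: pd.Series | None = None
    de_gene_mask: np.ndarray | None = None


def _base_gene_means(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene expected counts, normalized to sum to depth_mean."""
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    return raw / raw.sum() * cfg.depth_mean


def _nb_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def _allocate(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n items to weighted bins."""
    ideal = weights / weights.sum() * n
    base = np.floor(ideal).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(ideal - base), kind="stable")
    base[order[:rem]] += 1
    return base


def simulate_cohort(cfg: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate a cohort-style count matrix with annotated cells.

    Cells are spread as evenly as possible across the group x timepoint
    strata; within a stratum, subtype counts follow the configured
    fractions by multinomial draw.  Marker genes of a cell's subtype are
    elevated by their log2 fold; Tex cells carry a pseudotime drawn from
    the two-component normal mixture (truncated at zero).  Returns the
    counts matrix, the cell table (sample, group, timepoint, subtype,
    pseudotime) and the ground truth.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_genes, rng_cells, rng_counts, rng_pt = (
        np.random.default_rng(s) for s in ss.spawn(4))

    base = _base_gene_means(cfg, rng_genes)
    strata = cfg.strata()
    per_stratum = _allocate(cfg.n_cells, np.ones(len(strata)))

    subtypes = list(cfg.subtype_table)
    rows = []
    for (g, t), n_st in zip(strata, per_stratum):
        fracs = np.array([cfg.fraction(s, (g, t)) for s in subtypes])
        counts_st = rng_cells.multinomial(n_st, fracs)
        for sub, k in zip(subtypes, counts_st):
            rows += [(f"{g}_{t}", g, t, sub)] * int(k)
    cell_ids = np.array([f"cell{i:05d}" for i in range(cfg.n_cells)], dtype=object)
    cells = pd.DataFrame(rows, columns=["sample", "group", "timepoint", "subtype"],
                         index=pd.Index(cell_ids, name="cell_id"))

    # per-cell expected gene means
    log2_shift = np.zeros((cfg.n_genes, cfg.n_cells))
    for sub, (idx, fc) in cfg.marker_map.items():
        cols = np.flatnonzero((cells["subtype"] == sub).to_numpy())
        if len(cols):
            log2_shift[np.ix_(np.asarray(idx, dtype=int), cols)] += fc
    de_mask = np.zeros(cfg.n_genes, dtype=bool)
    if cfg.treatment_shift is not None:
        idx, fc = cfg.treatment_shift
        cols = np.flatnonzero((cells["timepoint"] == cfg.timepoints[1]).to_numpy())
        log2_shift[np.ix_(np.asarray(idx, dtype=int), cols)] += fc
        de_mask[np.asarray(idx, dtype=int)] = True

    libsize = rng_counts.lognormal(0.0, LIBSIZE_LOGNORMAL_SD, size=cfg.n_cells)
    mu = base[:, None] * np.exp2(log2_shift) * libsize[None, :]
    counts = _nb_counts(mu, cfg.nb_dispersion, rng_counts)

    # pseudotime for Tex cells: two-component truncated-normal mixture
    cells["pseudotime"] = np.nan
    tex_idx = np.flatnonzero((cells["subtype"] == cfg.tex_subtype).to_numpy())
    stage = pd.Series(index=cells.index[tex_idx], dtype=object)
    if len(tex_idx):
        (w0, m0, s0), (w1, m1, s1) = cfg.pseudotime_mix
        strat_keys = list(zip(cells["group"], cells["timepoint"]))
        early_w = np.full(len(tex_idx), w0)
        if cfg.tex_early_weight is not None:
            for j, ci in enumerate(tex_idx):
                early_w[j] = cfg.tex_early_weight.get(strat_keys[ci], w0)
        comp = rng_pt.random(len(tex_idx)) >= early_w  # False -> early
        pt = np.where(comp,
                      rng_pt.normal(m1, s1, len(tex_idx)),
                      rng_pt.normal(m0, s0, len(tex_idx)))
        pt = np.clip(pt, 0.0, None)
        cells.iloc[tex_idx, cells.columns.get_loc("pseudotime")] = pt
        stage[:] = np.where(comp, "terminal", "early")

    matrix = ExpressionMatrix(counts, cfg.gene_ids(), cell_ids, "counts")
    truth = GroundTruth(cell_subtype_labels=cells["subtype"].copy(),
                        tex_stage_labels=stage,
                        de_gene_mask=de_mask)
    return matrix, cells, truth


def disc_bins(center: tuple[int, int], radius: float,
              grid_shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Integer bins (x, y) with Euclidean distance from center <= radius."""
    rows, cols = grid_shape
    cx, cy = center
    out = []
    for y in range(rows):
        for x in range(cols):
            if (x - cx) ** 2 + (y - cy) ** 2 <= radius ** 2:
                out.append((x, y))
    return out


def simulate_spatial(
    cfg: SimConfig,
    t_signature: GeneSignature,
    b_signature: GeneSignature,
) -> tuple[SpatialSample, GroundTruth]:
    """Generate a binned spatial grid with planted TLS discs.

    Every bin draws negative-binomial counts from a common background;
    inside each planted disc the T- and B-signature genes are elevated by
    the region's log2 folds.  ``tls_bin_mask`` marks exactly the planted
    bins.  Bin ids encode the grid position (``bin_{x}_{y}``).
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_genes, rng_counts = (np.random.default_rng(s) for s in ss.spawn(2))

    rows, cols = cfg.grid_shape
    n_bins = rows * cols
    base = _base_gene_means(cfg, rng_genes)
    gene_ids = cfg.gene_ids()
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    t_idx = np.array([gene_pos[g] for g in t_signature.intersect(gene_ids)], dtype=int)
    b_idx = np.array([gene_pos[g] for g in b_signature.intersect(gene_ids)], dtype=int)

    xs, ys = np.meshgrid(np.arange(cols), np.arange(rows))
    xs, ys = xs.ravel(), ys.ravel()
    bin_ids = np.array([f"bin_{x}_{y}" for x, y in zip(xs, ys)], dtype=object)

    mask = np.zeros(n_bins, dtype=bool)
    log2_shift = np.zeros((cfg.n_genes, n_bins))
    for reg in cfg.planted_regions:
        inside = ((xs - reg.center[0]) ** 2 + (ys - reg.center[1]) ** 2
                  <= reg.radius ** 2)
        mask |= inside
        cols_in = np.flatnonzero(inside)
        if len(t_idx):
            log2_shift[np.ix_(t_idx, cols_in)] = np.maximum(
                log2_shift[np.ix_(t_idx, cols_in)], reg.t_elevation)
        if len(b_idx):
            log2_shift[np.ix_(b_idx, cols_in)] = np.maximum(
                log2_shift[np.ix_(b_idx, cols_in)], reg.b_elevation)

    libsize = rng_counts.lognormal(0.0, LIBSIZE_LOGNORMAL_SD, size=n_bins)
    mu = base[:, None] * np.exp2(log2_shift) * libsize[None, :]
    counts = _nb_counts(mu, cfg.nb_dispersion, rng_counts)

    matrix = ExpressionMatrix(counts, gene_ids, bin_ids, "counts")
    coords = pd.DataFrame({"x": xs, "y": ys}, index=pd.Index(bin_ids, name="bin_id"))
    sample = SpatialSample(matrix, coords, sample_label="synthetic")
    truth = GroundTruth(tls_bin_mask=pd.Series(mask, index=coords.index))
    return sample, truth


def default_cohort_config(seed: int = 0, **overrides) -> SimConfig:
    """Cohort defaults mirroring the study conditions.

    Five subtypes with responder/non-responder x pre/post composition
    shifts (B cells and Tex expand after treatment in responders); 40
    marker genes per subtype at +1 log2 fold; the Tex early-stage weight
    rises from 0.3 to 0.6 after treatment in responders only.
    """
    n_genes = overrides.pop("n_genes", 2000)
    subtype_table = {
        "Epithelial": {("R", "pre"): 0.40, ("R", "post"): 0.25,
                       ("NR", "pre"): 0.40, ("NR", "post"): 0.40},
        "Myeloid": 0.15,
        "B": {("R", "pre"): 0.10, ("R", "post"): 0.20,
              ("NR", "pre"): 0.10, ("NR", "post"): 0.10},
        "Tem": {("R", "pre"): 0.15, ("R", "post"): 0.15,
                ("NR", "pre"): 0.15, ("NR", "post"): 0.15},
        "Tex": {("R", "pre"): 0.20, ("R", "post"): 0.25,
                ("NR", "pre"): 0.20, ("NR", "post"): 0.20},
    }
    n_marker = 40
    marker_map = {
        sub: (list(range(100 + i * n_marker, 100 + (i + 1) * n_marker)), 1.0)
        for i, sub in enumerate(subtype_table)
    }
    cfg = dict(
        n_genes=n_genes,
        n_cells=4000,
        subtype_table=subtype_table,
        marker_map=marker_map,
        nb_dispersion=0.1,
        depth_mean=5000.0,
        pseudotime_mix=((0.5, 5.0, 1.0), (0.5, 20.0, 1.0)),
        tex_early_weight={("R", "pre"): 0.3, ("R", "post"): 0.6,
                          ("NR", "pre"): 0.3, ("NR", "post"): 0.3},
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def default_spatial_config(seed: int = 0, **overrides) -> SimConfig:
    """Spatial defaults: 60x60 grid, three planted discs, +2 log2 folds."""
    cfg = dict(
        n_genes=1000,
        grid_shape=(60, 60),
        planted_regions=(
            PlantedRegion((15, 15), 4.0, 2.0, 2.0),
            PlantedRegion((45, 20), 3.0, 2.0, 2.0),
            PlantedRegion((30, 45), 5.0, 2.0, 2.0),
        ),
        nb_dispersion=0.1,
        depth_mean=5000.0,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def write_cohort(outdir, matrix: ExpressionMatrix, cells: pd.DataFrame,
                 truth: GroundTruth) -> None:
    """Write a simulated cohort as MTX triplet + TSV tables."""
    from .matrix import write_expression

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(matrix, outdir, format="mtx")
    cells.to_csv(outdir / "cells.tsv", sep="\t")
    if truth.tex_stage_labels is not None:
        truth.tex_stage_labels.rename("stage").rename_axis("cell_id") \
            .to_csv(outdir / "tex_stages.tsv", sep="\t")
    if truth.de_gene_mask is not None:
        pd.Series(truth.de_gene_mask, index=matrix.gene_ids, name="is_de") \
            .rename_axis("gene_id").to_csv(outdir / "de_genes.tsv", sep="\t")
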