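# Methods

This note records the models, conventions and numerical choices behind
`neotls`, in the order data flows through the pipeline.

## Quality control

Per-cell metrics are the UMI total, the detected-gene count and the
mitochondrial percentage (genes matched by prefix, default `MT-`). A
cell is removed iff

- mito% > median + 5·MAD (one-sided: only high mitochondrial load marks
  damage), or
- |UMI − median| > 3·MAD, or
- |genes − median| > 3·MAD (both two-sided: unusually shallow and
  unusually deep cells are suspect).

MAD is the raw median absolute deviation from the median with **no**
1.4826 consistency constant; the multipliers therefore act on the raw
robust scale. When every cell shares a metric value the MAD is zero and
no cell deviates, so none is removed on that metric — only strict
exceedance removes a cell. When a sample assignment is supplied the
medians and MADs are computed within each sample, since depth and
quality vary more across libraries than within them; a global mode is
available and is what a single-sample matrix gets.

Normalization is the standard depth-scaled log transform
`ln(1 + c / total · scale)` with `scale = 10,000` (configurable). Cells
with zero totals stay all-zero with a warning rather than erroring,
because QC normally removes them first.

## Module scores

Genes are ranked by mean expression over all entities and cut into 25
equal-size abundance bins. Each signature gene contributes control genes
from its own bin: the whole bin (deterministically) when the bin has at
most `n_ctrl = 100` members, otherwise a without-replacement sample of
100. The score is the mean over signature genes minus the mean over the
pooled controls. This centres a random signature at zero on exchangeable
data and makes the score exactly zero when the signature *is* the
background (every bin exhausted), which is the degenerate case worth
keeping exact. Scores are deterministic given the seed.

Summed scores are plain totals of the signature genes' values; they are
linear in the signature (score(S₁∪S₂) = score(S₁)+score(S₂) for disjoint
sets) and are the quantity thresholded in spatial TLS calling, where an
absolute, monotone score is wanted rather than a background-relative
one.

## Differential expression and derived signatures

Per-gene comparison uses the two-sided Wilcoxon rank-sum
(Mann–Whitney U) test in its asymptotic form with tie correction and
continuity correction; a gene constant across both groups gets p = 1 by
convention. Fold changes are computed on the depth-normalized scale:
`log2FC = log2(mean expm1 A + ε) − log2(mean expm1 B + ε)` with
ε = 10⁻⁹ to avoid infinities on all-zero groups. P-values are BH-adjusted
across exactly the genes tested in the call, and a gene is significant
when `log2FC > 0.5` and `padj < 0.05` (both strict).

The treatment-associated TLS signature is the published TLS gene list
restricted to genes whose pre-vs-post `padj` falls below α = 0.05.
Direction is **not** filtered by default — treatment response in either
direction keeps a gene — with an optional flag to require upregulation.
Order follows the published list, and the output is always a subset of
it.

Top-ratio markers take the significant upregulated DEGs of a target
population and rank them by the log2 ratio of mean normalized
expression, returning the top k = 20 (all candidates, with a warning, if
fewer). With strong planted elevations the returned set matches the
largest planted folds; the ranking of near-tied folds is noise-limited,
which is why tests assert set recovery plus ordering by the measured
ratio rather than by the planted one.

MSI classification applies the fixed cutoff 3.5: scores strictly above
are MSI, the boundary value is assigned to MSS as the conservative
majority class.

## Exhausted-T-cell staging

Pseudotime is consumed as an input column (trajectory inference is out
of scope). The density is a Gaussian KDE with Silverman's bandwidth
(overridable by a numeric bandwidth), evaluated on a 512-point grid
spanning `[min − 3·bw, max + 3·bw]`. Modes are local maxima with
prominence of at least 5% of the density maximum — the floor rejects
estimation ripple in tails that would otherwise masquerade as a second
mode on genuinely unimodal data. The two highest-density modes are the
peaks (ties broken toward the more separated pair); the split point is
the grid minimum strictly between them, the midpoint on ties. Cells at
or below the split are early-Tex, above it terminal-Tex, so labels are
monotone in pseudotime by construction. Density values are normalized by
their maximum before peak and tie detection, which makes the whole
procedure invariant to affine rescaling of pseudotime. Fewer than two
qualifying modes raises a `UnimodalityError` carrying the diagnostics;
`quantile_split` is the documented fallback.

## TLS calling in spatial bins

For each sample, the T and B summed scores are thresholded at calibrated
absolute cutoffs. The cutoff for top-fraction `p` over `n` bins is the
`ceil(p·n)`-th largest score: the smallest cutoff for which the fraction
of bins at or above it is ≥ p. With distinct scores exactly `ceil(p·n)`
bins pass; ties can only enlarge the passing set. "Above the threshold"
is implemented as ≥, which with this minimal-cutoff rule reproduces
"top p%" exactly on continuous scores and is deterministic under ties.
Defaults are p_t = 0.239 and p_b = 0.054; alternatively the fractions
are taken directly from matched single-cell T/B cell-type fractions
(fraction = top-percentile). Quantiles are computed within each spatial
sample independently.

A bin is a TLS bin when **both** scores pass. Called bins are grouped
into connected components under 8-adjacency (4-adjacency available);
components smaller than 2 bins are demoted to non-TLS. The adjacency and
minimum size are this package's own aggregation rule — any choice here
defines what counts as one structure, and 8-connectivity with a 2-bin
floor treats diagonal contact as contiguity while discarding isolated
single-bin calls. The TLS proportion is the fraction of all bins inside
a retained region. Because demotion only removes bins, the final TLS set
remains monotone in (p_t, p_b).

Validation uses the rank-statistic AUC of the summed TLS-signature score
against the calls: ties receive half credit via midranks, so the value
equals the all-pairs probability that a random TLS bin outscores a
random non-TLS bin, exactly.

## Study statistics

Pearson correlations match entities by id intersection (not order),
require ≥ 3 shared entities and nonzero variance, and take the two-sided
p from the t transform. BH adjustment is the step-up procedure with
monotonicity enforcement. Composition summaries pool cells within each
group × timepoint stratum by default (every cell weighted equally, as in
stacked proportion bars); a per-sample-mean mode weights patients
equally instead, with fractions renormalized after averaging. The
pre→post change column is the signed fraction difference within each
group.

## Synthetic data

The generator is the test bed for every stage and mirrors the study
design it emulates:

- **Counts.** Gene-wise negative binomial via a gamma–Poisson mixture
  with shared dispersion 0.1; per-gene base means are lognormal(0, 1)
  normalized to an expected library size of 5,000 counts; library-size
  variation is a per-cell lognormal(0, 0.3) factor. Marker and region
  elevations are log2 fold-changes applied multiplicatively to the mean.
- **Cohort.** Cells are spread evenly over responder/non-responder ×
  pre/post strata; subtype counts per stratum are multinomial in the
  configured fractions. The default cohort has five subtypes with B
  cells and Tex expanding after treatment in responders only.
- **Tex pseudotime.** A two-component normal mixture, default
  0.5·N(5,1) + 0.5·N(20,1) truncated at zero; the early-component weight
  can differ per stratum (default 0.3 pre → 0.6 post in responders,
  flat 0.3 in non-responders), planting the stage shift the staging and
  proportion code must recover.
- **Spatial.** A 60×60 grid of bins with three planted discs (radii 3–5,
  +2 log2 folds on the T and B signature genes; disc membership is
  Euclidean distance from the center ≤ radius on integer coordinates).
  The ground-truth mask marks exactly the planted bins.
- **Determinism.** One `SeedSequence` per call, spawned into per-stage
  substreams, so identical config + seed gives byte-identical output.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, spatial diffusion between bins, gene–gene correlation beyond
the planted structure, and irregular (non-grid) bin layouts. Passing
tests therefore demonstrate correctness of the procedures under the
stated statistical assumptions, not robustness to these real-data
artifacts.

## Problem sizes

Tests and the reproduction script run cohorts of 400–6,000 cells with
400–2,000 genes and one 60×60 spatial grid — sizes chosen so planted
effects are comfortably detectable at the configured effect sizes while
the whole suite stays interactive. Calibration checks use 1,000
replicates where a rate is being estimated (type-I error) and 100
replicates where agreement is exact (BH oracle).

## Known limitations

- The antimode split assumes exactly two meaningful modes; more complex
  pseudotime topologies need upstream branch handling.
- Percentile threshold calibration transfers single-cell fractions to
  spatial bins one-to-one; systematic differences in per-bin cell
  content would bias the mapping.
- The Wilcoxon asymptotic p-value is inaccurate below ~8 cells per
  group; groups that small are rejected outright rather than handled
  exactly.
- `score_ratio` with the default shift makes ratios comparable within a
  call but not across calls with different score ranges; use a fixed
  `shift` for cross-dataset comparisons.
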