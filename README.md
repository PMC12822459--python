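# neotls

Tools for analysing the tumor microenvironment around **tertiary lymphoid
structures (TLS)** in single-cell and binned spatial transcriptomics of
neoadjuvant-chemoradiotherapy (neoCRT) cohorts — for computational
biologists who need the bespoke steps of such a study as tested, reusable
functions rather than one-off notebook code.

## What it does

The package implements the full pipeline around TLS biology:

- **QC** (`mad_filter`, `lognormalize`) — cells are removed when
  mitochondrial fraction exceeds `median + 5·MAD` (one-sided) or when
  UMI total or detected-gene count deviates from the median by more than
  `3·MAD` (two-sided). MAD is the raw median absolute deviation, no
  consistency constant. Normalization is `ln(1 + c/total · 10⁴)`.
- **Signature scoring** (`module_score`, `summed_score`) — a module score
  is the mean signature expression minus the mean over expression-matched
  control genes drawn from 25 abundance bins (100 controls per signature
  gene); a summed score is the plain total, used for spatial bins.
- **Differential expression** (`wilcoxon_de`) — two-sided Wilcoxon
  rank-sum per gene, Benjamini–Hochberg adjustment; significant when
  `log2FC > 0.5` and `padj < 0.05`.
- **Derived signatures** — `derive_treatment_signature` keeps the
  published TLS genes that change significantly pre→post treatment;
  `top_ratio_markers` ranks significant DEGs by log2 expression ratio and
  returns the top 20 (the LAMP3⁺ dendritic-cell marker rule).
- **Exhausted-T-cell staging** (`split_bimodal`) — Tex pseudotime is
  bimodal; the split point is the antimode of a Gaussian KDE between the
  two modes; cells at or below it are early-Tex, above it terminal-Tex.
- **TLS calling in spatial data** (`calibrate_thresholds`, `call_tls`) —
  a bin is TLS when its summed T-cell score is in the top 23.9% **and**
  its summed B-cell score is in the top 5.4% (percentiles calibrated from
  matched single-cell T/B fractions, configurable); called bins are
  merged into 8-connected regions (min size 2) and validated by the AUC
  of the summed TLS-signature score.
- **Study statistics** (`pearson`, `two_group_test`, `bh_adjust`,
  `composition_summary`) and an MSI/MSS classifier at the 3.5 score
  cutoff.
- **Synthetic data with ground truth** (`simulate_cohort`,
  `simulate_spatial`) — negative-binomial cohorts with subtype markers,
  responder/non-responder × pre/post composition shifts, a two-component
  Tex pseudotime mixture, and spatial grids with planted TLS discs.

## Worked example

```python
import neotls as nt

cfg = nt.default_spatial_config(seed=3)
gene_ids = cfg.gene_ids()
t_sig = nt.GeneSignature("T-cell", tuple(gene_ids[500:520]))
b_sig = nt.GeneSignature("B-cell", tuple(gene_ids[600:620]))

raw, truth = nt.simulate_spatial(cfg, t_sig, b_sig)
sample = nt.SpatialSample(nt.lognormalize(raw.matrix), raw.coords)
tls_sig = nt.GeneSignature("TLS", t_sig.genes + b_sig.genes)
result = nt.call_tls(sample, t_sig, b_sig, tls_sig=tls_sig)
```

Running `python examples/04_tls_spatial.py` (the script version of the
above) prints:

```
grid 60x60: 159 TLS bins in 3 regions (sizes [29, 49, 81])
TLS proportion 0.0442 vs planted 0.0442
cutoffs: T >= 40.42 (top 23.9%), B >= 38.53 (top 5.4%)
TLS signature AUC vs calls: 1.000
per-bin recovery of the planted discs: F1 = 1.000
```

The three planted discs are recovered as exactly three connected
regions; the TLS proportion (fraction of all bins inside a retained
region) matches the planted fraction, and the summed TLS-signature score
separates TLS from non-TLS bins perfectly (AUC 1.0). The other scripts
in `examples/` walk through QC, signature scoring and DE, Tex staging,
and cohort statistics the same way.

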