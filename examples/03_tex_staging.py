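"""Split exhausted T cells into early and terminal stages from pseudotime.

The pseudotime density of exhausted T cells (Tex) is bimodal; the split
point is the antimode of a Gaussian KDE between the two modes.  Stage
proportions per group x timepoint reveal treatment-driven shifts.
"""

import neotls as nt

cfg = nt.default_cohort_config(seed=2, n_cells=6000, n_genes=400)
matrix, cells, truth = nt.simulate_cohort(cfg)

tex = cells[cells["subtype"] == "Tex"].copy()
assignment = nt.split_bimodal(tex["pseudotime"])
print(f"{len(tex)} Tex cells; KDE peaks at "
      f"{assignment.peak_locations[0]:.1f} and {assignment.peak_locations[1]:.1f}, "
      f"split at pseudotime {assignment.split_point:.2f}")

agree = (assignment.stages == truth.tex_stage_labels).mean()
print(f"agreement with the generating mixture component: {agree:.1%}")

tex["stage"] = assignment.stages
table = nt.proportion_table(tex, subtype_col="stage")
early = table[table["stage"] == "early"]
for _, row in early.iterrows():
    print(f"  {row['group']:>2} {row['timepoint']:>4}: "
          f"early-Tex fraction {row['fraction']:.2f} (n={row['count']})")
# Responders shift from ~0.3 early-Tex before treatment to ~0.6 after;
# non-responders stay near 0.3 — the planted treatment effect.
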