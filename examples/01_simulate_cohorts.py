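"""Simulate a multi-cohort RNA-seq study with a built-in pair-bond signature.

Eight cohorts (opposite-/same-sex pairing x paired/separated x short/long
timepoint), negative-binomial counts, a sparse true opposite-vs-same-sex
effect whose cross-timepoint correlation and long-term erosion are tunable.
"""

import sigerode as sg

design = sg.SimDesign(
    n_genes=2000,
    n_per_cohort=6,
    de_fraction=0.15,       # fraction of genes carrying a true pairing effect
    effect_sd=0.8,          # scale of true log2 fold changes
    concordance_kappa=0.9,  # correlation of effects between timepoints
    erosion_fraction=0.9,   # effects silenced in the separated long-term contrast
    seed=11,
)
effects = sg.make_true_effects(design)
counts, samples = sg.simulate_counts(effects, design)

print(f"counts matrix: {counts.counts.shape[0]} genes x {counts.counts.shape[1]} samples")
print(f"cohorts: {sorted(samples['cohort'].unique())}")
print(f"true effect genes: {int(effects['is_de'].sum())} of {design.n_genes}")
eroded = int((effects["is_de"] & (effects["effect_sep_long"] == 0)).sum())
print(f"effects erased in the separated long-term contrast: {eroded}")
print(f"median library size: {counts.library_sizes.median():,.0f} reads")
# The erased effects are what the downstream erosion analysis must recover
# from the counts alone.
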