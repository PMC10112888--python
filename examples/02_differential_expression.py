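"""Filter, normalize and contrast: the stand-in differential-expression stage.

Genes under 10 total counts are removed, expression is TPM-normalized, and
each opposite- vs same-sex contrast is a Welch t-test on log2(TPM + 1).
DEGs use the study thresholds: |log2FC| > 0.30 and p < 0.05 (strict).
"""

import sigerode as sg

design = sg.SimDesign(n_genes=2000, n_per_cohort=6, seed=11)
counts, samples = sg.simulate_counts(sg.make_true_effects(design), design)

counts = sg.filter_low_counts(counts, min_total=10)
print(f"genes passing the low-count filter: {counts.n_genes}")

contrast = sg.Contrast("paired_short", ["OS_paired_short"], ["SS_paired_short"])
table = sg.differential_expression(counts, samples, contrast)
up, down = sg.call_degs(table)
print(f"paired short-term contrast: {len(up)} up- and {len(down)} down-regulated genes")

# pooling both paired timepoints gives the better-powered combined signature
pooled = sg.pool_cohorts(samples, ["OS_paired_short", "OS_paired_long"], "combined_pair_bond_OS")
pooled = sg.pool_cohorts(pooled, ["SS_paired_short", "SS_paired_long"], "combined_pair_bond_SS")
pb = sg.differential_expression(
    counts, pooled,
    sg.Contrast("combined_pair_bond", ["combined_pair_bond_OS"], ["combined_pair_bond_SS"]),
)
up_pb, down_pb = sg.call_degs(pb)
print(f"combined pair-bond signature: {len(up_pb)} up, {len(down_pb)} down")
# More animals per side -> smaller p-values -> more genes pass the strict cuts.
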