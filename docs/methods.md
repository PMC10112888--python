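# Methods

## Scope and data model

`sigerode` analyzes gene-level contrasts between an experimental and a
reference group — in the motivating design, opposite-sex (OS) vs same-sex
(SS) paired male voles — across cohorts defined by pairing type, separation
condition and timepoint. The in-memory objects are a `CountsMatrix` (genes ×
samples integer counts with per-gene lengths), a sample table (animal,
pairing, condition, timepoint, cohort label = the triple), DE tables
(`gene_id, base_mean, log2_fold_change, pvalue`), ranked lists, RRHO maps,
and gene sets bound to a universe size. All statistics downstream of the DE
tables depend only on the tables, so DESeq2 (or any other) results can be
substituted for the built-in contrast via the dialect reader.

## The differential-expression stand-in

The package's contribution is downstream of differential expression, so the
DE stage is intentionally minimal and fully specified:

- **Low-count filter**: keep genes with total count ≥ 10 across all samples
  (the boundary count of exactly 10 is kept). Idempotent; an empty result is
  an error.
- **TPM**: rate_g = count_g / length_kb_g, scaled so each sample sums to
  10⁶. An all-zero sample yields an all-zero column with a warning.
- **Contrast**: two-sided Welch t-test per gene on log2(TPM + 1), OS side
  minus SS side, Satterthwaite degrees of freedom. Degenerate rows (both
  group variances zero) get p = 1 when means agree and the p-floor when they
  differ. All p-values are floored at 1e-300 so −log10(p) is finite.
- **Pooling**: the two paired timepoints are relabeled into one combined
  pair-bond comparison per pairing type; pooling OS with SS cohorts into one
  side is refused.
- **DEG thresholds**: strictly |log2FC| > 0.30 and p < 0.05, following the
  nominal-threshold convention for detecting pathway-level shifts rather
  than single-gene candidates.

No dispersion modelling, shrinkage, covariate adjustment or multiplicity
correction is attempted — that is deliberate: under the null the Welch p
distribution on the simulated data is flat (KS distance ≈ 0.01 at 12,000
genes, checked in the tests), which is all the downstream ranking needs.

## RRHO

Ranking: r_g = −log10(p) · sign(log2FC), sorted descending, with ties broken
by |log2FC| descending then gene id lexicographic so orderings are identical
across platforms. Maps: prefix sizes grow by `step` (default 100, matching
common practice) up to N, the final partial prefix included; overlaps k_ij
come from a cumulative 2-D histogram of rank positions; each cell is the
upper hypergeometric tail computed via the survival function, never
1 − CDF. Cells whose tail underflows double precision are recomputed by
log-space summation of the pmf, so −log10(p) is always finite (values can
legitimately exceed the display cap). Display: the conventional capped scale
clips −log10(p) into [1, 300]; the log-odds view reports the natural-log
odds ratio of each cell's 2×2 table (k, i−k, j−k, N−i−j+k) with a
Haldane–Anscombe 0.5 correction applied to all four cells whenever any is
zero, clipped to ±6.

Two map modes exist. `described` (default) is the single-statistic
algorithm above — one matrix of top-prefix overlaps. `stratified` computes
the down-regulated block from list tails and the discordant blocks from one
head and one tail, in the style of stratified RRHO implementations; the
block boundary is each list's sign-change index. The `boundary` parameter
(0.02) is recorded in configs for provenance but has no effect on the
described algorithm. Quadrant gene lists use the sign-of-rank-value
partition — UU = {r₁ > 0 and r₂ > 0} etc., genes with r = 0 in either list
assigned to none — not peak-pixel extraction; this is the "all transcripts
in each quadrant" convention.

## Set statistics and erosion

Overlap tests are exact one-sided hypergeometric upper tails on the shared
filtered universe (the whole post-filter gene set by default), reported with
the overlap size and fold enrichment k·N/(|a|·|b|). No χ² statistic is
emitted: an exact test has none. Eroded genes are the set difference of the
matching concordant quadrants, eroded_Q = (PB∩ST)_Q \ (PB∩LT)_Q; the
implementation also reports the retained intersection and an upset-style
size table. Inverted genes filter the separation-RRHO UU quadrant by
pair-bond log2FC < −0.30 and the DD quadrant by > +0.30 (strict), i.e.
genes whose separation-stable regulation is opposite to their bonded state.
The neuronal-enrichment intersection takes translatome-enriched DEGs ∩ the
union of externally supplied co-expression module gene sets (module
detection is out of scope; modules arrive as gene-set files). Profile
clustering z-scores each gene's fold-change vector across contrasts (sample
sd; rows with exactly constant values map to zeros and are set aside in a
dedicated cluster 0), then applies complete-linkage agglomeration on
1 − Pearson distance with the tree cut at k clusters (k is a user choice;
3 is the conventional starting point).

## Permutation nulls

**Cohort shuffle.** The observed statistic is the Spearman ρ (average-rank
ties, two-sided t-approximation p) between the fold-change vectors of a
fixed and a shuffled contrast. Each iteration permutes cohort labels
uniformly at random across the animal pool, preserving cohort sizes,
re-estimates the shuffled contrast and records the null ρ. Both the plain
empirical p (#{null ≥ observed}/n_iter, so p = 0 is possible) and the
add-one smoothed (k+1)/(n+1) are reported.

The pool choice matters. With `pool="all"`, null draws can place the fixed
contrast's own animals — or effect-carrying OS animals generally — into the
shuffled groups; because Spearman ρ is invariant to monotone scaling, a
partially reassembled OS-vs-SS split tracks the observed ρ, so the null has
a heavy right tail and the test is conservative regardless of effect size.
With `pool="long_term_only"` and a short-timepoint fixed contrast, the fixed
animals never enter the shuffle and observed and null are exchangeable under
the null hypothesis, giving a calibrated test (type-I rate ≈ 5% at α = 0.05
in the acceptance suite). The pipeline therefore uses the narrow pool for
the short- vs long-term paired concordance permutation and the configured
pool (default `all`) for the pair-bond vs separation permutations, whose
shuffled cohorts live at the short timepoint and cannot be permuted by a
long-timepoint-only shuffle. Degenerate shuffles that would empty a contrast
side are redrawn and counted.

**Rank shuffle.** List 1's gene order is permuted uniformly (rank values
keep their positions) and the RRHO map is rebuilt against the intact list 2;
genuine concordance collapses to near-baseline map maxima.

**Quartile exclusion.** Q1 and Q3 of the reference fold-change distribution
are linear-interpolation quantiles; genes strictly outside [Q1, Q3] are
retained and ρ recomputed. On concordant synthetic data the filtered ρ
exceeds the unfiltered one in ≥ 90% of seeds — concordance is carried by the
genes with larger expression differences.

## The synthetic-data generator

No generative model of the real data exists to copy, so the generator uses
the simplest mechanisms that reproduce the qualitative structure the
analysis targets:

- **Effects**: DE genes ~ Bernoulli(`de_fraction`); base effect
  β_g ~ N(0, `effect_sd`²) shared by both short-timepoint contrasts; the
  paired-long effect is κ·β_g + √(1−κ²)·ε_g with ε_g ~ N(0, `effect_sd`²),
  so the two paired-effect columns have correlation exactly κ; the
  separated-long effect is zeroed with probability `erosion_fraction`, else
  β_g. Non-DE genes are exactly zero everywhere.
- **Counts**: baseline log2 abundance b_g ~ N(mu, sd); expected relative
  abundance ∝ gene_length · 2^(b_g + effect·[OS]); per-sample means are the
  library size times the normalized abundance; counts are NB with
  Var = m + α·m².
- **Reproducibility**: one RNG stream per draw site, derived from the master
  seed by fixed labels, so adding draw sites never perturbs existing ones;
  identical design + seed gives bit-identical output.

Defaults, chosen once: 12,000 genes (the scale of a filtered brain
transcriptome), 8 cohorts × 6 animals (the study's per-cohort range is
5–8), de_fraction 0.15, effect_sd 0.8 (a sparse, moderate signature),
baseline log2 mean μ = 3, σ = 1.5 (a few orders of magnitude of dynamic
range), NB dispersion α = 0.05 (inbred-colony-like biological variability),
gene lengths log-uniform on [500, 10,000] bp (so TPM ≠ CPM), library sizes
uniform on [5, 20] million reads. κ defaults to 0.9; erosion defaults to 0
and is raised to 0.9 in the study-emulation configurations. The
acceptance-scale emulation uses 8 animals per cohort, where the calibrated
permutation separates observed concordance from every shuffled draw across
seeds.

What the generator does **not** emulate: read-level artifacts, batch or
parentage structure, within-pair correlation, covariate confounding,
gene–gene correlation beyond the shared library-size constraint, or any
absolute effect-size distribution of real bond-associated genes (only the
correlation structure is targeted). Passing tests therefore demonstrate
that the machinery recovers planted concordance/erosion structure from
NB-noisy counts — not that any particular biological effect size is
detectable in real tissue.

## Numerical choices

- p-floor 1e-300 before ranking; hypergeometric tails below the smallest
  subnormal are floored there in the scalar API while map cells carry exact
  −log10 values from log-space summation.
- Ranking tie-break: |log2FC| descending, then gene id lexicographic.
- Exactly-constant profile rows are detected on raw values (max == min),
  not on the float-noisy standard deviation.
- Quantiles are linear-interpolation (the numpy default) with strict
  exclusion of [Q1, Q3].
- Complete-linkage clustering is deterministic for a fixed row order; ties
  in merge distances are resolved by the linkage implementation's stable
  ordering (test fixtures use continuous data, where ties have measure
  zero).
- Empirical permutation p-values are reported both plain and smoothed.

## Limitations

- The Welch stand-in is not a replacement for a count-model DE analysis on
  real data; use DESeq2 tables as input for real studies. Cohort shuffling
  needs raw counts and is unavailable in tables-only mode.
- The `pool="all"` cohort shuffle is conservative by construction (see
  above); its p-values should be read as upper bounds.
- Multi-way (> 2 set) exact intersection p-values, GO/pathway enrichment,
  and co-expression module detection are out of scope; modules and
  annotation results are inputs, not outputs.
- The stratified RRHO mode is a convenience view; all quantitative results
  in the pipeline use the described single-statistic algorithm.
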