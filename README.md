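# sigerode

Concordance and erosion analysis of differential-expression signatures,
built around rank–rank hypergeometric overlap (RRHO).

## The problem

Some behavioral states — pair bonding in socially monogamous voles is the
motivating case — are accompanied by a broad, stable shift in brain gene
expression. Two questions follow for anyone comparing such signatures across
conditions or timepoints:

1. **Concordance** — is the genome-wide pattern of up-/down-regulation the
   same in two independent contrasts (e.g. opposite- vs same-sex pairing at
   two and at six weeks)?
2. **Erosion** — after a perturbation (e.g. partner separation), which genes
   lose their signature regulation, and on what timescale?

`sigerode` implements the full analysis chain for these questions on
gene-level count matrices or precomputed differential-expression tables, plus
a negative-binomial multi-cohort simulator so every stage is testable without
any external data.

## The method

For each contrast (opposite-sex experimental vs same-sex reference), genes
are scored by the signed significance rank value

```
r_g = −log10(p_g) · sign(log2FC_g)
```

and sorted descending, so the most significantly upregulated genes head the
list. Two ranked lists are compared threshold-free: for prefix sizes
*i, j ∈ {s, 2s, …, N}* (step *s*, universe *N*), each cell of the RRHO map
holds

```
−log10 P(X ≥ k_ij),   X ~ Hypergeometric(N, i, j),   k_ij = |top_i(L1) ∩ top_j(L2)|
```

Concordant regulation concentrates signal in the UU (up/up, bottom-left) and
DD (down/down, top-right) quadrants, defined by the sign of the rank value in
each list. Downstream of the maps:

- **DEG calling** at strict thresholds |log2FC| > 0.30, p < 0.05;
- **exact overlap tests** (hypergeometric upper tail with fold enrichment)
  between any two gene sets on the shared universe;
- **eroded genes**: `(PB ∩ ST)_Q \ (PB ∩ LT)_Q` for Q ∈ {UU, DD} — genes
  concordant between the pair-bond signature and short-term separation that
  are no longer concordant after long-term separation;
- **inverted genes**: separation-concordant genes whose pair-bond fold change
  has the opposite sign (beyond ±0.30);
- **permutation nulls**: cohort-identity shuffling with re-estimated fold
  changes for the cross-comparison Spearman ρ, and rank shuffling for RRHO;
- **quartile exclusion**: ρ recomputed after dropping genes inside the middle
  two quartiles of the reference fold-change distribution;
- **profile clustering**: per-gene z-scored fold-change vectors, 1 − Pearson
  distance, complete linkage.

The differential-expression stage itself is a deliberately simple stand-in
(low-count filter, TPM, Welch t on log2(TPM+1)); externally produced DESeq2
result tables are accepted as input through a dialect reader.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/04_erosion_analysis.py` (2,000 simulated genes, strong
concordance, 90% erosion) prints:

```
quadrant  pb_short_term  pb_long_term  intersection  eroded    overlap_p  fold_enrichment
      UU            451           418           235     216 2.816602e-67         2.493131
      DD            700           603           377     323 4.659753e-63         1.786307
UU: |eroded| = 216, short/long overlap fold-enrichment = 2.49 (p = 2.82e-67)
DD: |eroded| = 323, short/long overlap fold-enrichment = 1.79 (p = 4.66e-63)
```

Reading: of the 451 genes concordantly upregulated between the pair-bond
signature and short-term separation, only 235 are still concordant after
long-term separation; the 216 others are the eroded UU set. The overlap of
the short- and long-term concordant sets is still far larger than chance
(fold enrichment 2.49, hypergeometric p ≈ 3e-67), i.e. the signature decays
but does not vanish. `examples/05_permutation_nulls.py` shows the matching
controls — an observed cross-timepoint ρ of 0.278 that beats nearly all
cohort-shuffled draws, an RRHO maximum of 90.9 that collapses to 2.0 under
rank shuffling, and ρ rising to 0.484 when the middle-quartile genes are
excluded.

A thin CLI mirrors the library (`sigerode simulate | de | rrho | quadrants |
erode | invert | permute-cohorts | permute-ranks | cluster | run`); `run`
executes the whole pipeline from a YAML config and writes a manifest of
config hash and per-file checksums, so identical config + seed reproduces a
run byte-for-byte.

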