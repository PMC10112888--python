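import numpy as np
import pandas as pd
import pytest

import sigerode as sg

PAIRED_COHORTS = tuple(c for c in sg.FULL_DESIGN if c.condition == "paired")

PS = sg.Contrast("paired_short", ["OS_paired_short"], ["SS_paired_short"])
PL = sg.Contrast("paired_long", ["OS_paired_long"], ["SS_paired_long"])
PB = sg.Contrast("combined_pair_bond", ["combined_pair_bond_OS"], ["combined_pair_bond_SS"])
SS_ = sg.Contrast("sep_short", ["OS_separated_short"], ["SS_separated_short"])
SL = sg.Contrast("sep_long", ["OS_separated_long"], ["SS_separated_long"])


def pool_pair_bond(samples: pd.DataFrame) -> pd.DataFrame:
    pooled = sg.pool_cohorts(
        samples, ["OS_paired_short", "OS_paired_long"], "combined_pair_bond_OS"
    )
    return sg.pool_cohorts(
        pooled, ["SS_paired_short", "SS_paired_long"], "combined_pair_bond_SS"
    )


def make_counts(matrix, lengths=None, genes=None, samples=None) -> sg.CountsMatrix:
    """Small hand-built counts matrix for unit tests."""
    matrix = np.asarray(matrix)
    n_genes, n_samples = matrix.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{j}" for j in range(n_samples)]
    lengths = lengths if lengths is not None else [1000] * n_genes
    return sg.CountsMatrix(
        pd.DataFrame(matrix, index=pd.Index(genes, name="gene_id"), columns=samples),
        pd.Series(lengths, index=pd.Index(genes, name="gene_id"), name="length_bp"),
    )


def de_table(gene_ids, lfc, pvalue, contrast="toy", base_mean=None) -> pd.DataFrame:
    t = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "base_mean": base_mean if base_mean is not None else np.ones(len(lfc)),
            "log2_fold_change": np.asarray(lfc, dtype=float),
            "pvalue": np.asarray(pvalue, dtype=float),
        }
    )
    t.attrs["contrast"] = contrast
    return t


@pytest.fixture(scope="session")
def default_sim():
    """Full default design (12,000 genes, 8 cohorts x 6 animals), seed 11."""
    design = sg.SimDesign(seed=11)
    effects = sg.make_true_effects(design)
    counts, samples = sg.simulate_counts(effects, design)
    return design, effects, counts, samples


@pytest.fixture(scope="session")
def small_paired_sim():
    """Four paired cohorts, 600 genes — quick concordance checks."""
    design = sg.SimDesign(
        n_genes=600, cohorts=PAIRED_COHORTS, n_per_cohort=4, concordance_kappa=1.0, seed=5
    )
    effects = sg.make_true_effects(design)
    counts, samples = sg.simulate_counts(effects, design)
    return design, effects, counts, samples
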