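"""Synthetic multi-cohort RNA-seq count generator.

Emulates the study design used throughout this package: male voles housed in
opposite-sex (OS) or same-sex (SS) pairs, either remaining paired or separated
from their partner, sampled at a short- and a long-term timepoint — eight
cohorts in all.  A sparse set of genes carries a true OS-vs-SS ("pair bond")
log2 effect; the correlation of that effect between the short- and long-term
paired contrasts is a tunable concordance parameter, and a configurable
fraction of effect genes is silenced ("eroded") in the separated long-term
contrast.  Counts are negative-binomial with gene-length- and
library-size-dependent means, so TPM and CPM genuinely differ downstream.

The generator is the test bed for every downstream stage; nothing in it is
fit to real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "SimDesign",
    "FULL_DESIGN",
    "make_true_effects",
    "simulate_counts",
]

PAIRINGS = ("OS", "SS")
CONDITIONS = ("paired", "separated")
TIMEPOINTS = ("short", "long")

# Fixed per-operation RNG stream labels: adding a new draw site never
# perturbs existing streams for a given master seed.
_STREAM_EFFECTS = 101
_STREAM_LENGTHS = 102
_STREAM_BASELINE = 103
_STREAM_LIBSIZE = 104
_STREAM_COUNTS = 105
_STREAM_COVARIATES = 106


@dataclass(frozen=True)
class Cohort:
    """One cell of the pairing x condition x timepoint design."""

    pairing: str
    condition: str
    timepoint: str

    def __post_init__(self) -> None:
        if self.pairing not in PAIRINGS:
            raise ValueError(f"pairing must be one of {PAIRINGS}, got {self.pairing!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")

    @property
    def label(self) -> str:
        return f"{self.pairing}_{self.condition}_{self.timepoint}"

    @property
    def effect_column(self) -> str:
        """Which true-effect column applies to this cohort's OS samples."""
        return f"effect_{'paired' if self.condition == 'paired' else 'sep'}_{self.timepoint}"


FULL_DESIGN: tuple[Cohort, ...] = tuple(
    Cohort(p, c, t) for p in PAIRINGS for c in CONDITIONS for t in TIMEPOINTS
)


@dataclass(frozen=True)
class SimDesign:
    """Parameters of the synthetic study.

    Defaults emulate the full eight-cohort design: a ~12,000-gene universe,
    six animals per cohort, a sparse pair-bond effect (15% of genes,
    log2 effects ~ Normal(0, 0.8)), strong cross-timepoint concordance, and
    no erosion unless requested.
    """

    n_genes: int = 12_000
    cohorts: tuple[Cohort, ...] = FULL_DESIGN
    n_per_cohort: int = 6
    baseline_log2_mean_mu: float = 3.0
    baseline_log2_mean_sd: float = 1.5
    nb_dispersion: float = 0.05
    de_fraction: float = 0.15
    effect_sd: float = 0.8
    concordance_kappa: float = 0.9
    erosion_fraction: float = 0.0
    library_size_range: tuple[float, float] = (5e6, 2e7)
    gene_length_range: tuple[float, float] = (500.0, 10_000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be a positive integer")
        if not self.cohorts:
            raise ValueError("at least one cohort is required")
        if len(set(c.label for c in self.cohorts)) != len(self.cohorts):
            raise ValueError("cohorts must be unique")
        if self.n_per_cohort < 1:
            raise ValueError("n_per_cohort must be a positive integer")
        for name in ("de_fraction", "concordance_kappa", "erosion_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("baseline_log2_mean_sd", "nb_dispersion", "effect_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive with min <= max")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_range must be positive with min <= max")

    @property
    def gene_ids(self) -> pd.Index:
        width = max(5, len(str(self.n_genes)))
        return pd.Index([f"g{i:0{width}d}" for i in range(self.n_genes)], name="gene_id")

    def with_(self, **kwargs) -> "SimDesign":
        return replace(self, **kwargs)


def _rng(design: SimDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(design.seed), stream)))


def make_true_effects(design: SimDesign) -> pd.DataFrame:
    """Draw the true per-gene log2 OS-vs-SS effects for each contrast.

    DE genes are Bernoulli(de_fraction).  A DE gene g has base effect
    beta_g ~ Normal(0, effect_sd) shared by the paired-short and
    separated-short contrasts; the paired-long effect is
    kappa*beta_g + sqrt(1-kappa^2)*eps_g (eps_g ~ Normal(0, effect_sd)) so the
    two paired-contrast effect columns have correlation kappa; the
    separated-long effect is zeroed with probability erosion_fraction and
    beta_g otherwise.  Non-DE genes carry exactly zero in all four columns.
    """
    rng = _rng(design, _STREAM_EFFECTS)
    n = design.n_genes
    is_de = rng.random(n) < design.de_fraction
    beta = rng.normal(0.0, design.effect_sd, size=n)
    eps = rng.normal(0.0, design.effect_sd, size=n)
    eroded = rng.random(n) < design.erosion_fraction

    k = design.concordance_kappa
    effects = pd.DataFrame(
        {
            "is_de": is_de,
            "effect_paired_short": np.where(is_de, beta, 0.0),
            "effect_paired_long": np.where(
                is_de, k * beta + np.sqrt(max(0.0, 1.0 - k * k)) * eps, 0.0
            ),
            "effect_sep_short": np.where(is_de, beta, 0.0),
            "effect_sep_long": np.where(is_de & ~eroded, beta, 0.0),
        },
        index=design.gene_ids,
    )
    return effects


@dataclass
class CountsMatrix:
    """Gene x sample integer counts with per-gene lengths (bp)."""

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in counts matrix: {dups[:5]}")
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                raise ValueError("every gene needs a length")
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0].tolist()
            raise ValueError(f"non-positive gene length for: {bad[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def subset_genes(self, genes: Iterable[str]) -> "CountsMatrix":
        idx = self.counts.index.intersection(pd.Index(genes), sort=False)
        return CountsMatrix(self.counts.loc[idx], self.lengths.loc[idx])


def _sample_table(design: SimDesign) -> pd.DataFrame:
    rng = _rng(design, _STREAM_COVARIATES)
    rows = []
    animal = 0
    for cohort in design.cohorts:
        for i in range(design.n_per_cohort):
            rows.append(
                {
                    "sample_id": f"{cohort.label}_{i + 1}",
                    "animal_id": f"A{animal:03d}",
                    "pairing": cohort.pairing,
                    "condition": cohort.condition,
                    "timepoint": cohort.timepoint,
                    "cohort": cohort.label,
                    "parent_code": f"P{rng.integers(1, 13):02d}",
                    "age_at_pairing": int(rng.integers(60, 169)),
                }
            )
            animal += 1
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(
    effects: pd.DataFrame, design: SimDesign
) -> tuple[CountsMatrix, pd.DataFrame]:
    """Simulate NB counts for every sample of the design.

    For gene g in cohort c the expected relative abundance is proportional to
    gene_length_g * 2^(b_g + effect_{g,c} * [pairing == OS]) with baseline
    b_g ~ Normal(mu, sd); expected counts are the sample's library size times
    the normalized abundance, and observed counts are NB(mean, alpha) with
    Var = mean + alpha * mean^2.  Deterministic given the design seed.
    """
    if len(effects) != design.n_genes or not effects.index.equals(design.gene_ids):
        raise ValueError("effects were not generated from this design")

    len_rng = _rng(design, _STREAM_LENGTHS)
    lo, hi = design.gene_length_range
    lengths = pd.Series(
        np.exp(len_rng.uniform(np.log(lo), np.log(hi), size=design.n_genes)),
        index=design.gene_ids,
        name="length_bp",
    ).round().astype(int)

    base_rng = _rng(design, _STREAM_BASELINE)
    b = base_rng.normal(
        design.baseline_log2_mean_mu, design.baseline_log2_mean_sd, size=design.n_genes
    )

    samples = _sample_table(design)
    n_samples = len(samples)

    lib_rng = _rng(design, _STREAM_LIBSIZE)
    lib_lo, lib_hi = design.library_size_range
    lib_sizes = lib_rng.uniform(lib_lo, lib_hi, size=n_samples)

    count_rng = _rng(design, _STREAM_COUNTS)
    alpha = np.broadcast_to(np.asarray(design.nb_dispersion, dtype=float), (design.n_genes,))
    if (alpha <= 0).any():
        raise ValueError("nb_dispersion must be strictly positive")

    # Per-cohort relative abundance profiles (shared by all its samples).
    profiles: dict[str, np.ndarray] = {}
    for cohort in design.cohorts:
        eff = effects[cohort.effect_column].to_numpy() if cohort.pairing == "OS" else 0.0
        w = lengths.to_numpy() * np.exp2(b + eff)
        profiles[cohort.label] = w / w.sum()

    counts = np.empty((design.n_genes, n_samples), dtype=np.int64)
    for j, (sid, row) in enumerate(samples.iterrows()):
        mean = lib_sizes[j] * profiles[row["cohort"]]
        nb_n = 1.0 / alpha
        nb_p = nb_n / (nb_n + mean)
        counts[:, j] = count_rng.negative_binomial(nb_n, nb_p)

    cm = CountsMatrix(
        pd.DataFrame(counts, index=design.gene_ids, columns=samples.index.copy()),
        lengths,
    )
    samples = samples.copy()
    samples["target_library_size"] = lib_sizes.round().astype(int)
    return cm, samples
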