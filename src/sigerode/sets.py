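"""Gene-set algebra and overlap statistics for signature comparisons.

Covers the overlap tests between DEG/quadrant lists (exact hypergeometric,
reported with fold enrichment), the eroded-gene construction (concordant with
the pair-bond signature after short- but not long-term separation), the
inverted-gene filter, the neuronal-enrichment intersection (DEGs with
externally supplied co-expression module gene sets), and the scaled
fold-change profile clustering used for the contrast heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .de import LFC_THRESHOLD
from .rrho import QuadrantPartition, hypergeom_overlap_p

__all__ = [
    "GeneSet",
    "OverlapStats",
    "ErosionResult",
    "overlap_test",
    "eroded_genes",
    "inverted_genes",
    "intersect_enriched",
    "scale_effect_profiles",
    "cluster_profiles",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set within a fixed universe of size ``universe_size``."""

    name: str
    genes: frozenset
    universe_size: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if self.universe_size < len(self.genes):
            raise ValueError(
                f"gene set {self.name!r} ({len(self.genes)}) exceeds its universe "
                f"({self.universe_size})"
            )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class OverlapStats:
    overlap: int
    fold_enrichment: float
    pvalue: float


def overlap_test(a: GeneSet, b: GeneSet) -> OverlapStats:
    """Exact one-sided overlap test of two gene sets on a shared universe.

    p is the upper tail of Hypergeometric(N, |a|, |b|) at the observed
    overlap; fold enrichment is observed / expected-under-independence.
    """
    if a.universe_size != b.universe_size:
        raise ValueError(
            f"mismatched universes: {a.name!r} N={a.universe_size} vs "
            f"{b.name!r} N={b.universe_size}"
        )
    N = a.universe_size
    k = len(a.genes & b.genes)
    expected = len(a) * len(b) / N if len(a) and len(b) else 0.0
    fold = k / expected if expected > 0 else float("nan")
    p = hypergeom_overlap_p(k, len(a), len(b), N)
    return OverlapStats(overlap=k, fold_enrichment=fold, pvalue=p)


@dataclass
class ErosionResult:
    """Per-quadrant concordant and eroded gene sets with overlap statistics.

    For each concordant quadrant Q in {UU, DD}: ``pb_st[Q]`` is the set of
    genes concordant between the pair-bond signature and short-term
    separation, ``pb_lt[Q]`` the same against long-term separation, and
    ``eroded[Q] = pb_st[Q] - pb_lt[Q]`` — genes whose bond-associated
    regulation is gone after prolonged separation.
    """

    pb_st: dict
    pb_lt: dict
    eroded: dict
    retained: dict
    overlap_stats: dict
    universe_size: int

    def intersection_table(self) -> pd.DataFrame:
        """Upset-style table of set and intersection sizes per quadrant."""
        rows = []
        for q in ("UU", "DD"):
            rows.append(
                {
                    "quadrant": q,
                    "pb_short_term": len(self.pb_st[q]),
                    "pb_long_term": len(self.pb_lt[q]),
                    "intersection": len(self.pb_st[q] & self.pb_lt[q]),
                    "eroded": len(self.eroded[q]),
                    "overlap_p": self.overlap_stats[q].pvalue,
                    "fold_enrichment": self.overlap_stats[q].fold_enrichment,
                }
            )
        return pd.DataFrame(rows)


def eroded_genes(
    pb_vs_st: QuadrantPartition,
    pb_vs_lt: QuadrantPartition,
    universe_size: int | None = None,
) -> ErosionResult:
    """Genes present in the pair-bond/short-term concordant quadrants but
    absent from the matching pair-bond/long-term quadrants.

    Quadrants are matched UU with UU and DD with DD; each pairwise
    intersection additionally gets an exact overlap test on the shared
    universe.
    """
    if universe_size is None:
        universe_size = pb_vs_st.universe_size
    if pb_vs_st.universe_size != pb_vs_lt.universe_size:
        raise ValueError(
            "quadrant partitions disagree on universe size: "
            f"{pb_vs_st.universe_size} vs {pb_vs_lt.universe_size}"
        )
    pb_st, pb_lt, eroded, retained, tests = {}, {}, {}, {}, {}
    for q in ("UU", "DD"):
        st, lt = pb_vs_st[q], pb_vs_lt[q]
        pb_st[q], pb_lt[q] = st, lt
        eroded[q] = st - lt
        retained[q] = st & lt
        tests[q] = overlap_test(
            GeneSet(f"pb_st_{q}", st, universe_size),
            GeneSet(f"pb_lt_{q}", lt, universe_size),
        )
    return ErosionResult(
        pb_st=pb_st,
        pb_lt=pb_lt,
        eroded=eroded,
        retained=retained,
        overlap_stats=tests,
        universe_size=universe_size,
    )


def inverted_genes(
    sep_quadrants: QuadrantPartition,
    pair_bond: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
) -> tuple[set, set]:
    """Separation-concordant genes whose pair-bond regulation is inverted.

    From the short- vs long-term separation RRHO's UU quadrant, keep genes
    with pair-bond LFC strictly below -threshold; from its DD quadrant, keep
    genes with pair-bond LFC strictly above +threshold.  Quadrant genes
    missing from the pair-bond table are dropped with a logged count.
    """
    lfc = pd.Series(
        pair_bond["log2_fold_change"].to_numpy(), index=pair_bond["gene_id"].to_numpy()
    )
    dropped = 0
    out = []
    for quadrant, keep in (("UU", lambda v: v < -lfc_threshold), ("DD", lambda v: v > lfc_threshold)):
        genes = sep_quadrants[quadrant]
        known = [g for g in genes if g in lfc.index]
        dropped += len(genes) - len(known)
        out.append({g for g in known if keep(lfc.loc[g])})
    if dropped:
        logger.info("inverted_genes: dropped %d quadrant genes absent from the DE table", dropped)
    return out[0], out[1]


def intersect_enriched(
    deg_set: GeneSet, module_sets: Sequence[GeneSet]
) -> tuple[GeneSet, dict]:
    """Enriched DEGs restricted to the union of supplied module gene sets.

    Mirrors the neuronal-enrichment construction: translatome-enriched DEGs
    intersected with pulldown-correlated co-expression modules.  Returns the
    intersection and per-module contribution counts.
    """
    if not module_sets:
        raise ValueError("at least one module gene set is required")
    union = frozenset().union(*(m.genes for m in module_sets))
    result = GeneSet(
        name=f"{deg_set.name}_in_modules",
        genes=deg_set.genes & union,
        universe_size=deg_set.universe_size,
    )
    contributions = {m.name: len(deg_set.genes & m.genes) for m in module_sets}
    return result, contributions


def scale_effect_profiles(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-gene z-scored LFC profile across contrasts (genes x contrasts).

    Each row (a gene's LFC vector across the supplied DE tables) is scaled to
    mean 0 and sample sd 1; rows constant across contrasts map to all zeros.
    Tables must share a gene universe.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 contrasts to scale profiles")
    cols = {}
    base_index = None
    for t in tables:
        name = t.attrs.get("contrast", f"contrast_{len(cols)}")
        s = pd.Series(t["log2_fold_change"].to_numpy(), index=t["gene_id"].to_numpy())
        if base_index is None:
            base_index = s.index
        elif not base_index.sort_values().equals(s.index.sort_values()):
            raise ValueError("DE tables do not share a gene universe")
        cols[name] = s.reindex(base_index)
    mat = pd.DataFrame(cols)
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    # a constant LFC vector has no profile shape: map it to exact zeros
    # (detected on the raw values, not the float-noisy sd)
    constant = mat.max(axis=1) == mat.min(axis=1)
    scaled = mat.sub(mu, axis=0).div(sd.where(~constant, np.inf), axis=0)
    scaled[constant] = 0.0
    scaled.index.name = "gene_id"
    return scaled


def cluster_profiles(scaled: pd.DataFrame, k: int) -> pd.Series:
    """Hierarchical clustering of profile rows, one-minus-Pearson distance,
    complete linkage, tree cut at ``k`` clusters.

    Rows with zero variance (undefined correlation) are set aside into a
    dedicated cluster labelled 0 before clustering; the remaining rows get
    labels 1..k.  Deterministic for a fixed row order.
    """
    if scaled.shape[1] < 2:
        raise ValueError("need at least 2 contrasts to cluster")
    values = scaled.to_numpy(dtype=float)
    flat = values.max(axis=1) == values.min(axis=1)
    labels = pd.Series(0, index=scaled.index, name="cluster", dtype=int)
    active = values[~flat]
    if len(active) < k:
        raise ValueError(f"fewer than k={k} clusterable rows ({len(active)})")
    centered = active - active.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1, keepdims=True)
    corr = np.clip((centered / norm) @ (centered / norm).T, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    assign = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels.loc[scaled.index[~flat]] = assign
    return labels
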