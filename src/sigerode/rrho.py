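"""Rank-rank hypergeometric overlap (RRHO) between two DE comparisons.

Genes from each comparison are ranked by the signed significance score
``-log10(pvalue) * sign(log2FC)`` so the most significantly upregulated genes
sit at the top of the list and the most significantly downregulated at the
bottom.  Two ranked lists are then compared threshold-free: prefixes of each
list grow by a fixed step, and each (prefix_i, prefix_j) cell records the
upper-tail hypergeometric p-value of their overlap within the shared gene
universe.  The resulting -log10(p) matrix, displayed with list 1 along the
x-axis and the smallest prefixes at the bottom-left, concentrates signal in
the UU (concordantly up) and DD (concordantly down) quadrants when the two
comparisons agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "RankedList",
    "RRHOMap",
    "QuadrantPartition",
    "rank_genes",
    "hypergeom_overlap_p",
    "build_rrho",
    "extract_quadrants",
    "cap_for_display",
    "log_odds_map",
]

logger = logging.getLogger(__name__)

LOG10 = np.log(10.0)


@dataclass
class RankedList:
    """Genes in descending order of signed significance rank value."""

    genes: np.ndarray
    rank_values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.rank_values = np.asarray(self.rank_values, dtype=float)
        if self.genes.shape != self.rank_values.shape or self.genes.ndim != 1:
            raise ValueError("genes and rank_values must be 1-d and aligned")
        if not np.isfinite(self.rank_values).all():
            raise ValueError("rank values must all be finite")
        if (np.diff(self.rank_values) > 0).any():
            raise ValueError("rank values must be in descending order")
        if len(np.unique(self.genes)) != len(self.genes):
            raise ValueError("each gene may appear only once")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_up(self) -> int:
        """Number of genes with positive rank value (the sign-change index)."""
        return int((self.rank_values > 0).sum())

    def rank_value_series(self) -> pd.Series:
        return pd.Series(self.rank_values, index=self.genes)

    def subset(self, genes: set) -> "RankedList":
        keep = np.isin(self.genes, list(genes))
        return RankedList(self.genes[keep], self.rank_values[keep])

    def shuffled(self, rng: np.random.Generator) -> "RankedList":
        """Same genes, uniformly permuted order; rank values keep positions."""
        perm = rng.permutation(len(self.genes))
        return RankedList(self.genes[perm], np.sort(self.rank_values)[::-1].copy())


def rank_genes(table: pd.DataFrame) -> RankedList:
    """Signed significance ranking of one DE table.

    r_g = -log10(p_g) * sign(LFC_g); p must already be floored to be strictly
    positive.  Ties are broken by |LFC| descending then gene id lexicographic
    so the ordering is deterministic across platforms.
    """
    p = table["pvalue"].to_numpy(dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("pvalues must lie in (0, 1]; floor them upstream")
    lfc = table["log2_fold_change"].to_numpy(dtype=float)
    if not np.isfinite(lfc).all():
        raise ValueError("log2 fold changes must be finite")
    r = -np.log10(p) * np.sign(lfc)
    order = (
        pd.DataFrame(
            {
                "gene_id": table["gene_id"].to_numpy(),
                "rank_value": r,
                "abs_lfc": np.abs(lfc),
            }
        )
        .sort_values(
            ["rank_value", "abs_lfc", "gene_id"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        .reset_index(drop=True)
    )
    return RankedList(order["gene_id"].to_numpy(), order["rank_value"].to_numpy())


def hypergeom_overlap_p(k: int, i: int, j: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, i, j).

    Computed via the survival function (never 1 - CDF); exact zeros from
    floating-point underflow are resolved through log-space summation so the
    result is always strictly positive.
    """
    if not (0 <= k <= min(i, j) <= N) or i > N or j > N:
        raise ValueError(f"inconsistent counts k={k}, i={i}, j={j}, N={N}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, i, j))
    if p == 0.0:
        # rescue underflow via log-space summation; tails below the smallest
        # subnormal are floored so the contract p > 0 always holds
        p = float(np.exp(_log_sf(k, i, j, N)))
        return max(p, np.nextafter(0.0, 1.0))
    return min(p, 1.0)


def _log_sf(k: int, i: int, j: int, N: int) -> float:
    """Natural-log upper tail via logsumexp over the support [k, min(i, j)]."""
    support = np.arange(k, min(i, j) + 1)
    return float(logsumexp(stats.hypergeom.logpmf(support, N, i, j)))


def _neglog10_sf_matrix(k: np.ndarray, i: np.ndarray, j: np.ndarray, N: int) -> np.ndarray:
    """-log10 upper-tail p for a whole grid, with log-space rescue of underflow."""
    with np.errstate(divide="ignore"):
        p = stats.hypergeom.sf(k - 1, N, i, j)
        out = -np.log10(np.minimum(p, 1.0))
    under = ~np.isfinite(out)
    if under.any():
        ii, jj = np.broadcast_arrays(i, j)
        for a, b in zip(*np.nonzero(under)):
            out[a, b] = -_log_sf(int(k[a, b]), int(ii[a, b]), int(jj[a, b]), N) / LOG10
    # k == 0 cells have p = 1 exactly
    out[k == 0] = 0.0
    return out


@dataclass
class RRHOMap:
    """Threshold-grid overlap map between two ranked lists.

    ``overlap`` and ``neglog10_p`` are indexed [i_index, j_index]: axis 0
    walks list 1's prefix sizes, axis 1 list 2's.  ``prefix_sizes`` includes
    the final partial prefix, which equals the full list.
    """

    step: int
    n_genes: int
    prefix_sizes: np.ndarray
    overlap: np.ndarray
    neglog10_p: np.ndarray
    mode: str = "described"
    genes: np.ndarray | None = None
    n_up1: int | None = None
    n_up2: int | None = None

    @property
    def max_signal(self) -> float:
        return float(self.neglog10_p.max())


def _align(list1: RankedList, list2: RankedList) -> tuple[RankedList, RankedList]:
    shared = np.intersect1d(list1.genes, list2.genes)
    if len(shared) < len(list1) or len(shared) < len(list2):
        dropped = (len(list1) - len(shared)) + (len(list2) - len(shared))
        logger.info("build_rrho: dropped %d list entries outside the shared universe", dropped)
        shared_set = set(shared.tolist())
        list1 = list1.subset(shared_set)
        list2 = list2.subset(shared_set)
    if len(list1) == 0:
        raise ValueError("empty shared gene universe")
    return list1, list2


def build_rrho(
    list1: RankedList,
    list2: RankedList,
    step: int = 100,
    mode: str = "described",
) -> RRHOMap:
    """Prefix-overlap hypergeometric map between two ranked lists.

    ``described`` mode (default) is the single-statistic algorithm: for
    prefix sizes i, j in {step, 2*step, ..., N}, the cell holds
    -log10 P(overlap >= |top_i(list1) & top_j(list2)|).  ``stratified`` mode
    computes the down-regulated block from list tails and the discordant
    blocks from one head and one tail, in the style of stratified RRHO
    implementations; the block of a cell is set by each list's sign-change
    index.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    list1, list2 = _align(list1, list2)
    N = len(list1)
    if step > N:
        raise ValueError(f"step {step} exceeds universe size {N}")
    if mode not in ("described", "stratified"):
        raise ValueError(f"unknown RRHO mode {mode!r}")

    n_bins = int(np.ceil(N / step))
    edges = np.minimum(np.arange(1, n_bins + 1) * step, N)

    pos2 = pd.Series(np.arange(N), index=list2.genes)
    pos2_of_list1 = pos2.loc[list1.genes].to_numpy()
    bin_edges = np.concatenate([[0], edges])
    hist, _, _ = np.histogram2d(
        np.arange(N), pos2_of_list1, bins=[bin_edges, bin_edges]
    )
    k_top = hist.cumsum(axis=0).cumsum(axis=1).astype(np.int64)

    i_sizes = edges[:, None].astype(np.int64)
    j_sizes = edges[None, :].astype(np.int64)

    if mode == "described":
        k = k_top
        neglog = _neglog10_sf_matrix(k, i_sizes, j_sizes, N)
    else:
        # Overlaps of all four head/tail combinations, derived from k_top:
        # |top_i & top_j| = k; |top_i & tail_j| = i - k;
        # |tail_i & top_j| = j - k; |tail_i & tail_j| = N - i - j + k,
        # where tail_x is the list minus its x-prefix.
        u1, u2 = list1.n_up, list2.n_up
        bi = N - i_sizes
        bj = N - j_sizes
        in_up1 = i_sizes <= max(u1, step)  # head block while prefixes are "up"
        in_up2 = j_sizes <= max(u2, step)
        k = np.where(
            in_up1 & in_up2,
            k_top,
            np.where(
                in_up1 & ~in_up2,
                i_sizes - k_top,
                np.where(~in_up1 & in_up2, j_sizes - k_top, N - i_sizes - j_sizes + k_top),
            ),
        )
        eff_i = np.where(in_up1, i_sizes, bi)
        eff_j = np.where(in_up2, j_sizes, bj)
        neglog = np.zeros_like(k, dtype=float)
        valid = (eff_i > 0) & (eff_j > 0)
        kv = np.where(valid, k, 0)
        neglog = _neglog10_sf_matrix(
            kv, np.maximum(eff_i, 1), np.maximum(eff_j, 1), N
        )
        neglog[~valid] = 0.0

    return RRHOMap(
        step=step,
        n_genes=N,
        prefix_sizes=edges,
        overlap=k_top if mode == "described" else k,
        neglog10_p=neglog,
        mode=mode,
        genes=list1.genes.copy(),
        n_up1=list1.n_up,
        n_up2=list2.n_up,
    )


@dataclass
class QuadrantPartition:
    """Sign-of-rank-value partition of the shared universe.

    UU/DD hold genes concordantly up-/down-regulated in both lists, UD/DU the
    discordant genes; genes with a zero rank value in either list belong to
    no quadrant and are reported in ``unsigned``.
    """

    uu: frozenset
    dd: frozenset
    ud: frozenset
    du: frozenset
    unsigned: frozenset = frozenset()
    n_up1: int = 0
    n_up2: int = 0

    def __getitem__(self, quadrant: str) -> frozenset:
        return {"UU": self.uu, "DD": self.dd, "UD": self.ud, "DU": self.du}[quadrant]

    @property
    def universe_size(self) -> int:
        return len(self.uu) + len(self.dd) + len(self.ud) + len(self.du) + len(self.unsigned)


def extract_quadrants(list1: RankedList, list2: RankedList) -> QuadrantPartition:
    """Quadrant gene sets by rank-value sign in each list (all transcripts)."""
    list1, list2 = _align(list1, list2)
    r1 = list1.rank_value_series()
    r2 = list2.rank_value_series().loc[r1.index]
    s1 = np.sign(r1.to_numpy())
    s2 = np.sign(r2.to_numpy())
    genes = r1.index.to_numpy()
    return QuadrantPartition(
        uu=frozenset(genes[(s1 > 0) & (s2 > 0)].tolist()),
        dd=frozenset(genes[(s1 < 0) & (s2 < 0)].tolist()),
        ud=frozenset(genes[(s1 > 0) & (s2 < 0)].tolist()),
        du=frozenset(genes[(s1 < 0) & (s2 > 0)].tolist()),
        unsigned=frozenset(genes[(s1 == 0) | (s2 == 0)].tolist()),
        n_up1=list1.n_up,
        n_up2=list2.n_up,
    )


def cap_for_display(
    rrho_map: RRHOMap, max_val: float = 300.0, min_val: float = 1.0
) -> np.ndarray:
    """Clip the -log10(p) matrix into [min_val, max_val] for plotting.

    Returns a new array; the map itself is untouched.
    """
    if min_val > max_val:
        raise ValueError("min_val must not exceed max_val")
    return np.clip(rrho_map.neglog10_p, min_val, max_val)


def log_odds_map(rrho_map: RRHOMap, cap: float = 6.0) -> np.ndarray:
    """Natural-log odds ratio of each cell's 2x2 overlap table, clipped to +-cap.

    The table is (k, i-k, j-k, N-i-j+k); a Haldane-Anscombe 0.5 correction is
    applied to all four cells of any table containing a zero.
    """
    N = rrho_map.n_genes
    i = rrho_map.prefix_sizes[:, None].astype(float)
    j = rrho_map.prefix_sizes[None, :].astype(float)
    k = rrho_map.overlap.astype(float)
    a, b, c, d = k, i - k, j - k, N - i - j + k
    has_zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    corr = np.where(has_zero, 0.5, 0.0)
    a, b, c, d = a + corr, b + corr, c + corr, d + corr
    lor = np.log(a * d) - np.log(b * c)
    return np.clip(lor, -cap, cap)
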