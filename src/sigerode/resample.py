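"""Permutation nulls and concordance statistics.

Three null constructions accompany the signature comparisons: (1) cohort
shuffling — animals' cohort identities are permuted (cohort sizes preserved)
and the shuffled contrast's fold changes are re-estimated to build a null for
the cross-comparison Spearman Rho; (2) rank shuffling — one ranked list's
order is permuted before rebuilding an RRHO map, destroying any genuine
concordance; (3) the quartile-exclusion analysis, which drops genes whose
reference fold change falls inside the middle two quartiles before
recomputing Rho.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import Contrast, differential_expression, log_expression
from .rrho import RankedList, RRHOMap, build_rrho
from .simulate import CountsMatrix

__all__ = [
    "PermutationResult",
    "spearman_rho",
    "cohort_shuffle_null",
    "rank_shuffle_null",
    "quartile_filtered_rho",
]

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    """Observed statistic with its permutation null.

    ``p_plain`` is the plain fraction of null draws at or above the observed
    value (zero is possible when the observed value beats every draw);
    ``p_smoothed`` is the (k+1)/(n+1) add-one estimate.
    """

    observed: float
    null: np.ndarray
    n_iter: int
    seed: int | None
    scheme: str
    n_resampled: int = 0

    @property
    def p_plain(self) -> float:
        return float((self.null >= self.observed).sum()) / self.n_iter

    @property
    def p_smoothed(self) -> float:
        return (float((self.null >= self.observed).sum()) + 1.0) / (self.n_iter + 1.0)

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "observed": self.observed,
            "p_plain": self.p_plain,
            "p_smoothed": self.p_smoothed,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "scheme": self.scheme,
            "n_resampled": self.n_resampled,
        }
        if include_null:
            out["null"] = self.null.tolist()
        return out


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; two-sided t-approx p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho is undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _aligned_lfc(table_a: pd.DataFrame, table_b: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    a = pd.Series(table_a["log2_fold_change"].to_numpy(), index=table_a["gene_id"].to_numpy())
    b = pd.Series(table_b["log2_fold_change"].to_numpy(), index=table_b["gene_id"].to_numpy())
    b = b.reindex(a.index)
    if b.isna().any():
        raise ValueError("DE tables do not share a gene universe")
    return a.to_numpy(), b.to_numpy()


def cohort_shuffle_null(
    counts: CountsMatrix,
    samples: pd.DataFrame,
    fixed_contrast: Contrast,
    shuffled_contrast: Contrast,
    n_iter: int = 1000,
    seed: int | None = None,
    pool: str = "all",
    permutation_fn: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> PermutationResult:
    """Null distribution of Rho under shuffled cohort identity.

    The observed statistic is the Spearman Rho between the fold changes of
    ``fixed_contrast`` and ``shuffled_contrast`` as observed.  Each iteration
    permutes cohort labels uniformly at random across the animal pool
    (``"all"`` animals by default, or ``"long_term_only"``), preserving cohort
    sizes, re-estimates the shuffled contrast's fold changes and records the
    null Rho.  A shuffle that leaves a contrast side with fewer than two
    samples is redrawn (counted in ``n_resampled``).  ``permutation_fn`` is a
    test hook returning a permutation of ``n`` indices.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if pool not in ("all", "long_term_only"):
        raise ValueError(f"unknown shuffle pool {pool!r}")

    logexpr = log_expression(counts)
    fixed = differential_expression(counts, samples, fixed_contrast, logexpr=logexpr)
    observed_tbl = differential_expression(counts, samples, shuffled_contrast, logexpr=logexpr)
    fixed_lfc, obs_lfc = _aligned_lfc(fixed, observed_tbl)
    observed, _ = spearman_rho(fixed_lfc, obs_lfc)

    if pool == "all":
        pool_ids = samples.index
    else:
        pool_ids = samples.index[samples["timepoint"] == "long"]
    pool_labels = samples.loc[pool_ids, "cohort"].to_numpy()
    n_pool = len(pool_ids)
    if n_pool < 2:
        raise ValueError("shuffle pool has fewer than 2 samples")

    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    n_resampled = 0
    shuffled_samples = samples.copy()
    needed = set(shuffled_contrast.experimental) | set(shuffled_contrast.reference)
    # labels untouched by the shuffle still count towards group sizes
    outside = samples.loc[samples.index.difference(pool_ids), "cohort"].value_counts()
    max_redraws = 1000
    for it in range(n_iter):
        for _ in range(max_redraws):
            perm = (
                permutation_fn(rng, n_pool)
                if permutation_fn is not None
                else rng.permutation(n_pool)
            )
            new_labels = pool_labels[perm]
            counts_per = pd.Series(new_labels).value_counts()
            if all(
                counts_per.get(lab, 0) + outside.get(lab, 0) >= 2 for lab in needed
            ):
                break
            n_resampled += 1
        else:
            raise ValueError(
                "could not draw a shuffle keeping both contrast sides populated"
            )
        shuffled_samples.loc[pool_ids, "cohort"] = new_labels
        tbl = differential_expression(
            counts, shuffled_samples, shuffled_contrast, logexpr=logexpr
        )
        _, null_lfc = _aligned_lfc(fixed, tbl)
        null[it], _ = spearman_rho(fixed_lfc, null_lfc)
    if n_resampled:
        logger.info("cohort_shuffle_null: redrew %d degenerate shuffles", n_resampled)
    return PermutationResult(
        observed=observed,
        null=null,
        n_iter=n_iter,
        seed=seed,
        scheme=f"cohort_shuffle[{pool}]",
        n_resampled=n_resampled,
    )


def rank_shuffle_null(
    list1: RankedList,
    list2: RankedList,
    step: int = 100,
    seed: int | None = None,
    mode: str = "described",
) -> RRHOMap:
    """RRHO of a uniformly order-shuffled list 1 against the intact list 2."""
    rng = np.random.default_rng(seed)
    return build_rrho(list1.shuffled(rng), list2, step=step, mode=mode)


def quartile_filtered_rho(
    reference: pd.DataFrame, other: pd.DataFrame
) -> tuple[float, float, set]:
    """Rho after dropping genes inside the reference's middle two quartiles.

    Q1 and Q3 of the reference fold-change distribution are linear-interpolated
    quantiles; genes with reference LFC strictly below Q1 or strictly above Q3
    are retained and the Spearman Rho of the two fold-change vectors is
    recomputed over that set.
    """
    ref_lfc, other_lfc = _aligned_lfc(reference, other)
    q1, q3 = np.quantile(ref_lfc, [0.25, 0.75])
    keep = (ref_lfc < q1) | (ref_lfc > q3)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 genes retained outside the middle quartiles")
    rho, p = spearman_rho(ref_lfc[keep], other_lfc[keep])
    retained = set(np.asarray(reference["gene_id"])[keep].tolist())
    return rho, p, retained
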