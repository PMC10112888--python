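"""Differential-expression stand-in: filtering, TPM, contrasts, DEG calling.

The study's tissue-level stage is emulated with a deliberately simple test:
genes with fewer than 10 total counts are removed, expression is TPM
normalized, and each contrast is a two-sided Welch t-test on log2(TPM + 1)
with the opposite-sex (OS) side as experimental and the same-sex (SS) side as
reference, so log2_fold_change = mean(OS) - mean(SS).  Externally produced DE
tables (e.g. DESeq2 results) are accepted through :mod:`sigerode.io` and flow
into the same downstream machinery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CountsMatrix

__all__ = [
    "Contrast",
    "filter_low_counts",
    "tpm_normalize",
    "log_expression",
    "differential_expression",
    "pool_cohorts",
    "call_degs",
    "P_FLOOR",
    "LFC_THRESHOLD",
    "P_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: p-values are floored here so -log10(p) stays finite for ranking.
P_FLOOR = 1e-300
LFC_THRESHOLD = 0.30
P_THRESHOLD = 0.05

DE_COLUMNS = ["gene_id", "base_mean", "log2_fold_change", "pvalue"]


@dataclass(frozen=True)
class Contrast:
    """A pairwise cohort contrast: experimental (OS) vs reference (SS) labels."""

    name: str
    experimental: tuple[str, ...]
    reference: tuple[str, ...]

    def __init__(self, name: str, experimental: Sequence[str], reference: Sequence[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "experimental", tuple(experimental))
        object.__setattr__(self, "reference", tuple(reference))
        if not self.experimental or not self.reference:
            raise ValueError("both contrast sides need at least one cohort label")


def filter_low_counts(counts: CountsMatrix, min_total: int = 10) -> CountsMatrix:
    """Retain genes whose total count across all samples is >= ``min_total``.

    Gene order is preserved; an empty result signals degenerate input and is
    an error.  Idempotent.
    """
    totals = counts.counts.sum(axis=1)
    keep = totals >= min_total
    if not keep.any():
        raise ValueError(
            f"no gene reaches {min_total} total counts; input looks degenerate"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_low_counts: dropped %d of %d genes", dropped, len(keep))
    return CountsMatrix(counts.counts.loc[keep], counts.lengths.loc[keep])


def tpm_normalize(counts: CountsMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates scaled to 1e6 per sample.

    rate_g = count_g / length_kb_g; TPM_g = 1e6 * rate_g / sum(rate).  An
    all-zero sample column is returned as all zeros with a warning.
    """
    lengths_kb = counts.lengths.to_numpy(dtype=float) / 1e3
    if (lengths_kb <= 0).any():
        raise ValueError("zero or negative gene length encountered")
    rate = counts.counts.to_numpy(dtype=float) / lengths_kb[:, None]
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} all-zero sample column(s); TPM left at zero",
            RuntimeWarning,
            stacklevel=2,
        )
        colsum = np.where(zero_cols, 1.0, colsum)
    tpm = 1e6 * rate / colsum
    return pd.DataFrame(tpm, index=counts.gene_ids, columns=counts.sample_ids)


def log_expression(counts: CountsMatrix) -> pd.DataFrame:
    """log2(TPM + 1), the expression scale used by the stand-in DE test."""
    return np.log2(tpm_normalize(counts) + 1.0)


def _group_samples(samples: pd.DataFrame, labels: Sequence[str]) -> pd.Index:
    known = set(samples["cohort"])
    unknown = [lab for lab in labels if lab not in known]
    if unknown:
        raise KeyError(f"unknown cohort label(s): {unknown}")
    return samples.index[samples["cohort"].isin(labels)]


def welch_t_pvalues(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided Welch t-test (Satterthwaite df) returning (lfc, p).

    Degenerate rows (both group variances zero): p = 1 when the means agree,
    the p floor otherwise.  All p-values are floored at ``P_FLOOR``.
    """
    nx, ny = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    lfc = mx - my

    se2 = vx / nx + vy / ny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)

    degenerate = se2 == 0
    if degenerate.any():
        p = np.where(degenerate & (lfc == 0), 1.0, p)
        p = np.where(degenerate & (lfc != 0), P_FLOOR, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), P_FLOOR, 1.0)
    return lfc, p


def differential_expression(
    counts: CountsMatrix,
    samples: pd.DataFrame,
    contrast: Contrast,
    logexpr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene Welch t contrast on log2(TPM + 1).

    Returns a DE table with columns gene_id, base_mean (mean TPM over the
    contrast's samples), log2_fold_change (experimental minus reference) and
    pvalue; the contrast name is recorded in ``table.attrs['contrast']``.
    ``logexpr`` lets callers (permutation loops) reuse a precomputed
    log-expression matrix, which does not depend on sample labels.
    """
    exp_ids = _group_samples(samples, contrast.experimental)
    ref_ids = _group_samples(samples, contrast.reference)
    if len(exp_ids) < 2 or len(ref_ids) < 2:
        raise ValueError(
            f"contrast {contrast.name!r} needs >= 2 samples per side "
            f"(got {len(exp_ids)} vs {len(ref_ids)})"
        )
    if logexpr is None:
        logexpr = log_expression(counts)
    x = logexpr[exp_ids].to_numpy()
    y = logexpr[ref_ids].to_numpy()
    lfc, p = welch_t_pvalues(x, y)

    used = exp_ids.append(ref_ids)
    base_mean = (np.exp2(logexpr[used]) - 1.0).mean(axis=1).to_numpy()
    table = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "base_mean": base_mean,
            "log2_fold_change": lfc,
            "pvalue": p,
        }
    ).reset_index(drop=True)
    table.attrs["contrast"] = contrast.name
    return table


def pool_cohorts(
    samples: pd.DataFrame, labels: Sequence[str], pooled_label: str
) -> pd.DataFrame:
    """Relabel the listed cohorts to one pooled label (rows unchanged).

    Pooling OS with SS cohorts into one side is refused: each pooled group
    must stay on one side of the opposite- vs same-sex comparison.
    """
    if not labels:
        raise ValueError("no cohorts given to pool")
    _group_samples(samples, labels)  # raises on unknown labels
    mask = samples["cohort"].isin(labels)
    pairings = set(samples.loc[mask, "pairing"])
    if len(pairings) > 1:
        raise ValueError(
            f"refusing to pool across pairing types {sorted(pairings)} into one group"
        )
    pooled = samples.copy()
    pooled.loc[mask, "cohort"] = pooled_label
    return pooled


def call_degs(
    table: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> tuple[set[str], set[str]]:
    """Strict-threshold DEG calling: up = LFC > +thr & p < p_thr, down mirrored."""
    lfc = table["log2_fold_change"]
    p = table["pvalue"]
    sig = p < p_threshold
    up = set(table.loc[sig & (lfc > lfc_threshold), "gene_id"])
    down = set(table.loc[sig & (lfc < -lfc_threshold), "gene_id"])
    return up, down
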