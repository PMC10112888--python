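"""On-disk formats: counts TSV, sample tables, DE tables, gene sets, RRHO maps.

Every writer/reader pair round-trips exactly (counts as integers, floats via
repr-precision text).  All files are UTF-8 with LF line endings.  Formats:

* counts TSV      — header ``gene_id<TAB>length_bp<TAB><sample ids...>``
* sample TSV      — ``sample_id, animal_id, pairing, condition, timepoint`` +
                    optional covariates
* DE table CSV    — ``gene_id,base_mean,log2_fold_change,pvalue``; a DESeq2
                    results dialect (baseMean/log2FoldChange/pvalue) is read
                    with NA-p rows dropped and counted
* gene-set text   — ``# universe_size=N`` header then one gene id per line
* RRHO export     — TSV matrix in the visual orientation (rows: list 2
                    thresholds descending, columns: list 1 ascending) plus a
                    JSON sidecar
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .rrho import RRHOMap
from .resample import PermutationResult
from .sets import GeneSet
from .simulate import CountsMatrix

__all__ = [
    "DuplicateGeneError",
    "SampleMismatchError",
    "MalformedHeaderError",
    "read_counts",
    "write_counts",
    "read_samples",
    "write_samples",
    "read_de_table",
    "write_de_table",
    "read_deseq2_table",
    "read_gene_set",
    "write_gene_set",
    "write_rrho",
    "write_permutation",
    "universe_hash",
]

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["animal_id", "pairing", "condition", "timepoint"]
DE_HEADER = "gene_id,base_mean,log2_fold_change,pvalue"


class DuplicateGeneError(ValueError):
    """A gene id appears more than once in a file."""


class SampleMismatchError(ValueError):
    """Counts-matrix columns and sample-table rows disagree."""


class MalformedHeaderError(ValueError):
    """A file header does not match the expected dialect."""


def _check_unique(ids: pd.Index | pd.Series, path: Path) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise DuplicateGeneError(f"duplicate gene id(s) in {path}: {dup[:5]}")


def write_counts(counts: CountsMatrix, path: str | Path) -> None:
    path = Path(path)
    df = counts.counts.copy()
    df.insert(0, "length_bp", counts.lengths.astype(int))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_counts(path: str | Path) -> CountsMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id" or (len(df.columns) < 3) or df.columns[1] != "length_bp":
        raise MalformedHeaderError(
            f"{path}: expected header gene_id<TAB>length_bp<TAB><samples...>, "
            f"got {list(df.columns[:3])}"
        )
    _check_unique(df["gene_id"], path)
    df = df.set_index("gene_id")
    lengths = df.pop("length_bp").astype(int)
    counts = df.astype(np.int64)
    return CountsMatrix(counts, lengths)


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(Path(path), sep="\t", lineterminator="\n")


def read_samples(path: str | Path, counts: CountsMatrix | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample_id":
        raise MalformedHeaderError(f"{path}: first column must be sample_id")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedHeaderError(f"{path}: missing column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SampleMismatchError(f"{path}: duplicate sample id(s) {dup[:5]}")
    df = df.set_index("sample_id")
    if "cohort" not in df.columns:
        df["cohort"] = df["pairing"] + "_" + df["condition"] + "_" + df["timepoint"]
    if counts is not None and (
        len(df) != counts.counts.shape[1]
        or set(df.index) != set(counts.sample_ids)
    ):
        raise SampleMismatchError(
            f"{path}: sample ids do not match the counts matrix columns"
        )
    return df


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    cols = ["gene_id", "base_mean", "log2_fold_change", "pvalue"]
    # default float formatting is the shortest round-trip representation
    table[cols].to_csv(path, index=False, lineterminator="\n")


def read_de_table(path: str | Path, contrast: str | None = None) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    if header != DE_HEADER:
        raise MalformedHeaderError(
            f"{path}: expected header {DE_HEADER!r}, got {header!r}"
        )
    df = pd.read_csv(path, dtype={"gene_id": str}, float_precision="round_trip")
    _check_unique(df["gene_id"], path)
    df.attrs["contrast"] = contrast or path.stem
    return df


def read_deseq2_table(path: str | Path, contrast: str | None = None) -> pd.DataFrame:
    """Read a DESeq2 results CSV (baseMean/log2FoldChange/pvalue dialect).

    The gene id is taken from a ``gene_id`` column or the unnamed first
    column; rows with NA p-values are dropped with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "gene_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "gene_id"})
    required = {"baseMean", "log2FoldChange", "pvalue"}
    if not required <= set(df.columns):
        raise MalformedHeaderError(
            f"{path}: missing DESeq2 column(s) {sorted(required - set(df.columns))}"
        )
    n_na = int(df["pvalue"].isna().sum())
    if n_na:
        logger.info("read_deseq2_table: dropped %d NA-pvalue rows from %s", n_na, path)
        df = df[df["pvalue"].notna()]
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"].astype(str),
            "base_mean": df["baseMean"].astype(float),
            "log2_fold_change": df["log2FoldChange"].astype(float),
            "pvalue": df["pvalue"].astype(float).clip(lower=1e-300),
        }
    ).reset_index(drop=True)
    _check_unique(out["gene_id"], path)
    out.attrs["contrast"] = contrast or path.stem
    out.attrs["n_dropped_na"] = n_na
    return out


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# universe_size={gene_set.universe_size}\n")
        for g in sorted(gene_set.genes):
            fh.write(f"{g}\n")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("# universe_size="):
            raise MalformedHeaderError(
                f"{path}: expected '# universe_size=N' header, got {header!r}"
            )
        try:
            universe = int(header.split("=", 1)[1])
        except ValueError as exc:
            raise MalformedHeaderError(f"{path}: unparseable universe size") from exc
        genes = [line.strip() for line in fh if line.strip()]
    seen: set = set()
    for g in genes:
        if g in seen:
            raise DuplicateGeneError(f"{path}: duplicate gene id {g!r}")
        seen.add(g)
    return GeneSet(name=name or path.stem, genes=frozenset(genes), universe_size=universe)


def universe_hash(genes) -> str:
    """sha256 of the sorted gene-id universe (first 16 hex chars)."""
    payload = "\n".join(sorted(map(str, genes))).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_rrho(rrho_map: RRHOMap, prefix: str | Path, matrix: np.ndarray | None = None) -> None:
    """Write an RRHO map as ``<prefix>.tsv`` + ``<prefix>.json``.

    The TSV is in the visual orientation: columns are list 1 thresholds
    ascending (x-axis), rows are list 2 thresholds descending so the smallest
    prefixes land at the bottom-left when the file is read top-to-bottom.
    ``matrix`` defaults to the -log10(p) matrix; pass a capped or log-odds
    matrix to export those views.
    """
    prefix = Path(prefix)
    values = rrho_map.neglog10_p if matrix is None else matrix
    # internal layout is [list1 prefix, list2 prefix]; visual = transpose with
    # list2 rows reversed (largest threshold first)
    visual = values.T[::-1]
    sizes = rrho_map.prefix_sizes
    df = pd.DataFrame(
        visual,
        index=pd.Index(sizes[::-1], name="list2_prefix"),
        columns=pd.Index(sizes, name="list1_prefix"),
    )
    df.to_csv(prefix.with_suffix(".tsv"), sep="\t", lineterminator="\n")
    sidecar = {
        "n_genes": int(rrho_map.n_genes),
        "step": int(rrho_map.step),
        "mode": rrho_map.mode,
        "universe_hash": universe_hash(rrho_map.genes) if rrho_map.genes is not None else None,
        "n_up_list1": rrho_map.n_up1,
        "n_up_list2": rrho_map.n_up2,
        "max_neglog10_p": rrho_map.max_signal,
    }
    with open(prefix.with_suffix(".json"), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_rrho_heatmap(
    rrho_map: RRHOMap, path: str | Path, max_val: float = 300.0, min_val: float = 1.0
) -> None:
    """Capped -log10(p) heatmap PNG, list 1 on x, smallest prefixes bottom-left."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .rrho import cap_for_display

    capped = cap_for_display(rrho_map, max_val=max_val, min_val=min_val)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(
        capped.T,
        origin="lower",
        aspect="auto",
        cmap="turbo",
        vmin=min_val,
        vmax=max_val,
    )
    ax.set_xlabel("list 1 prefix (threshold index)")
    ax.set_ylabel("list 2 prefix (threshold index)")
    fig.colorbar(im, ax=ax, label=r"$-\log_{10}(p)$ (capped)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_permutation(
    result: PermutationResult, path: str | Path, include_null: bool = False
) -> None:
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(result.to_dict(include_null=include_null), fh, indent=2, sort_keys=True)
        fh.write("\n")
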