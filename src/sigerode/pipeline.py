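"""End-to-end workflow: simulate/load -> filter -> DE -> RRHO -> erosion -> nulls.

The pipeline mirrors the study's transcriptional analysis: per-timepoint
opposite- vs same-sex contrasts, the pooled "combined pair bond" signature,
RRHO maps of the pair-bond signature against each separation contrast (and
short- vs long-term separation), quadrant extraction, eroded- and
inverted-gene sets, cohort-shuffle and rank-shuffle nulls, and clustering of
scaled fold-change profiles.  Every run writes a manifest with the config
hash and file checksums so reruns are verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ConfigError, RunConfig
from .de import (
    Contrast,
    call_degs,
    differential_expression,
    filter_low_counts,
    log_expression,
    pool_cohorts,
)
from .io import (
    read_counts,
    read_de_table,
    read_gene_set,
    read_samples,
    universe_hash,
    write_counts,
    write_de_table,
    write_gene_set,
    write_permutation,
    write_rrho,
    write_rrho_heatmap,
    write_samples,
)
from .resample import cohort_shuffle_null, quartile_filtered_rho, rank_shuffle_null, spearman_rho
from .rrho import build_rrho, extract_quadrants, rank_genes
from .sets import (
    GeneSet,
    cluster_profiles,
    eroded_genes,
    intersect_enriched,
    inverted_genes,
    scale_effect_profiles,
)
from .simulate import make_true_effects, simulate_counts

__all__ = ["run_pipeline", "STANDARD_CONTRASTS", "PipelineResult"]

logger = logging.getLogger(__name__)

# contrast name -> (experimental cohort labels, reference cohort labels)
STANDARD_CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "paired_short": (("OS_paired_short",), ("SS_paired_short",)),
    "paired_long": (("OS_paired_long",), ("SS_paired_long",)),
    "combined_pair_bond": (("combined_pair_bond_OS",), ("combined_pair_bond_SS",)),
    "sep_short": (("OS_separated_short",), ("SS_separated_short",)),
    "sep_long": (("OS_separated_long",), ("SS_separated_long",)),
}


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    out_dir: Path
    config: RunConfig
    de_tables: dict = field(default_factory=dict)
    ranked: dict = field(default_factory=dict)
    rrho_maps: dict = field(default_factory=dict)
    quadrants: dict = field(default_factory=dict)
    erosion: object = None
    inverted: tuple | None = None
    permutations: dict = field(default_factory=dict)
    rho: dict = field(default_factory=dict)
    clusters: pd.Series | None = None
    neuronal_enriched: object = None
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _available(samples: pd.DataFrame, contrast: Contrast) -> bool:
    cohorts = set(samples["cohort"])
    return set(contrast.experimental) <= cohorts and set(contrast.reference) <= cohorts


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow described by ``config``; returns handles and
    writes all artifacts (plus ``manifest.json``) under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(out_dir=out, config=config)
    rng_seed = int(config.seed)

    counts = samples = None
    if config.simulation is not None:
        design = config.simulation
        effects = make_true_effects(design)
        counts, samples = simulate_counts(effects, design)
        effects.to_csv(out / "true_effects.csv", lineterminator="\n")
        write_counts(counts, out / "counts.tsv")
        write_samples(samples, out / "samples.tsv")
    elif config.counts_path is not None:
        counts = read_counts(config.counts_path)
        samples = read_samples(config.samples_path, counts=counts)

    tables: dict[str, pd.DataFrame] = {}
    if counts is not None:
        counts = filter_low_counts(counts, min_total=config.min_total)
        logger.info("filtered universe: %d genes", counts.n_genes)
        # pool the two paired timepoints per pairing type into the combined
        # pair-bond comparison
        pooled = samples
        for pairing in ("OS", "SS"):
            labels = [
                lab
                for lab in (f"{pairing}_paired_short", f"{pairing}_paired_long")
                if lab in set(samples["cohort"])
            ]
            if labels:
                pooled = pool_cohorts(pooled, labels, f"combined_pair_bond_{pairing}")
        logexpr = log_expression(counts)
        for name, (exp, ref) in STANDARD_CONTRASTS.items():
            contrast = Contrast(name, exp, ref)
            table_samples = pooled if name == "combined_pair_bond" else samples
            if not _available(table_samples, contrast):
                continue
            tbl = differential_expression(counts, table_samples, contrast, logexpr=logexpr)
            tbl.attrs["contrast"] = name
            tables[name] = tbl
    else:
        for name, path in config.de_table_paths.items():
            tables[name] = read_de_table(path, contrast=name)
    if not tables:
        raise ConfigError("no differential-expression tables could be produced")
    result.de_tables = tables
    for name, tbl in tables.items():
        write_de_table(tbl, out / f"de_{name}.csv")

    universe = len(next(iter(tables.values())))
    up_down = {name: call_degs(t, config.lfc_threshold, config.p_threshold) for name, t in tables.items()}
    deg_summary = {
        name: {"up": len(u), "down": len(d)} for name, (u, d) in up_down.items()
    }
    for name, (u, d) in up_down.items():
        write_gene_set(GeneSet(f"{name}_up", u, universe), out / f"degs_{name}_up.txt")
        write_gene_set(GeneSet(f"{name}_down", d, universe), out / f"degs_{name}_down.txt")

    result.ranked = {name: rank_genes(t) for name, t in tables.items()}

    rrho_pairs = [
        ("paired_short", "paired_long"),
        ("combined_pair_bond", "sep_short"),
        ("combined_pair_bond", "sep_long"),
        ("sep_short", "sep_long"),
    ]
    for l1, l2 in rrho_pairs:
        if l1 not in result.ranked or l2 not in result.ranked:
            continue
        key = f"{l1}__vs__{l2}"
        m = build_rrho(
            result.ranked[l1], result.ranked[l2], step=config.rrho_step, mode=config.rrho_mode
        )
        result.rrho_maps[key] = m
        write_rrho(m, out / f"rrho_{key}")
        result.quadrants[key] = extract_quadrants(result.ranked[l1], result.ranked[l2])
        if config.make_plots:
            write_rrho_heatmap(
                m,
                out / f"rrho_{key}.png",
                max_val=config.display_cap_max,
                min_val=config.display_cap_min,
            )

    pb_st = result.quadrants.get("combined_pair_bond__vs__sep_short")
    pb_lt = result.quadrants.get("combined_pair_bond__vs__sep_long")
    if pb_st is not None and pb_lt is not None:
        result.erosion = eroded_genes(pb_st, pb_lt, universe_size=universe)
        result.erosion.intersection_table().to_csv(
            out / "erosion_intersections.tsv", sep="\t", index=False, lineterminator="\n"
        )
        for q in ("UU", "DD"):
            write_gene_set(
                GeneSet(f"eroded_{q}", result.erosion.eroded[q], universe),
                out / f"eroded_{q}.txt",
            )

    sep_vs_sep = result.quadrants.get("sep_short__vs__sep_long")
    if sep_vs_sep is not None and "combined_pair_bond" in tables:
        inv_up, inv_down = inverted_genes(
            sep_vs_sep, tables["combined_pair_bond"], lfc_threshold=config.lfc_threshold
        )
        result.inverted = (inv_up, inv_down)
        write_gene_set(GeneSet("inverted_from_up", inv_up, universe), out / "inverted_from_up.txt")
        write_gene_set(GeneSet("inverted_from_down", inv_down, universe), out / "inverted_from_down.txt")

    # cross-comparison Spearman rho on shared fold changes
    def _rho(name_a: str, name_b: str) -> None:
        if name_a in tables and name_b in tables:
            a = tables[name_a].set_index("gene_id")["log2_fold_change"]
            b = tables[name_b].set_index("gene_id")["log2_fold_change"].reindex(a.index)
            rho, p = spearman_rho(a.to_numpy(), b.to_numpy())
            result.rho[f"{name_a}__vs__{name_b}"] = {"rho": rho, "pvalue": p}

    _rho("paired_short", "paired_long")
    _rho("combined_pair_bond", "sep_short")
    _rho("combined_pair_bond", "sep_long")
    if "paired_short" in tables and "paired_long" in tables:
        f_rho, f_p, retained = quartile_filtered_rho(tables["paired_short"], tables["paired_long"])
        result.rho["paired_short__vs__paired_long_quartile_filtered"] = {
            "rho": f_rho,
            "pvalue": f_p,
            "n_retained": len(retained),
        }

    # permutation nulls need raw counts; unavailable in DE-tables-only mode
    if counts is not None:
        # The short- vs long-term paired concordance is permuted with the
        # long-timepoint-only pool: the fixed contrast's animals never enter
        # the shuffle, so observed and null are exchangeable under the null.
        # The pair-bond-vs-separation shuffles must use the configured pool
        # (their shuffled cohorts live at the short timepoint too).
        perm_specs = [
            ("paired_short", "paired_long", samples, "long_term_only"),
            ("combined_pair_bond", "sep_short", pooled, config.shuffle_pool),
            ("combined_pair_bond", "sep_long", pooled, config.shuffle_pool),
        ]
        for offset, (fixed, shuffled, tab, pool) in enumerate(perm_specs):
            if fixed not in tables or shuffled not in tables:
                continue
            fixed_c = Contrast(fixed, *STANDARD_CONTRASTS[fixed])
            shuf_c = Contrast(shuffled, *STANDARD_CONTRASTS[shuffled])
            perm = cohort_shuffle_null(
                counts,
                tab,
                fixed_c,
                shuf_c,
                n_iter=config.n_iter,
                seed=rng_seed + offset,
                pool=pool,
            )
            key = f"{fixed}__vs__{shuffled}"
            result.permutations[key] = perm
            write_permutation(perm, out / f"perm_{key}.json")

        if "combined_pair_bond" in result.ranked and "sep_short" in result.ranked:
            shuffled_map = rank_shuffle_null(
                result.ranked["combined_pair_bond"],
                result.ranked["sep_short"],
                step=config.rrho_step,
                seed=rng_seed + 100,
                mode=config.rrho_mode,
            )
            result.rrho_maps["rank_shuffled_pb_vs_sep_short"] = shuffled_map
            write_rrho(shuffled_map, out / "rrho_rank_shuffled_pb_vs_sep_short")

    profile_names = [n for n in ("combined_pair_bond", "sep_short", "sep_long") if n in tables]
    if len(profile_names) >= 2:
        scaled = scale_effect_profiles([tables[n] for n in profile_names])
        result.clusters = cluster_profiles(scaled, k=config.n_clusters)
        pd.DataFrame({"cluster": result.clusters}).to_csv(
            out / "profile_clusters.csv", lineterminator="\n"
        )

    if config.module_set_paths and "combined_pair_bond" in up_down:
        modules = [read_gene_set(p) for p in config.module_set_paths]
        modules = [
            GeneSet(m.name, m.genes, universe) if m.universe_size != universe else m
            for m in modules
        ]
        up_set = GeneSet("combined_pair_bond_up", up_down["combined_pair_bond"][0], universe)
        enriched, contributions = intersect_enriched(up_set, modules)
        result.neuronal_enriched = enriched
        write_gene_set(enriched, out / "neuronal_enriched.txt")
        with open(out / "module_contributions.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(contributions, fh, indent=2, sort_keys=True)
            fh.write("\n")

    summary = {
        "universe_size": universe,
        "deg_counts": deg_summary,
        "rho": result.rho,
        "rrho_max_signal": {k: m.max_signal for k, m in result.rrho_maps.items()},
        "permutations": {k: p.to_dict() for k, p in result.permutations.items()},
        "eroded_sizes": (
            {q: len(result.erosion.eroded[q]) for q in ("UU", "DD")}
            if result.erosion is not None
            else None
        ),
    }
    with open(out / "summary.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    config.to_yaml(out / "config.yaml")
    outputs = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "sigerode": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "universe_hash": universe_hash(tables[next(iter(tables))]["gene_id"]),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.manifest = manifest
    return result
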