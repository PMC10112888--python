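"""Run configuration: thresholds, RRHO parameters, resampling, simulation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import Cohort, SimDesign

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, serializable to YAML/JSON.

    Exactly one input route must be available: a simulation block, a
    counts+samples pair of paths, or a set of precomputed DE-table paths
    keyed by contrast name.
    """

    out_dir: str = "sigerode_run"
    counts_path: str | None = None
    samples_path: str | None = None
    de_table_paths: dict = field(default_factory=dict)
    module_set_paths: tuple = ()
    simulation: SimDesign | None = None

    min_total: int = 10
    lfc_threshold: float = 0.30
    p_threshold: float = 0.05

    rrho_step: int = 100
    rrho_boundary: float = 0.02  # recorded for provenance; unused by the described algorithm
    rrho_mode: str = "described"
    display_cap_max: float = 300.0
    display_cap_min: float = 1.0
    log_odds_cap: float = 6.0

    n_iter: int = 1000
    seed: int = 0
    shuffle_pool: str = "all"

    n_clusters: int = 3
    make_plots: bool = False

    def __post_init__(self) -> None:
        for name in ("min_total", "lfc_threshold", "p_threshold", "rrho_step", "n_iter"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        has_sim = self.simulation is not None
        has_counts = self.counts_path is not None and self.samples_path is not None
        has_tables = bool(self.de_table_paths)
        if not (has_sim or has_counts or has_tables):
            raise ConfigError(
                "configuration needs a simulation block, counts+samples paths, "
                "or DE-table paths"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["cohorts"] = [c.label for c in self.simulation.cohorts]
            d["simulation"] = sim
        d["de_table_paths"] = dict(sorted(self.de_table_paths.items()))
        d["module_set_paths"] = list(self.module_set_paths)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _cohort_from_label(label: str) -> Cohort:
    try:
        pairing, condition, timepoint = label.split("_")
        return Cohort(pairing, condition, timepoint)
    except ValueError as exc:
        raise ConfigError(f"unparseable cohort label {label!r}") from exc


def _sim_from_dict(d: dict) -> SimDesign:
    d = dict(d)
    if "cohorts" in d:
        d["cohorts"] = tuple(_cohort_from_label(lab) for lab in d["cohorts"])
    for tup_key in ("library_size_range", "gene_length_range"):
        if tup_key in d:
            d[tup_key] = tuple(d[tup_key])
    try:
        return SimDesign(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulation block: {exc}") from exc


def load_config(source: str | Path | dict) -> RunConfig:
    """Build a RunConfig from a YAML file path or an already-parsed mapping."""
    if isinstance(source, (str, Path)):
        with open(Path(source), encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    sim = raw.pop("simulation", None)
    cfg_kwargs = dict(raw)
    if sim is not None:
        cfg_kwargs["simulation"] = _sim_from_dict(sim)
    if "de_table_paths" in cfg_kwargs and cfg_kwargs["de_table_paths"] is None:
        cfg_kwargs["de_table_paths"] = {}
    if "module_set_paths" in cfg_kwargs:
        cfg_kwargs["module_set_paths"] = tuple(cfg_kwargs["module_set_paths"] or ())
    try:
        return RunConfig(**cfg_kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
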