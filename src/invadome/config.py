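"""Pipeline and simulation configuration.

All thresholds that gate a pipeline stage live in :class:`PipelineConfig`;
all knobs of the synthetic-data generator live in :class:`SimConfig`.  Both
are plain dataclasses with eager validation and flat-YAML (de)serialization
so that a run is fully described by one small text file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraints."""


@dataclass
class PipelineConfig:
    """Thresholds and parameters of the analysis pipeline.

    Attributes
    ----------
    cv_threshold:
        Technical-replicate coefficient-of-variation gate.  A protein is
        retained only if every defined per-sample CV is below this value in
        both conditions.
    presence_min, presence_total:
        Presence rule of the aggregation step: a protein must be quantified
        in at least ``presence_min`` of the ``presence_total`` columns of
        each condition (6 of 9 for the 3-sample x 3-replicate design).
    padj_threshold:
        BH-adjusted p-value cutoff declaring a protein differentially
        expressed.
    logfc_clustermap_human, logfc_clustermap_mouse:
        |log2 fold change| gates (on top of ``padj_threshold``) selecting
        proteins for the clustermap; species-specific because stromal
        (mouse) fold changes run much larger.
    logfc_enrichment:
        |log2 fold change| gate selecting the subset submitted to
        over-representation analysis.
    ora_padj:
        BH-adjusted p-value cutoff calling a gene set enriched.
    edge_confidence_min:
        Minimum interaction confidence retained in the network ("medium"
        confidence on the STRING 0-1 scale).
    mcl_inflation, mcl_max_iter, mcl_prune:
        Markov Cluster Algorithm parameters.
    bootstrap_n:
        Number of feature resamples for dendrogram branch support.
    angioscore_top_n:
        Number of top hits per area entering the AngioScore comparison.
    rng_seed:
        Seed for every stochastic stage (bootstrap, simulation defaults).
    """

    cv_threshold: float = 0.8
    presence_min: int = 6
    presence_total: int = 9
    padj_threshold: float = 0.01
    logfc_clustermap_human: float = 2.0
    logfc_clustermap_mouse: float = 5.0
    logfc_enrichment: float = 1.0
    ora_padj: float = 0.05
    edge_confidence_min: float = 0.4
    mcl_inflation: float = 2.0
    mcl_max_iter: int = 200
    mcl_prune: float = 1e-5
    bootstrap_n: int = 200
    angioscore_top_n: int = 30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cv_threshold",
            "padj_threshold",
            "logfc_clustermap_human",
            "logfc_clustermap_mouse",
            "logfc_enrichment",
            "ora_padj",
            "mcl_inflation",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 <= self.edge_confidence_min <= 1:
            raise ConfigError(
                f"edge_confidence_min must be in [0, 1], got {self.edge_confidence_min}"
            )
        if self.presence_min <= 0 or self.presence_total <= 0:
            raise ConfigError("presence_min and presence_total must be > 0")
        if self.presence_min > self.presence_total:
            raise ConfigError(
                f"presence_min ({self.presence_min}) exceeds presence_total "
                f"({self.presence_total})"
            )
        if self.bootstrap_n < 1:
            raise ConfigError("bootstrap_n must be >= 1")
        if self.mcl_max_iter < 1:
            raise ConfigError("mcl_max_iter must be >= 1")

    def logfc_clustermap(self, species: str) -> float:
        """Species-specific clustermap |log2FC| threshold."""
        if species == "human":
            return self.logfc_clustermap_human
        if species == "mouse":
            return self.logfc_clustermap_mouse
        raise ConfigError(f"unknown species {species!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


@dataclass
class SimConfig:
    """Synthetic quantification-table generator settings.

    The defaults mirror the scale of a two-area xenograft study: two
    conditions (core ``A`` / invasive ``I``), 3 biological samples x 3
    technical replicates per condition, roughly 750 human and 520 mouse
    proteins, log-normal abundances with a heavy-tailed technical-CV
    mixture, abundance-dependent dropout and a planted differentially
    expressed fraction.

    Attributes
    ----------
    n_human, n_mouse:
        Protein counts per species.
    de_fraction:
        Fraction of proteins with a planted non-zero log2 fold change.
    log2fc_range:
        (low, high) magnitude of planted effects; sign drawn at random
        with a core-up bias (``invasive_up_fraction``).
    invasive_up_fraction:
        Fraction of planted effects that are positive (invasive-up).
    base_log2_mean, base_log2_sd:
        Log-normal base-abundance distribution (log2 scale).
    sample_sd_log2:
        Biological-sample effect standard deviation (log2 scale), drawn
        per (protein, sample).
    cv_bulk, cv_tail, cv_tail_fraction:
        Technical-CV mixture: most proteins get CV ``cv_bulk``; a fraction
        ``cv_tail_fraction`` gets CV ``cv_tail`` (the irreproducible tail
        crossing the 0.8 gate).
    dropout_midpoint, dropout_steepness:
        Logistic missingness on log2 abundance: a cell at log2 abundance x
        is missing with probability ``1 / (1 + exp(steepness * (x -
        midpoint)))``; set ``dropout_steepness = 0`` together with
        ``dropout_midpoint = -inf`` — or simply ``dropout = False`` — for
        complete tables.
    dropout:
        Master switch for missingness.
    samples, replicates:
        Grid dimensions per condition.
    seed:
        Generator seed.
    """

    n_human: int = 750
    n_mouse: int = 520
    de_fraction: float = 0.2
    log2fc_range: Tuple[float, float] = (1.0, 6.0)
    invasive_up_fraction: float = 0.25
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.0
    sample_sd_log2: float = 0.25
    cv_bulk: float = 0.2
    cv_tail: float = 1.2
    cv_tail_fraction: float = 0.1
    dropout: bool = True
    dropout_midpoint: float = 16.0
    dropout_steepness: float = 1.0
    samples: int = 3
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_human < 0 or self.n_mouse < 0 or self.n_human + self.n_mouse == 0:
            raise ConfigError("need at least one protein to simulate")
        for name in ("de_fraction", "cv_tail_fraction", "invasive_up_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.log2fc_range
        if lo < 0 or hi < lo:
            raise ConfigError(f"log2fc_range must satisfy 0 <= lo <= hi, got {self.log2fc_range}")
        if self.cv_bulk < 0 or self.cv_tail < 0:
            raise ConfigError("CVs must be nonnegative")
        if self.samples < 1 or self.replicates < 1:
            raise ConfigError("samples and replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "log2fc_range" in data:
            data["log2fc_range"] = tuple(data["log2fc_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["log2fc_range"] = list(data["log2fc_range"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
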