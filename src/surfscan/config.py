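"""Configuration objects for simulation, variant calling and epitope scoring.

All tunables funnel through three frozen dataclasses so a run is fully
described by (config, seed).  YAML round-tripping is provided for the CLI.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError

__all__ = ["SimConfig", "CallerThresholds", "ScorerConfig", "load_yaml_config"]

STRAND_MODES = ("per_strand", "total_with_both_strands")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cell-line panel.

    The defaults describe a desk-scale panel that mirrors the shape of a
    23-line targeted-capture study: ~30X depth, clonal heterozygous variants
    (VAF 0.5), a ~5x somatic-load contrast between mutator and non-mutator
    lines, and a germline background far denser than the somatic signal.
    """

    n_cell_lines: int = 6
    n_genes: int = 40
    mean_cds_length: int = 450          # bases; multiple-of-3 enforced per gene
    somatic_load_mutator: float = 40.0  # expected somatic variants per mutator line
    somatic_load_normal: float = 8.0    # expected somatic variants per other line
    mutator_fraction: float = 0.4       # fraction of lines with the mutator phenotype
    indel_fraction: float = 0.13        # fraction of somatic variants that are InDels
    germline_density: float = 1.0       # germline variants per kb of target
    depth_mean: float = 30.0            # mean pileup depth (Poisson)
    base_quality_mean: float = 35.0     # Phred; sd 6, clipped to [2, 41]
    map_quality_mean: float = 50.0      # Phred; sd 8, clipped to [0, 60]
    vaf: float = 0.5                    # variant allele fraction, in (0, 1]
    error_rate: float = 0.0             # per-base uniform miscall rate
    fraction_expressed: float = 0.6     # fraction of (gene, line) pairs above threshold
    impact_rate_snv: float = 0.4        # hidden truth P(damaging) for missense/nonsense
    impact_rate_indel: float = 0.8      # hidden truth P(damaging) for InDels
    druggable_fraction: float = 0.3     # fraction of genes in the druggable list
    known_fraction: float = 0.5         # fraction of genes in the known-mutated list
    seed: int = 0

    def validate(self) -> "SimConfig":
        for name in ("n_cell_lines", "n_genes", "mean_cds_length"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        for name in ("somatic_load_mutator", "somatic_load_normal",
                     "germline_density", "depth_mean", "base_quality_mean",
                     "map_quality_mean", "error_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("indel_fraction", "mutator_fraction", "fraction_expressed",
                     "impact_rate_snv", "impact_rate_indel",
                     "druggable_fraction", "known_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if not 0.0 < self.vaf <= 1.0:
            raise ConfigError(f"vaf must lie in (0, 1], got {self.vaf!r}")
        if self.somatic_load_mutator <= self.somatic_load_normal:
            raise ConfigError(
                "somatic_load_mutator must exceed somatic_load_normal "
                f"({self.somatic_load_mutator} <= {self.somatic_load_normal})")
        if self.mean_cds_length < 30:
            raise ConfigError("mean_cds_length must be at least 30 bases")
        return self

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class CallerThresholds:
    """Filter cascade for the pileup caller.

    ``strand_mode='per_strand'`` requires at least ``min_support_per_strand``
    high-quality reads on *each* strand; ``'total_with_both_strands'`` relaxes
    this to that many in total with at least one on each strand.
    """

    min_base_quality: int = 25
    min_map_quality: int = 20
    min_support_per_strand: int = 3
    strand_mode: str = "per_strand"
    recurrence_k: int = 3               # flag variants seen in > k cell lines

    def validate(self) -> "CallerThresholds":
        for name in ("min_base_quality", "min_map_quality",
                     "min_support_per_strand", "recurrence_k"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.strand_mode not in STRAND_MODES:
            raise ConfigError(
                f"strand_mode must be one of {STRAND_MODES}, got {self.strand_mode!r}")
        return self


@dataclass(frozen=True)
class ScorerConfig:
    """Thresholds and options for MHC-I binding / cleavage / differential calls."""

    percent_optimum_threshold: float = 50.0   # percent of the matrix optimum
    ic50_threshold: float = 500.0             # nM, binder cut-off
    ic50_cap: float = 50000.0                 # nM, weakest representable affinity
    differential_factor: float = 1.2          # mutant/reference affinity ratio
    strict_differential: bool = False         # True: ratio must exceed the factor
    require_reference_candidate: bool = False  # True: reference window must itself bind
    hla_allele: str = "HLA-A*02:01"
    flank: int = 10                           # residues either side of the mutation
    cleavage_cterm: str = "LVIFYWMKR"         # C-terminal residues deemed cleavable

    def validate(self) -> "ScorerConfig":
        for name in ("percent_optimum_threshold", "ic50_threshold", "ic50_cap"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.differential_factor <= 1.0:
            raise ConfigError("differential_factor must exceed 1")
        if self.flank < 0:
            raise ConfigError("flank must be non-negative")
        return self


_SECTIONS = {"simulate": SimConfig, "caller": CallerThresholds, "scorer": ScorerConfig}


def load_yaml_config(path: str | Path) -> dict:
    """Load a per-stage YAML config into validated dataclasses.

    Recognised top-level keys: ``simulate``, ``caller``, ``scorer``; unknown
    keys raise, unknown fields raise (naming the field).
    """
    raw: Mapping = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for key, payload in raw.items():
        if key not in _SECTIONS:
            raise ConfigError(f"unknown config section {key!r}")
        cls = _SECTIONS[key]
        try:
            obj = cls(**(payload or {}))
        except TypeError as exc:
            raise ConfigError(f"section {key!r}: {exc}") from None
        out[key] = obj.validate()
    return out


def dump_yaml_config(objs: Mapping[str, object], path: str | Path) -> None:
    payload = {k: asdict(v) for k, v in objs.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
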