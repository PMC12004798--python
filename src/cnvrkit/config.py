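"""Simulation and pipeline configuration.

A single seeded :class:`SimulationConfig` determines every random draw of the
synthetic cohort generator. Stage-local generators are derived from the one
global seed by fixed offsets, so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


# fixed per-stage offsets for deriving stage-local RNGs from the global seed
STAGE_OFFSETS = {
    "genome": 0,
    "loci": 1,
    "samples": 2,
    "signals": 3,
    "annotations": 4,
    "enrichment": 5,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic Holstein-like cohort.

    Defaults describe a desk-scale version of a high-density SNP-array CNV
    study: 300 animals on 5 autosomes (a 3,000-sample / 29-autosome design
    scaled by 10x / to 5 chromosomes), a 78:22 deletion:duplication mix with
    deletions shorter than duplications on average, probe density ~300
    SNPs/Mb, and two paired call sets (A = full cohort, B = after sample/SNP
    QC) whose disagreements are single-SNP boundary shifts.
    """

    seed: int = 1
    n_samples: int = 300
    n_loci: int = 150
    chromosome_lengths_mb: tuple[float, ...] = (60.0, 55.0, 50.0, 45.0, 40.0)
    chromosome_names: tuple[str, ...] | None = None

    # CNV locus mixture: fraction of loci that are deletions, and log-normal
    # length models per type (means from large-cohort SNP-array estimates:
    # deletions ~60 kb, duplications ~93 kb).
    deletion_fraction: float = 0.78
    del_mean_length: float = 60_000.0
    dup_mean_length: float = 93_000.0
    length_log_sd: float = 0.6
    min_locus_length: int = 5_000
    homozygous_del_fraction: float = 0.10   # state 0 among deletions
    double_dup_fraction: float = 0.10       # state 4 among duplications

    # carrier frequency per locus drawn U(lo, hi); at n_samples=300 the
    # resulting carrier counts are >=5 for nearly all loci
    carrier_freq_min: float = 0.03
    carrier_freq_max: float = 0.35

    # dataset B: the post-QC companion call set
    b_sample_drop_rate: float = 0.02
    b_snp_drop_rate: float = 0.02
    perturbation_fraction: float = 0.10

    # signal model
    snp_density_per_mb: float = 300.0
    lrr_sd: float = 0.15
    baf_sd: float = 0.03
    gc_wave_slope: float = 0.0  # LRR units per GC percentage point
    gc_mean: float = 45.0
    gc_sd: float = 5.0

    # annotation / enrichment planting
    n_genes: int = 400
    gene_mean_length: float = 25_000.0
    protein_coding_fraction: float = 0.8734
    enriched_trait: str = "Milk yield"
    enriched_trait_size: int = 50
    enriched_overlap_prob: float = 0.9
    background_overlap_prob: float = 0.1
    n_background_traits: int = 20
    qtls_per_trait: int = 50
    qtl_mean_length: float = 150_000.0
    novel_fraction: float = 0.17

    def __post_init__(self) -> None:
        rates = {
            "deletion_fraction": self.deletion_fraction,
            "homozygous_del_fraction": self.homozygous_del_fraction,
            "double_dup_fraction": self.double_dup_fraction,
            "carrier_freq_min": self.carrier_freq_min,
            "carrier_freq_max": self.carrier_freq_max,
            "b_sample_drop_rate": self.b_sample_drop_rate,
            "b_snp_drop_rate": self.b_snp_drop_rate,
            "perturbation_fraction": self.perturbation_fraction,
            "enriched_overlap_prob": self.enriched_overlap_prob,
            "background_overlap_prob": self.background_overlap_prob,
            "novel_fraction": self.novel_fraction,
            "protein_coding_fraction": self.protein_coding_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.carrier_freq_min > self.carrier_freq_max:
            raise ConfigError("carrier_freq_min must be <= carrier_freq_max")
        if any(l <= 0 for l in self.chromosome_lengths_mb):
            raise ConfigError("chromosome lengths must be positive")
        if self.snp_density_per_mb <= 0:
            raise ConfigError("snp_density_per_mb must be positive")
        for name in ("lrr_sd", "baf_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_samples < 1 or self.n_loci < 0:
            raise ConfigError("n_samples must be >= 1 and n_loci >= 0")

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-local generator derived from the global seed by a fixed offset."""
        return np.random.default_rng([int(self.seed), STAGE_OFFSETS[stage]])

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["chromosome_lengths_mb"] = list(self.chromosome_lengths_mb)
        if self.chromosome_names is not None:
            d["chromosome_names"] = list(self.chromosome_names)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation parameters: {sorted(unknown)}")
        d = dict(d)
        if "chromosome_lengths_mb" in d:
            d["chromosome_lengths_mb"] = tuple(d["chromosome_lengths_mb"])
        if d.get("chromosome_names") is not None:
            d["chromosome_names"] = tuple(d["chromosome_names"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data.get("simulation", data))


def load_yaml(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return data
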