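"""Configuration objects for the simulator and the end-to-end pipeline.

Both configs are plain dataclasses that validate on construction, reject
unknown keys when loaded from YAML, and round-trip through serialization
unchanged.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["SimulationConfig", "PipelineConfig", "ParameterError"]


class ParameterError(ValueError):
    """A configuration value is outside its documented range."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic allohexaploid dataset.

    The defaults describe a 21-chromosome hexaploid (subgenomes A/B/D,
    homeologous groups 1-7) segregating for loss of one chromosome: a
    selfed monosomic whose chromosome-lacking (null) pollen succeeds at
    half the rate of normal pollen, while null egg cells transmit at the
    normal rate.  Expression is chromosome-dosage proportional unless
    ``dosage_compensation`` is raised above 0.
    """

    seed: int = 0
    focal_chromosome: str = "chr2A"
    n_genes: int = 2100
    n_snps: int = 5000
    mean_depth_snp: float = 50.0
    mean_library_size: int = 1_000_000
    nb_dispersion: float = 0.05
    dosage_compensation: float = 0.0
    male_null_transmission: float = 0.5
    female_null_transmission: float = 1.0
    n_progeny: int = 42
    bulk_sizes: tuple[int, int] = (20, 5)
    n_tissues: int = 5
    marker_noise_sd: float = 0.05
    # marker panel composition; the focal panel mirrors a multi-marker
    # dosage-sensitive SSR readout, off-focal markers act as controls
    n_markers_focal: int = 9
    n_markers_other: int = 3
    # genome composition
    triad_fraction: float = 0.78
    stamen_specific_fraction: float = 0.05
    other_tissue_specific_fraction: float = 0.10
    snp_beta_a: float = 5.0
    min_depth_snp: int = 4

    def __post_init__(self) -> None:
        _check(isinstance(self.seed, int) and self.seed >= 0, "seed must be a nonnegative integer")
        _check(self.n_genes >= 21, "n_genes must be at least one per chromosome")
        _check(self.n_snps >= 21, "n_snps must be >= 21 (one per chromosome)")
        _check(self.mean_depth_snp > 0, "mean_depth_snp must be positive")
        _check(self.mean_library_size > 0, "mean_library_size must be positive")
        _check(self.nb_dispersion > 0, "nb_dispersion must be positive")
        for name in ("dosage_compensation", "male_null_transmission",
                     "female_null_transmission", "triad_fraction",
                     "stamen_specific_fraction", "other_tissue_specific_fraction"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must lie in [0, 1], got {v}")
        _check(self.n_progeny > 0, "n_progeny must be positive")
        self.bulk_sizes = tuple(self.bulk_sizes)  # type: ignore[assignment]
        _check(len(self.bulk_sizes) == 2 and all(b > 0 for b in self.bulk_sizes),
               "bulk_sizes must be two positive integers (fertile, sterile)")
        _check(self.n_tissues >= 2, "n_tissues must be >= 2")
        _check(self.marker_noise_sd >= 0, "marker_noise_sd must be nonnegative")
        _check(self.n_markers_focal >= 1, "need at least one focal marker")
        _check(self.snp_beta_a > 0, "snp_beta_a must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bulk_sizes"] = list(self.bulk_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration: input paths, thresholds, seed.

    Any path left ``None`` is produced by the simulator stage (when
    ``simulate`` is true) or the corresponding stage is skipped.
    """

    out_dir: str = "hexanull_out"
    seed: int = 0
    focal_chromosome: str = "chr2A"
    log_level: str = "INFO"
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # input paths for running on pre-existing files
    vcf: Optional[str] = None
    counts: Optional[str] = None
    sample_metadata: Optional[str] = None
    gene_map: Optional[str] = None
    homeolog_table: Optional[str] = None
    marker_table: Optional[str] = None
    tissue_counts: Optional[str] = None
    # bsa_ed thresholds
    ed_threshold: float = 0.33
    ed_threshold_mode: str = "fixed"
    min_depth: int = 4
    # dosage_scan cutoffs
    null_max: float = 0.25
    mono_max: float = 0.75
    reference_samples: Optional[list[str]] = None
    # marker_genotyping cutoffs
    absent_max: float = 0.2
    half_max: float = 0.75
    # expression_screen thresholds
    fc_min: float = 2.0
    fdr_max: float = 0.01
    k: int = 8
    target_tissue: str = "stamen"
    specificity_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        _check(0.0 < self.ed_threshold < 2.0 ** 0.5, "ed_threshold must lie in (0, sqrt(2))")
        _check(self.ed_threshold_mode in ("fixed", "mediansd"),
               "ed_threshold_mode must be 'fixed' or 'mediansd'")
        _check(self.min_depth >= 0, "min_depth must be nonnegative")
        _check(0.0 < self.null_max < self.mono_max < 1.0,
               "require 0 < null_max < mono_max < 1")
        _check(0.0 <= self.absent_max < self.half_max, "require 0 <= absent_max < half_max")
        _check(self.fc_min >= 1.0, "fc_min must be >= 1")
        _check(0.0 < self.fdr_max <= 1.0, "fdr_max must lie in (0, 1]")
        _check(self.k >= 2, "k must be >= 2")
        _check(0.0 < self.specificity_cutoff <= 1.0, "specificity_cutoff must lie in (0, 1]")
        _check(self.log_level in ("DEBUG", "INFO", "WARNING", "ERROR"),
               "log_level must be a standard logging level name")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
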