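"""Configuration objects for synthetic-data generation and the pipeline.

All thresholds default to the screening constants used throughout the
method: the ten-criterion ADMET screen, top-50% collaborative-filter
retention, the -8 kcal/mol docking-affinity cutoff, the 0.5 fingerprint
similarity deduplication threshold, FDR 0.05 and the 10-gene minimum
gene-set size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

#: Inclusive ADMET thresholds: (criterion, direction, bound).
#: ``le`` means the property must be <= bound to pass, ``ge`` >= bound.
DEFAULT_ADMET_THRESHOLDS: dict[str, tuple[str, float]] = {
    "MW": ("le", 500.0),
    "Hdon": ("le", 5.0),
    "Hacc": ("le", 10.0),
    "AlogP": ("le", 5.0),
    "RBN": ("le", 10.0),
    "OB": ("ge", 30.0),
    "DL": ("ge", 0.1),
    "BBB": ("ge", 0.3),
    "Caco2": ("ge", 0.4),
    "TPSA": ("le", 60.0),
}


def _check_range(name: str, value, lo=None, hi=None):
    if lo is not None and value < lo:
        raise ConfigError(f"{name} must be >= {lo}, got {value}")
    if hi is not None and value > hi:
        raise ConfigError(f"{name} must be <= {hi}, got {value}")


def _check_count_range(name: str, pair):
    lo, hi = pair
    if lo < 1 or hi < lo:
        raise ConfigError(f"{name} must be a (lo, hi) pair with 1 <= lo <= hi, got {pair}")


@dataclass
class SynthConfig:
    """Parameters of the synthetic input generator.

    The defaults emulate the scale of a three-prescription stroke study:
    roughly 100 active compounds per prescription after screening, a
    target universe of several hundred protein-coding genes, 23-189
    predicted targets per compound, and ~1,745 pathological genes.
    """

    seed: int = 0
    n_prescriptions: int = 3
    herbs_per_prescription: tuple[int, int] = (9, 12)
    compounds_per_herb: tuple[int, int] = (14, 22)
    #: fraction of generated compounds constructed to pass the full ADMET screen
    admet_pass_fraction: float = 0.5
    #: override: generate exactly this many compounds (herb structure still built)
    n_compounds: int | None = None
    n_gene_universe: int = 5000
    n_targets_universe: int = 2000
    targets_per_compound: tuple[int, int] = (23, 189)
    #: Zipf-like skew of target popularity; 0 = uniform. Promiscuous
    #: targets dominate real prediction servers, and the skew is what
    #: makes network filtering lose a realistic share of rare targets.
    target_popularity_exponent: float = 1.3
    #: fraction of herbs drawn from a pool shared between prescriptions
    shared_herb_fraction: float = 0.2
    #: probability that a predicted target is reported by all three servers
    prediction_overlap: float = 0.4
    n_pathological_genes: int = 1745
    #: fraction of the disease-database list confirmed by the other sources
    source_overlap: float = 0.85
    n_gene_sets: int = 150
    gene_set_size: tuple[int, int] = (5, 80)
    affinity_mean: float = -6.5   # kcal/mol
    affinity_sd: float = 1.5      # kcal/mol
    #: fraction of docked pairs drawn from the strong-binding tail (<= -8)
    fraction_strong: float = 0.25

    def __post_init__(self):
        _check_range("seed", self.seed, lo=0)
        _check_range("n_prescriptions", self.n_prescriptions, lo=1)
        _check_count_range("herbs_per_prescription", self.herbs_per_prescription)
        _check_count_range("compounds_per_herb", self.compounds_per_herb)
        _check_range("admet_pass_fraction", self.admet_pass_fraction, 0.0, 1.0)
        if self.n_compounds is not None:
            _check_range("n_compounds", self.n_compounds, lo=1)
        _check_range("n_gene_universe", self.n_gene_universe, lo=1)
        _check_range("n_targets_universe", self.n_targets_universe, lo=1)
        if self.n_targets_universe > self.n_gene_universe:
            raise ConfigError("n_targets_universe cannot exceed n_gene_universe")
        _check_count_range("targets_per_compound", self.targets_per_compound)
        _check_range("target_popularity_exponent", self.target_popularity_exponent, lo=0.0)
        if self.targets_per_compound[1] > self.n_targets_universe:
            raise ConfigError("targets_per_compound upper bound exceeds target universe")
        _check_range("shared_herb_fraction", self.shared_herb_fraction, 0.0, 1.0)
        _check_range("prediction_overlap", self.prediction_overlap, 0.0, 1.0)
        _check_range("n_pathological_genes", self.n_pathological_genes, lo=1)
        _check_range("source_overlap", self.source_overlap, 0.0, 1.0)
        if self.source_overlap <= 0:
            raise ConfigError("source_overlap must be > 0")
        _check_range("n_gene_sets", self.n_gene_sets, lo=1)
        _check_count_range("gene_set_size", self.gene_set_size)
        if self.gene_set_size[1] > self.n_gene_universe:
            raise ConfigError("gene_set_size upper bound exceeds gene universe")
        if self.affinity_mean >= 0:
            raise ConfigError("affinity_mean must be negative (docking energies)")
        _check_range("affinity_sd", self.affinity_sd, lo=0.0)
        _check_range("fraction_strong", self.fraction_strong, 0.0, 1.0)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration with the method's default constants."""

    out_dir: str = "synergyscreen_out"
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    admet_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_ADMET_THRESHOLDS))
    missing_policy: str = "fail"      # strict | fail | skip
    fingerprint_bits: int = 2048
    fingerprint_radius: int = 3       # ECFP6
    retention_fraction: float = 0.5
    affinity_cutoff: float = -8.0     # kcal/mol, inclusive
    similarity_threshold: float = 0.5 # strict > for deduplication
    fdr_level: float = 0.05
    min_set_size: int = 10
    #: number of curated pathways carried into the multilevel network
    n_curated_pathways: int = 6
    #: explicit curated pathway ids (overrides automatic selection when set)
    curated_pathways: list[str] | None = None
    top_k: int = 5

    def __post_init__(self):
        if isinstance(self.synth, dict):
            self.synth = SynthConfig(**self.synth)
        if self.missing_policy not in ("strict", "fail", "skip"):
            raise ConfigError(f"unknown missing_policy {self.missing_policy!r}")
        _check_range("fingerprint_bits", self.fingerprint_bits, lo=8)
        _check_range("fingerprint_radius", self.fingerprint_radius, lo=1)
        if not (0.0 < self.retention_fraction <= 1.0):
            raise ConfigError("retention_fraction must be in (0, 1]")
        _check_range("similarity_threshold", self.similarity_threshold, 0.0, 1.0)
        _check_range("fdr_level", self.fdr_level, 0.0, 1.0)
        _check_range("min_set_size", self.min_set_size, lo=0)
        _check_range("n_curated_pathways", self.n_curated_pathways, lo=1)
        _check_range("top_k", self.top_k, lo=1)
        # keep seeds in sync: the pipeline seed drives generation
        self.synth = SynthConfig(**{**asdict(self.synth), "seed": self.seed})

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat-key YAML config; keyword arguments override file values."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        raw.update(overrides)
        known = cls.__dataclass_fields__
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
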