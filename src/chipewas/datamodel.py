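"""Shared domain types and pipeline configuration.

The pipeline passes tabular data around as pandas DataFrames with the column
contracts documented on each type below; the dataclasses here are the typed
row/record views used at module boundaries and in tests.

Coordinate convention: all internal coordinates are 1-based inclusive.
BED input/output converts at the boundary (see :mod:`chipewas.io`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import yaml


class DriverGene(str, Enum):
    """CHIP driver-gene categories used for subtype analyses."""

    DNMT3A = "DNMT3A"
    TET2 = "TET2"
    ASXL1 = "ASXL1"
    OTHER = "other"


class Stratum(str, Enum):
    """Self-reported race stratum for the stratified meta-analysis."""

    WHITE = "White"
    BLACK = "Black"
    POOLED = "pooled"


@dataclass(frozen=True)
class CpGAnnotation:
    """A CpG probe location (1-based point coordinate)."""

    probe_id: str
    chromosome: str
    position: int
    gene_symbol: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"CpG position must be >= 1 (1-based), got {self.position}"
            )


@dataclass(frozen=True)
class GeneRegion:
    """A gene interval with its transcription start site (1-based inclusive)."""

    gene_symbol: str
    chromosome: str
    start: int
    end: int
    tss: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_symbol}: start {self.start} > end {self.end}"
            )

    @property
    def tss_within_bounds(self) -> bool:
        return self.start <= self.tss <= self.end


@dataclass(frozen=True)
class SampleChipStatus:
    """CHIP carrier status for one sample.

    CHIP is defined by a somatic driver mutation at variant allele frequency
    (VAF) >= 2%; ``driver_gene`` is set only for carriers.
    """

    sample_id: str
    any_chip: bool
    driver_gene: Optional[DriverGene] = None
    vaf: float = 0.0

    def __post_init__(self) -> None:
        if self.any_chip and self.vaf < 0.02:
            raise ValueError(
                f"{self.sample_id}: CHIP carrier with VAF {self.vaf} < 0.02"
            )
        if self.driver_gene is not None and not self.any_chip:
            raise ValueError(f"{self.sample_id}: driver gene set on non-carrier")


@dataclass(frozen=True)
class CohortEwasRecord:
    """Per-CpG association result from one cohort/stratum EWAS."""

    probe_id: str
    cohort_id: str
    stratum: str
    beta: float
    se: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.probe_id}: se must be > 0, got {self.se}")
        if not 0 < self.p <= 1:
            raise ValueError(f"{self.probe_id}: p must be in (0,1], got {self.p}")


# Column contracts for the tabular views used between stages.
SUMMARY_STATS_COLUMNS = ["probe_id", "cohort", "stratum", "beta", "se", "p", "n"]
META_COLUMNS = [
    "probe_id", "te", "se_te", "z", "p", "q_stat", "q_df", "i2",
    "direction", "n_studies",
]
MQTL_COLUMNS = [
    "snp_id", "probe_id", "beta_x", "se_x", "p_x", "effect_allele",
    "chromosome", "position",
]
OUTCOME_GWAS_COLUMNS = [
    "snp_id", "outcome", "beta_y", "se_y", "p_y", "effect_allele",
]
EVOC_COLUMNS = [
    "probe_id", "strand", "condition", "replicate",
    "reads_mc", "reads_c", "reads_other",
]


@dataclass
class PipelineConfig:
    """Thresholds and constants shared across pipeline stages.

    Defaults follow the study design: epigenome-wide Bonferroni threshold
    0.05/400,000 ≈ 1e-7, genomic-control correction applied only when
    λ > 1.5, cis windows of 1 Mb, instrument p-value ceiling 2e-11, LD
    pruning at r² < 0.01, diagnostic exclusion at p < 0.05 and BH-FDR
    significance at q < 0.05.
    """

    alpha_epigenome: float = 0.05
    n_probes_bonferroni: int = 400_000
    lambda_correction_threshold: float = 1.5
    vaf_sensitivity_cutoff: float = 0.10
    cis_window_bp: int = 1_000_000
    ld_r2_max: float = 0.01
    mqtl_p_max: float = 2e-11
    iv_exclusion_p: float = 0.05
    fdr_q: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 < self.alpha_epigenome < 1, "alpha_epigenome in (0,1)"),
            (self.n_probes_bonferroni >= 1, "n_probes_bonferroni >= 1"),
            (self.lambda_correction_threshold > 0, "lambda threshold > 0"),
            (0 <= self.vaf_sensitivity_cutoff <= 1, "vaf cutoff in [0,1]"),
            (self.cis_window_bp >= 0, "cis_window_bp >= 0"),
            (0 <= self.ld_r2_max <= 1, "ld_r2_max in [0,1]"),
            (0 < self.mqtl_p_max <= 1, "mqtl_p_max in (0,1]"),
            (0 < self.iv_exclusion_p < 1, "iv_exclusion_p in (0,1)"),
            (0 < self.fdr_q < 1, "fdr_q in (0,1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    @property
    def bonferroni_p(self) -> float:
        return self.alpha_epigenome / self.n_probes_bonferroni

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every synthetic dataset.

    ``causal_cpgs`` maps driver gene -> {probe_id: signed true effect δ
    in methylation-beta units}; ``mr_theta`` maps (probe_id, outcome) ->
    true causal effect; ``pleiotropy_alpha`` maps snp_id -> direct effect
    on the outcome bypassing methylation.
    """

    causal_cpgs: dict = field(default_factory=dict)
    confounder_loadings: dict = field(default_factory=dict)
    mr_theta: dict = field(default_factory=dict)
    pleiotropy_alpha: dict = field(default_factory=dict)

    def causal_probe_ids(self, driver: Optional[str] = None) -> set:
        if driver is not None:
            return set(self.causal_cpgs.get(driver, {}))
        out: set = set()
        for effects in self.causal_cpgs.values():
            out |= set(effects)
        return out
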