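"""Configuration models for the simulator and the pipeline.

Every tunable named in the analysis (depth filter 30, window width 200,
minimum 4 sites per unit, 25% delta cutoff, BH q 0.05, 2 kb shores/flanks,
18-bp tags, 1-mismatch tag matching) is surfaced here as a named key.
Unknown keys are rejected so a typo cannot silently fall back to a default.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigurationError

DEFAULT_SAMPLES = ("S0h", "S4h", "S12h", "S24h", "S96h")

ACTIVE_MARKS = ("H3K9ac", "H3K27ac", "H3K4me3")
REPRESSIVE_MARKS = ("H3K9me3", "H3K27me3")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationConfig(_Strict):
    """Parameters of the synthetic genome / methylome / library simulator.

    Defaults describe the study conditions every downstream analysis is
    exercised under: five timepoint samples, one baseline; mean sequencing
    depth 50 reads/site; unbiased libraries; abundant spike-in standards.
    """

    seed: int = 0
    n_chroms: int = Field(3, ge=1)
    chrom_length: int = Field(200_000, ge=1000)
    cgi_count: int = Field(30, ge=0)
    gene_count: int = Field(60, ge=0)
    mean_depth: float = Field(50.0, gt=0)
    hpaii_efficiency: float = Field(1.0, gt=0, le=1)
    inverse_efficiency: float = Field(1.0, gt=0, le=1)
    spike_in_mean: float = Field(3000.0, gt=0)
    seq_error_rate: float = Field(0.001, ge=0, lt=1)
    samples: tuple[str, ...] = DEFAULT_SAMPLES
    # genome texture
    ccgg_spacing: int = Field(50, ge=24, description="mean bp between planted CCGG sites outside CGIs")
    cgi_width: int = Field(1000, ge=200)
    cgi_ccgg_multiplier: float = Field(5.0, ge=3.0)
    marks: tuple[str, ...] = ACTIVE_MARKS + REPRESSIVE_MARKS
    shortrna_count: int = Field(12, ge=0)
    shortrna_width: int = Field(150, ge=50)
    repressive_peaks_per_chrom: int = Field(2, ge=0)
    # count model
    depth_dispersion: float = Field(0.0, ge=0, description="gamma shape^-1 of per-site depth means; 0 = pure Poisson")
    index_length: int = Field(6, ge=4)
    tag_length: int = Field(18, ge=10)

    @field_validator("samples")
    @classmethod
    def _unique_samples(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if len(v) < 2 or len(set(v)) != len(v):
            raise ValueError("need >=2 unique sample labels (first is baseline)")
        return v


class QuantifyConfig(_Strict):
    min_depth: int = Field(30, ge=1)
    scale_constant: float = Field(1e6, gt=0)


class MapConfig(_Strict):
    max_mismatch: int = Field(1, ge=0, le=2)


class AnnotateConfig(_Strict):
    tss_halfwidth: int = Field(1000, ge=0)
    flank: int = Field(2000, ge=0)
    shore_width: int = Field(2000, ge=0)


class DiffConfig(_Strict):
    window: int = Field(200, ge=1)
    min_sites: int = Field(4, ge=1)
    delta_cutoff: float = Field(0.25, ge=0, le=1)
    q_cutoff: float = Field(0.05, gt=0, le=1)
    delta_only: bool = False
    strict_sign: bool = False


class ProfilesConfig(_Strict):
    body_bins: int = Field(40, ge=1)
    flank_bins: int = Field(20, ge=1)
    ma_window: int = Field(11, ge=1)
    shortrna_flank: int = Field(2000, ge=0)


class PipelineConfig(_Strict):
    """Top-level YAML config: one section per stage."""

    outdir: Path = Path("mscc_out")
    simulate: bool = True
    scenario: str = "null"
    simulation: SimulationConfig = SimulationConfig()
    mapping: MapConfig = MapConfig()
    quantify: QuantifyConfig = QuantifyConfig()
    annotate: AnnotateConfig = AnnotateConfig()
    diff: DiffConfig = DiffConfig()
    profiles: ProfilesConfig = ProfilesConfig()
    with_reads: bool = False
    reads_fastq: Optional[Path] = None
    genome_fasta: Optional[Path] = None
    annotations_dir: Optional[Path] = None
    index_table: Optional[Path] = None
    # planted-DMR scenario knobs
    n_dmrs: int = Field(50, ge=0)
    dmr_delta: float = Field(0.4)
    dmr_width: int = Field(200, ge=1)
    expression_offset: float = Field(0.2, ge=0, le=1)

    @field_validator("scenario")
    @classmethod
    def _known_scenario(cls, v: str) -> str:
        allowed = {"null", "planted_dmr", "expression_coupled"}
        if v not in allowed:
            raise ValueError(f"unknown scenario {v!r}; expected one of {sorted(allowed)}")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigurationError(str(exc)) from exc
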