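"""Pipeline configuration with schema validation.

Defaults encode the study conditions the simulator emulates: a 12-
chromosome ~373 Mb rice-like genome, a 127-line CSSL panel built with four
backcrosses under MAS, two donor restorer loci (an Rf6-like locus at the
top of chromosome 8 and an Rf5-like locus mid chromosome 10), a 400-plant
F2 per segregation test and a >=4000-plant F2/F3 screen for fine mapping.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .genome import GenomeMap, rice_genome
from .plants import RfLocus

__all__ = ["PipelineConfig", "load_config"]


class GenomeConfig(BaseModel):
    chrom_lengths_bp: list[int] | None = None
    scale: float = 1.0

    def build(self) -> GenomeMap:
        if self.chrom_lengths_bp is not None:
            return GenomeMap(tuple((i + 1, l) for i, l in enumerate(self.chrom_lengths_bp)))
        return rice_genome(self.scale)


class RfLocusConfig(BaseModel):
    chrom: int
    pos: int = Field(gt=0)
    name: str

    def build(self) -> RfLocus:
        return RfLocus(self.chrom, self.pos, self.name)


class WindowConfig(BaseModel):
    window_size: int = Field(default=15, ge=3)
    step: int = Field(default=5, ge=1)
    max_gap: int = Field(default=1, ge=0)


class ScanConfig(BaseModel):
    alpha: float = Field(default=0.05, gt=0, lt=1)
    n_permutations: int = Field(default=1000, ge=100)


class SegTestConfig(BaseModel):
    n_f2: int = Field(default=400, gt=0)
    alpha: float = 0.05
    tolerance: float = 0.01


class FineMapConfig(BaseModel):
    n_plants: int = Field(default=4000, gt=0)
    n_markers: int = Field(default=14, ge=2)
    margin_bp: int = Field(default=50_000, ge=0)


class PipelineConfig(BaseModel):
    genome: GenomeConfig = GenomeConfig()
    snp_density: float = Field(default=50.0, gt=0)  # SNPs/Mb
    n_lines: int = Field(default=127, gt=0)
    n_backcrosses: int = Field(default=4, ge=1)
    mas_batch: int = Field(default=12, ge=1)
    rf_loci: list[RfLocusConfig] = [
        RfLocusConfig(chrom=8, pos=340_000, name="Rf6"),
        RfLocusConfig(chrom=10, pos=17_700_000, name="Rf5"),
    ]
    # panel design: lines whose MAS target is pinned to each restorer
    # region, guaranteeing the panel segregates there (the rest of the
    # panel draws random targets for genome-wide coverage)
    carrier_lines_per_locus: int = Field(default=3, ge=0)
    error_rate: float = Field(default=0.005, ge=0, lt=1)
    missing_rate: float = Field(default=0.02, ge=0, lt=1)
    regime: str = "normal"
    f1_replicates: int = Field(default=10, gt=0)
    window: WindowConfig = WindowConfig()
    scan: ScanConfig = ScanConfig()
    segtest: SegTestConfig = SegTestConfig()
    finemap: FineMapConfig = FineMapConfig()

    @field_validator("regime")
    @classmethod
    def _regime_known(cls, v: str) -> str:
        if v not in ("normal", "heat"):
            raise ValueError("regime must be 'normal' or 'heat'")
        return v


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML or JSON config file; None gives the defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return PipelineConfig.model_validate(data or {})
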