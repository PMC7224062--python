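"""Run configuration: one YAML-backed schema holding every pipeline default.

All thresholds the pipeline uses live here with their documented domains, so
the places where a judgement call was made (germline call threshold, het band,
MLPA thresholds, error rates) are visible and overridable in one file. Unknown
keys are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LocusConfig(_Strict):
    length: int = Field(4000, ge=2000)
    n_paralogs: int = Field(6, ge=0)
    identity: float = Field(0.98, ge=0.8, lt=1.0)
    n_anchors: int | None = None
    n_exons: int = Field(3, ge=1)
    exon_length: int = Field(300, ge=50)


class AmpliconConfig(_Strict):
    amplicon_length: int = Field(900, ge=200)
    min_overlap: int = Field(250, ge=50)
    primer_length: int = Field(25, ge=15)


class ScenarioConfig(_Strict):
    position: int = Field(ge=0)
    ref: str
    alt: str
    zygosity: Literal["het", "hom", "mosaic"] = "het"
    mosaic_fraction: float | None = Field(None, gt=0.0, lt=0.5)
    dropout: bool = False
    dropout_amplicon: str | None = None
    name: str | None = None


class ReadsConfig(_Strict):
    depth: float = Field(200.0, ge=1.0)
    contamination: float = Field(0.05, ge=0.0, lt=1.0)
    read_length: int = Field(200, ge=30)
    substitution_rate: float = Field(0.002, ge=0.0, lt=1.0)
    homopolymer_rate0: float = Field(0.002, ge=0.0, lt=1.0)
    gc_multiplier: float = Field(3.0, ge=1.0)
    scenarios: list[ScenarioConfig] = []


class AlignConfig(_Strict):
    match: int = Field(2, ge=1)
    mismatch: int = Field(-3, le=-1)
    gap: int = Field(-5, le=-1)
    band: int = Field(16, ge=4)
    min_score_frac: float = Field(0.6, gt=0.0, lt=1.0)
    min_confidence: int = Field(20, ge=0, le=60)


class CallConfig(_Strict):
    threshold: float = Field(0.10, gt=0.0, lt=1.0)
    het_low: float = Field(0.20, gt=0.0, lt=1.0)
    het_high: float = Field(0.80, gt=0.0, lt=1.0)
    hom_threshold: float = Field(0.90, gt=0.0, le=1.0)
    min_depth: int = Field(20, ge=1)
    coverage_threshold: int = Field(20, ge=1)
    mosaic: bool = True
    error_rate: float = Field(0.01, gt=0.0, lt=1.0)
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    min_alt: int = Field(10, ge=1)

    @model_validator(mode="after")
    def _ordered(self) -> "CallConfig":
        if not (self.threshold < self.het_low <= self.het_high < self.hom_threshold):
            raise ValueError("need threshold < het_low <= het_high < hom_threshold")
        if self.error_rate >= self.threshold:
            raise ValueError("error_rate must be below the germline threshold")
        return self


class MlpaConfig(_Strict):
    n_exons: int = Field(12, ge=2)
    probes_per_exon: int = Field(1, ge=1)
    n_reference_probes: int = Field(4, ge=2)
    n_controls: int = Field(3, ge=1)
    noise_sd: float = Field(0.05, ge=0.0, lt=0.5)
    low: float = Field(0.70, gt=0.0, lt=1.0)
    high: float = Field(1.30, gt=1.0)
    copy_state: dict[str, int] = {}


class CohortConfig(_Strict):
    n: int = Field(120, ge=10)
    family_history_rate: float = Field(0.767, ge=0.0, le=1.0)


STAGES = ("locus", "reads", "align", "call", "mlpa", "classify", "pedigree", "cohort")


class RunConfig(_Strict):
    seed: int = 0
    stages: list[str] = list(STAGES)
    locus: LocusConfig = LocusConfig()
    amplicons: AmpliconConfig = AmpliconConfig()
    reads: ReadsConfig = ReadsConfig()
    align: AlignConfig = AlignConfig()
    call: CallConfig = CallConfig()
    mlpa: MlpaConfig = MlpaConfig()
    cohort: CohortConfig = CohortConfig()

    @model_validator(mode="after")
    def _known_stages(self) -> "RunConfig":
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def demo_config() -> RunConfig:
    """The bundled demonstration configuration."""
    from importlib.resources import files

    text = files("pkdpanel").joinpath("data/demo.yaml").read_text()
    return RunConfig.model_validate(yaml.safe_load(text))
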