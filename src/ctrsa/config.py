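"""Pipeline configuration: schema-validated YAML for the CLI."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .synthetic import StudyConfig

__all__ = ["AnalysisOptions", "PipelineConfig", "load_pipeline_config"]


class AnalysisOptions(BaseModel):
    """Options of the measurement and statistics stages."""

    model_config = ConfigDict(extra="forbid")

    #: implant point whose displacement is reported
    translation_reference: str = "centroid"
    #: df convention for the precision t critical value
    df_rule: str = Field(default="n-1", pattern="^(n-1|n)$")
    breakpoint_months: float = Field(default=3.0, gt=0.0)
    ci_level: float = Field(default=0.95, gt=0.0, lt=1.0)
    #: decimals for report-time rounding of precision tables
    report_decimals: int = Field(default=2, ge=0)
    #: fail (exit non-zero) on any quality-gate violation
    strict_gates: bool = False


class PipelineConfig(BaseModel):
    """Top-level config: a study to simulate plus analysis options.

    Validated strictly — unknown keys are rejected before any stage
    runs.
    """

    model_config = ConfigDict(extra="forbid")

    study: StudyConfig = Field(default_factory=StudyConfig)
    analysis: AnalysisOptions = Field(default_factory=AnalysisOptions)
    log_level: str = "INFO"


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    return PipelineConfig.model_validate(raw)
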