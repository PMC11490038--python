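"""Schema-validated pipeline configuration.

Defaults reproduce the published analysis constants: classification
thresholds 100/100 on the 0-255 scale, epithelial criteria (area > 200 px,
solidity > 0.70, mean red intensity >= 180), the 250 um^2 minimum-aggregate
gate, the 0.71 um optical section step, and the Bonferroni-adjusted
significance thresholds 0.01 (intra-gel) and 0.008 (inter-gel).  Unknown
keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .classify import Thresholds
from .epithelial import EpithelialCriteria
from .stats import ComparisonConfig

__all__ = ["EpithelialConfig", "StatsConfig", "PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EpithelialConfig(_Strict):
    min_area_px: int = Field(default=200, ge=1)
    min_solidity: float = Field(default=0.70, gt=0, le=1)
    min_mean_intensity: float = Field(default=180.0, gt=0, lt=255)
    connectivity: Literal[4, 8] = 8


class StatsConfig(_Strict):
    familywise_alpha: float = Field(default=0.05, gt=0, lt=1)
    intra_family_size: int = Field(default=5, ge=1)
    inter_family_size: int = Field(default=6, ge=1)
    inter_display_decimals: int = Field(default=3, ge=1)
    paired_inter_gel: bool = False


class PipelineConfig(_Strict):
    """Every tunable of the quantification and analysis pipeline."""

    channel_map: dict[int, str] = Field(default_factory=lambda: {0: "green", 1: "red"})
    bit_depth: int = Field(default=8, ge=8, le=16)
    z_step_um: float = Field(default=0.71, gt=0)
    # back-derived so the 250 um^2 gate equals exactly 4750 pixels
    pixel_size_um: float = Field(default=(250.0 / 4750.0) ** 0.5, gt=0)
    slice_order: Literal["surface_first", "base_first"] = "surface_first"
    green_thr: float = Field(default=100.0, gt=0, lt=255)
    red_thr: float = Field(default=100.0, gt=0, lt=255)
    epithelial: EpithelialConfig = Field(default_factory=EpithelialConfig)
    min_area_um2: float = Field(default=250.0, gt=0)
    mft_min_cluster_um2: float = Field(default=250.0, gt=0)
    layer_mode: Literal["per_field", "harmonised"] = "per_field"
    layer_bv_mode: Literal["slice_mean", "pixel_pooled"] = "slice_mean"
    stats: StatsConfig = Field(default_factory=StatsConfig)
    seed: int = 0

    @field_validator("channel_map")
    @classmethod
    def _check_channel_map(cls, v: dict[int, str]) -> dict[int, str]:
        if sorted(v.values()) != ["green", "red"]:
            raise ValueError("channel_map must assign 'green' and 'red' exactly once")
        return v

    # -- derived objects ---------------------------------------------------

    def thresholds(self) -> Thresholds:
        return Thresholds(green_thr=self.green_thr, red_thr=self.red_thr)

    def criteria(self) -> EpithelialCriteria:
        return EpithelialCriteria(
            min_area_px=self.epithelial.min_area_px,
            min_solidity=self.epithelial.min_solidity,
            min_mean_intensity=self.epithelial.min_mean_intensity,
        )

    def comparison_config(self) -> ComparisonConfig:
        return ComparisonConfig(
            familywise_alpha=self.stats.familywise_alpha,
            intra_family_size=self.stats.intra_family_size,
            inter_family_size=self.stats.inter_family_size,
            inter_display_decimals=self.stats.inter_display_decimals,
            paired_inter_gel=self.stats.paired_inter_gel,
        )

    def mft_min_cluster_px(self) -> int:
        """Cluster-size gate for the thickness measurement, in pixels."""
        return max(1, round(self.mft_min_cluster_um2 / self.pixel_size_um**2))

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; ``None`` yields all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)
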