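"""Strict, typed pipeline configuration loaded from YAML."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .optics import OpticsConfig

__all__ = [
    "RestorationParams",
    "DetectionParams",
    "MatchingParams",
    "TrackingConfig",
    "PipelineConfig",
    "load_config",
]


class RestorationParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    lowpass_cutoff: float = 0.3
    rl_iterations: int = 10
    psf_sigma_um: float = 0.4

    @model_validator(mode="after")
    def _check(self) -> "RestorationParams":
        if not (0 < self.lowpass_cutoff <= 0.5):
            raise ValueError("lowpass_cutoff must be in (0, 0.5]")
        if self.rl_iterations < 1:
            raise ValueError("rl_iterations must be >= 1")
        if self.psf_sigma_um <= 0:
            raise ValueError("psf_sigma_um must be > 0")
        return self


class DetectionParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: Literal["hough", "blob"] = "hough"
    r_min_px: float = 5.0
    r_max_px: float = 15.0
    sensitivity: float = 0.35
    block_size_px: int = 31
    offset_nsigma: float = 2.0
    r_blob_px: float = 3.0

    @model_validator(mode="after")
    def _check(self) -> "DetectionParams":
        if not (0 < self.r_min_px <= self.r_max_px):
            raise ValueError("invalid Hough radius range")
        if self.block_size_px < 3 or self.block_size_px % 2 == 0:
            raise ValueError("block_size_px must be odd and >= 3")
        return self


class MatchingParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    w_y: float = 0.5
    w_r: float = 0.25
    w_e: float = 0.25
    row_tol_px: float = 2.0

    @model_validator(mode="after")
    def _check(self) -> "MatchingParams":
        if min(self.w_y, self.w_r, self.w_e) < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w_y + self.w_r + self.w_e - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.row_tol_px <= 0:
            raise ValueError("row_tol_px must be > 0")
        return self


class TrackingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_link_dist_um: float = 5.0
    max_gap_frames: int = 2
    max_gap_dist_um: float = 7.0
    z_scale: float = 1.0
    min_length: int = 3

    @model_validator(mode="after")
    def _check(self) -> "TrackingConfig":
        if self.max_link_dist_um <= 0 or self.max_gap_dist_um <= 0:
            raise ValueError("link distances must be > 0")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        if self.z_scale <= 0:
            raise ValueError("z_scale must be > 0")
        return self


class PipelineConfig(BaseModel):
    """Top-level config; unknown keys anywhere are rejected."""

    model_config = ConfigDict(extra="forbid")

    optics: OpticsConfig = OpticsConfig()
    restoration: RestorationParams = RestorationParams()
    detection: DetectionParams = DetectionParams()
    matching: MatchingParams = MatchingParams()
    tracking: TrackingConfig = TrackingConfig()
    seed: int = 0


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML config file into a validated :class:`PipelineConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
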