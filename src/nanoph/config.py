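"""Validated run configuration (strict: unknown keys are rejected)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "BackgroundConfig", "RegionConfig"]


class BackgroundConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    method: Literal["roi", "image", "constant", "none"] = "none"
    roi: Optional[tuple[int, int, int, int]] = None  # row0, row1, col0, col1
    constant_indicator: float = Field(0.0, ge=0)
    constant_reference: float = Field(0.0, ge=0)
    companion_path: Optional[str] = None

    @model_validator(mode="after")
    def _method_requirements(self):
        if self.method == "roi" and self.roi is None:
            raise ValueError("background method 'roi' requires a rectangle")
        if self.method == "image" and self.companion_path is None:
            raise ValueError("background method 'image' requires companion_path")
        return self


class RegionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_size: int = Field(1, ge=1)
    max_size: int = Field(10**9, ge=1)

    @model_validator(mode="after")
    def _ordered(self):
        if self.max_size < self.min_size:
            raise ValueError("max_size must be >= min_size")
        return self


class RunConfig(BaseModel):
    """Settings for one measurement run."""

    model_config = ConfigDict(extra="forbid")

    channel_indicator: int | str = 0
    channel_reference: int | str = 1
    slice_index: Optional[int] = None  # analyst-designated most in-focus slice
    background: BackgroundConfig = BackgroundConfig()
    threshold: Literal["auto"] | float = "auto"
    threshold_step: float = Field(1.0, gt=0)
    analysis_mode: Literal["pixel", "region", "image"] = "pixel"
    bin_width: float = Field(0.2, gt=0)
    regions: RegionConfig = RegionConfig()
    colormap: str = "viridis"
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
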