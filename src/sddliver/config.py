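"""Run configuration for the segmentation pipeline and CLI.

All tunables of every stage live in one nested, JSON-serialisable model;
unknown keys are rejected so that typos in a config file fail loudly.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .mrf import GibbsModel
from .sdd import SddParams

__all__ = ["RunConfig", "SddConfig", "MrfConfig", "MorphConfig", "AnatomyConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class SddConfig(_Strict):
    bandwidth_w: int = Field(default=12, ge=1, le=127)
    window_n: int = Field(default=20, ge=2, le=100)
    valley_merge_distance: int = Field(default=8, ge=0)
    mode_min_height: float = Field(default=0.02, ge=0.0, lt=1.0)

    def to_params(self) -> SddParams:
        return SddParams(
            bandwidth_w=self.bandwidth_w,
            window_n=self.window_n,
            valley_merge_distance=self.valley_merge_distance,
            mode_min_height=self.mode_min_height,
        )


class MrfConfig(_Strict):
    beta: float = Field(default=1.0, gt=0)
    max_sweeps: int = Field(default=20, ge=0)

    def to_model(self) -> GibbsModel:
        return GibbsModel(beta=self.beta, max_sweeps=self.max_sweeps)


class MorphConfig(_Strict):
    n_f: int = Field(default=8, ge=0)
    n_m: int = Field(default=16, ge=0)


class AnatomyConfig(_Strict):
    orientation_flip: bool = False
    min_bone_blob_area: int = Field(default=8, ge=1)
    # rib/spine split column: None = auto (body centroid), or a fixed column
    rib_split: float | None = None


class RunConfig(_Strict):
    """Full pipeline configuration (per-slice segmentation + smoothing)."""

    sdd_config: SddConfig = SddConfig()
    mrf: MrfConfig = MrfConfig()
    morph: MorphConfig = MorphConfig()
    anatomy: AnatomyConfig = AnatomyConfig()
    spline_alpha: float = Field(default=0.5, ge=0.0, lt=1.0)
    case: str = Field(default="auto", pattern="^(auto|stomach|kidney|heart)$")
    seed: int = 0

    @property
    def sdd(self) -> SddParams:
        return self.sdd_config.to_params()

    def with_sdd(self, **kwargs) -> "RunConfig":
        return self.model_copy(update={"sdd_config": self.sdd_config.model_copy(update=kwargs)})

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
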