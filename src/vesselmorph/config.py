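"""Pipeline configuration schema (YAML-backed, validated before any run)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .reference_shapes import SAMPLE_GROUPS, SHAPE_CLASSES

CONFIG_SCHEMA_VERSION = 1


class PanelConfig(BaseModel):
    n_per_class: int = Field(20, ge=1)
    noise: float = Field(0.03, ge=0.0)
    classes: list[str] = list(SHAPE_CLASSES)

    @field_validator("classes")
    @classmethod
    def _known_classes(cls, v: list[str]) -> list[str]:
        for name in v:
            if name not in SHAPE_CLASSES:
                raise ValueError(
                    f"classes: unknown shape class {name!r}; "
                    f"expected one of {SHAPE_CLASSES}"
                )
        return v


class SampleSetConfig(BaseModel):
    n_per_group: int = Field(8, ge=1)
    n_vessels: int = Field(20, ge=1)
    noise: float = Field(0.03, ge=0.0)
    groups: list[str] = list(SAMPLE_GROUPS)

    @field_validator("groups")
    @classmethod
    def _known_groups(cls, v: list[str]) -> list[str]:
        for name in v:
            if name not in SAMPLE_GROUPS:
                raise ValueError(
                    f"groups: unknown group {name!r}; "
                    f"expected one of {SAMPLE_GROUPS}"
                )
        return v


class PipelineConfig(BaseModel):
    """Resolved configuration for a vesselmorph run."""

    schema_version: int = CONFIG_SCHEMA_VERSION
    harmonics: int = Field(20, ge=5, description="computed EFD harmonics N")
    descriptors: int = Field(5, ge=1, description="retained descriptors K")
    resample_points: int = Field(256, ge=8)
    cluster_k: int = Field(5, ge=1)
    classify_method: str = "centroid"
    seed: int = 0
    pixel_size_um: float | None = None
    panel: PanelConfig = PanelConfig()
    samples: SampleSetConfig = SampleSetConfig()

    @field_validator("classify_method")
    @classmethod
    def _known_method(cls, v: str) -> str:
        if v not in ("centroid", "cocluster"):
            raise ValueError("classify_method must be 'centroid' or 'cocluster'")
        return v


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the resolved configuration next to a run's outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)
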