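"""Validated run configuration (YAML-backed, typo-safe).

One :class:`RunConfig` covers data handling, the synthetic generator,
model choice, training, fusion and output locations.  Unknown keys are
rejected so that a misspelled field fails loudly instead of silently
using a default.  Every command echoes the fully-resolved configuration
into its output directory.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .data import IOConfig
from .errors import ConfigurationError
from .synthetic import ClassSignature, GeneratorConfig, default_signatures
from .train import TrainConfig

__all__ = ["RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataSection(_Strict):
    root: str | None = None
    manifest: str | None = None
    train_fraction: float = 0.8
    height: int = 64
    width: int = 64
    flow_depth: int = 5
    flow_method: str = "ilk"
    flow_clip: float = 20.0
    rgb_frames: int = 1
    cache_dir: str | None = None


class SyntheticSection(_Strict):
    num_classes: int = 6
    clips_per_class: int = 60
    frames_per_clip: int = 32
    fps: float = 8.0
    height: int = 64
    width: int = 64
    appearance_noise: float = 0.5
    motion_noise: float = 0.3


class ModelSection(_Strict):
    backbone1: str = "tiny"
    backbone2: str = "tiny"


class TrainSection(_Strict):
    momentum: float = 0.9
    batch_size: int = 16
    learning_rate: float = 0.001
    alpha: float = 0.5
    epochs: int = 500
    kl_direction: str = "peer_to_self"
    kl_weight: float = 1.0
    mutual: bool = True
    update_scheme: str = "simultaneous"


class FusionSection(_Strict):
    w_rgb: float = 0.5
    student_pairing: str = "by_index"


class OutputSection(_Strict):
    dir: str = "runs/tsml"


class ExperimentCellSection(_Strict):
    backbone1: str
    backbone2: str | None = None
    mutual: bool = True


class RunConfig(_Strict):
    seed: int = 0
    data: DataSection = Field(default_factory=DataSection)
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    fusion: FusionSection = Field(default_factory=FusionSection)
    output: OutputSection = Field(default_factory=OutputSection)
    experiments: list[ExperimentCellSection] = Field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls.model_validate(raw)
        except Exception as exc:  # noqa: BLE001
            raise ConfigurationError(f"invalid config {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    # -- adapters to the library dataclasses ------------------------------

    def io_config(self) -> IOConfig:
        d = self.data
        return IOConfig(
            height=d.height, width=d.width, flow_depth=d.flow_depth,
            flow_method=d.flow_method, flow_clip=d.flow_clip,
            rgb_frames=d.rgb_frames, cache_dir=d.cache_dir,
        )

    def generator_config(self) -> GeneratorConfig:
        s = self.synthetic
        sigs = tuple(
            ClassSignature(c.name, c.texture_id, c.motion_id,
                           appearance_noise=s.appearance_noise,
                           motion_noise=s.motion_noise)
            for c in default_signatures(s.num_classes)
        )
        return GeneratorConfig(
            num_classes=s.num_classes, clips_per_class=s.clips_per_class,
            frames_per_clip=s.frames_per_clip, fps=s.fps,
            height=s.height, width=s.width, seed=self.seed, signatures=sigs,
        )

    def train_config(self) -> TrainConfig:
        t = self.train
        return TrainConfig(
            momentum=t.momentum, batch_size=t.batch_size,
            learning_rate=t.learning_rate, alpha=t.alpha, epochs=t.epochs,
            seed=self.seed, kl_direction=t.kl_direction, kl_weight=t.kl_weight,
            mutual=t.mutual, update_scheme=t.update_scheme,
            backbones=(self.model.backbone1, self.model.backbone2),
        )
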