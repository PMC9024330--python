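"""Shared pipeline configuration with ``paper`` and ``desk`` profiles.

The ``paper`` profile carries the published constants (eta0 = 0.002,
N = 200, beta = 0.9, short side 1024, crop 800, alpha = 0.5, 5 folds,
pyramid bins 1/2/3/6, deep residual backbone); the ``desk`` profile is the
CPU-scale twin used by the tests (96 px cores, 64 px crops, tiny backbone).
Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .model import LossConfig, SegModelConfig
from .training import TrainingSchedule

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    profile: str = "desk"
    seed: int = 0
    out_dir: str = "runs/desk"
    n_cores: int = 12
    image_size: int = 96
    short_side: int = 96
    crop: int = 64
    batch_size: int = 2
    epochs: int = 6
    k_folds: int = 5
    fusion_tol: float = 1e-6
    fusion_max_iter: int = 100
    model: SegModelConfig = field(default_factory=SegModelConfig)
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    loss: LossConfig = field(default_factory=LossConfig)

    @classmethod
    def paper_profile(cls) -> "PipelineConfig":
        return cls(
            profile="paper", out_dir="runs/paper", n_cores=224, image_size=1024,
            short_side=1024, crop=800, batch_size=8, epochs=200, k_folds=5,
            model=SegModelConfig(backbone_depth="resnet101-like",
                                 backbone_channels=64, output_stride=8),
            schedule=TrainingSchedule(eta0=0.002, total_rounds=200, beta=0.9),
            loss=LossConfig(alpha=0.5))

    @classmethod
    def desk_profile(cls) -> "PipelineConfig":
        return cls()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "model" in d:
            d["model"] = SegModelConfig.from_dict(d["model"])
        if "schedule" in d:
            d["schedule"] = TrainingSchedule(**d["schedule"])
        if "loss" in d:
            d["loss"] = LossConfig(**d["loss"])
        return cls(**d)


def save_config(cfg: PipelineConfig, path: str | Path):
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))
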