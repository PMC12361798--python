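"""Agent configuration: thresholds, checkpoint paths and training knobs.

Serialised as YAML; every threshold is validated against its documented
range, and serialisation round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field


class PhaseTrainSettings(BaseModel):
    epochs: int = Field(5, ge=1)
    lr: float = Field(3e-3, gt=0)
    batch_size: int = Field(32, ge=1)
    input_size: int = Field(64, ge=16)
    augment_flip: bool = True


class SegTrainSettings(BaseModel):
    epochs: int = Field(10, ge=1)
    lr: float = Field(2e-3, gt=0)
    lr_ratio_k: float = Field(1.0, gt=0)
    class_weights: tuple[float, float, float, float] = (0.5, 1.0, 1.0, 3.0)
    batch_size: int = Field(8, ge=1)
    input_size: int = Field(96, ge=32)
    width: int = Field(12, ge=2)


class HeatmapTrainSettings(BaseModel):
    epochs: int = Field(15, ge=1)
    lr: float = Field(3e-3, gt=0)
    batch_size: int = Field(8, ge=1)
    input_size: int = Field(128, ge=32)
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 2.0)


class AgentConfig(BaseModel):
    """Everything the end-to-end agent needs to run."""

    phase_main_checkpoint: str = "models/phase_main.npz"
    phase_secondary_checkpoint: str = "models/phase_secondary.npz"
    segmenter_checkpoint: str = "models/segmenter.npz"
    heatmap_checkpoint: str = "models/heatmap.npz"

    c_threshold: float = Field(0.4, ge=0.0, le=1.0)  # active-if constant C
    min_area: int = Field(1, ge=1)  # frame rule: MVP pixels for a positive frame
    patient_threshold: float = Field(0.5, ge=0.0, le=1.0)  # strict > on proportion
    belt_width: int = Field(3, ge=0)
    seed: int = 0

    phase_train: PhaseTrainSettings = PhaseTrainSettings()
    seg_train: SegTrainSettings = SegTrainSettings()
    heatmap_train: HeatmapTrainSettings = HeatmapTrainSettings()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AgentConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})
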