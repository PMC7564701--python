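"""Pipeline configuration: one YAML file covering every stage.

All defaults equal the published operating point of the method: a 7-frame
window on 500x500 frames, 100x100 ROIs, the (90,50,30)-(255,255,255)
background window, Adam at learning rate 0.01 with batch 256 for 10
epochs, a 7:3 train/validation split, and 10-frame persistence at 25 fps.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classifier import ModelSpec, TrainConfig
from .ethogram import SegmenterConfig
from .features import FeatureConfig
from .imaging import ColorThreshold

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    segmenter: SegmenterConfig = field(default_factory=SegmenterConfig)
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.model.input_size != self.features.roi:
            raise ValueError(
                f"model input size {self.model.input_size} must equal the "
                f"feature ROI size {self.features.roi}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        feat = dict(raw.get("features", {}))
        if "threshold" in feat:
            thr = feat["threshold"]
            feat["threshold"] = ColorThreshold(
                low=tuple(thr["low"]), high=tuple(thr["high"])
            )
        model = dict(raw.get("model", {}))
        if "conv_filters" in model:
            model["conv_filters"] = tuple(model["conv_filters"])
        return cls(
            features=FeatureConfig(**feat),
            model=ModelSpec(**model),
            train=TrainConfig(**raw.get("train", {})),
            segmenter=SegmenterConfig(**raw.get("segmenter", {})),
            train_fraction=raw.get("train_fraction", 0.7),
            seed=raw.get("seed", 0),
        )

    def to_yaml(self, path: str | Path) -> None:
        feat = asdict(self.features)
        feat["threshold"] = {
            "low": list(self.features.threshold.low),
            "high": list(self.features.threshold.high),
        }
        model = asdict(self.model)
        model["conv_filters"] = list(self.model.conv_filters)
        data = {
            "features": feat,
            "model": model,
            "train": asdict(self.train),
            "segmenter": asdict(self.segmenter),
            "train_fraction": self.train_fraction,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
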