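"""Pipeline configuration: one validated record of every tunable."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the segmentation pipeline with their defaults.

    The defaults are the operating point of the method: similarity
    threshold 0.81 for asymmetry flagging, background cut at mean
    brightness 5, annotation threshold 0.5, K grid 10..450 step 10 with
    the 90% merge rule, 10 SLIC iterations, texture quantization at
    {8, 16, 32, 64} levels in 4 directions, 4 Otsu channels, a 5-tree
    random forest, 5-fold CV and an 80/20 train split.
    """

    similarity_threshold: float = 0.81
    background_threshold: float = 5.0
    annotation_threshold: float = 0.5
    k_min: int = 10
    k_max: int = 450
    k_step: int = 10
    merge_ratio: float = 0.9
    plateau_epsilon: float = 0.01
    iterations: int = 10
    quant_levels: tuple = (8, 16, 32, 64)
    directions: tuple = (0, 45, 90, 135)
    otsu_channels: int = 4
    rf_trees: int = 5
    cv_folds: int = 5
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.similarity_threshold <= 1.0):
            raise ValueError("similarity_threshold must lie in (0, 1]")
        if self.background_threshold < 0:
            raise ValueError("background_threshold must be non-negative")
        if not (0.0 < self.annotation_threshold <= 1.0):
            raise ValueError("annotation_threshold must lie in (0, 1]")
        if not (0 < self.k_min <= self.k_max) or self.k_step < 1:
            raise ValueError("invalid K grid")
        if not (0.0 < self.merge_ratio < 1.0):
            raise ValueError("merge_ratio must lie in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.rf_trees < 1 or self.cv_folds < 2 or self.otsu_channels < 2:
            raise ValueError("invalid model parameters")
        self.quant_levels = tuple(int(v) for v in self.quant_levels)
        self.directions = tuple(int(v) for v in self.directions)

    @property
    def k_grid(self) -> tuple[int, ...]:
        return tuple(range(self.k_min, self.k_max + 1, self.k_step))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["quant_levels"] = list(self.quant_levels)
        d["directions"] = list(self.directions)
        return d

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**obj)

    @classmethod
    def load(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        return cls.from_dict(obj)
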