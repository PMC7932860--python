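"""Workflow configuration: YAML-backed, validated, reproducibly seeded.

One :class:`PipelineConfig` describes a complete run: synthetic dataset
geometry, augmentation, both segmentation trainings, classifier training,
the decision threshold and the method-comparison settings.  A single global
seed expands into fixed per-stage seeds (global * 100 + stage offset) so any
stage can be reproduced in isolation; each stage seed can also be overridden
explicitly in the file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentationConfig
from .classifier import ClsTrainConfig, DecisionThreshold
from .errors import ParameterError
from .segmentation import SegTrainConfig
from .synthetic import SyntheticParams

__all__ = ["DatasetSpec", "ComparisonSpec", "PipelineConfig", "stage_seed"]

_STAGE_OFFSETS = {
    "synth": 1,
    "augment": 2,
    "seg_cell": 3,
    "seg_nucleus": 4,
    "classifier": 5,
    "quantify": 6,
    "compare": 7,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    if stage not in _STAGE_OFFSETS:
        raise ParameterError(f"unknown stage {stage!r}")
    return (int(global_seed) * 100 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass(frozen=True)
class DatasetSpec:
    """How much synthetic data each stage sees."""

    n_seg_cells: int = 200
    n_cls_cells: int = 1200
    smear_fractions: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
    cells_per_smear: int = 30
    #: expand the segmentation pool with the augmentation stage; off by
    #: default because the generator can produce unlimited fresh examples
    augment_segmentation: bool = False

    def __post_init__(self) -> None:
        if self.n_seg_cells < 2 or self.n_cls_cells < 2 or self.cells_per_smear < 1:
            raise ParameterError("dataset sizes must be positive")
        if any(not 0.0 <= f <= 1.0 for f in self.smear_fractions):
            raise ParameterError("smear fractions must lie in [0, 1]")


@dataclass(frozen=True)
class ComparisonSpec:
    """Method-comparison settings, incl. the simulated manual raters."""

    bootstrap_samples: int = 999
    manual_noise_sd: float = 2.0  # percentage points per simulated rater

    def __post_init__(self) -> None:
        if self.bootstrap_samples < 1 or self.manual_noise_sd < 0:
            raise ParameterError("invalid comparison settings")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "vacuoquant_run"
    synthetic: SyntheticParams = field(default_factory=lambda: SyntheticParams.for_image_size(64))
    dataset: DatasetSpec = field(default_factory=DatasetSpec)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    seg_cell: SegTrainConfig = field(default_factory=lambda: SegTrainConfig(target="cell"))
    seg_nucleus: SegTrainConfig = field(default_factory=lambda: SegTrainConfig(target="nucleus"))
    classifier: ClsTrainConfig = field(default_factory=ClsTrainConfig)
    threshold: DecisionThreshold = field(default_factory=DecisionThreshold)
    comparison: ComparisonSpec = field(default_factory=ComparisonSpec)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, key, **extra):
            block = dict(raw.get(key) or {})
            block.update(extra)
            for name, value in block.items():
                if isinstance(value, list):
                    block[name] = tuple(value)
            try:
                return klass(**block)
            except TypeError as exc:
                raise ParameterError(f"invalid {key} block: {exc}") from exc

        seed = int(raw.get("seed", 0))
        synth_block = dict(raw.get("synthetic") or {})
        image_size = int(synth_block.pop("image_size", 64))
        for name, value in synth_block.items():
            if isinstance(value, list):
                synth_block[name] = tuple(value)
        return cls(
            seed=seed,
            out_dir=str(raw.get("out_dir", "vacuoquant_run")),
            synthetic=SyntheticParams.for_image_size(
                image_size, seed=stage_seed(seed, "synth"), **synth_block
            ),
            dataset=build(DatasetSpec, "dataset"),
            augmentation=build(AugmentationConfig, "augmentation",
                               seed=stage_seed(seed, "augment")),
            seg_cell=build(SegTrainConfig, "seg_cell", target="cell",
                           seed=stage_seed(seed, "seg_cell")),
            seg_nucleus=build(SegTrainConfig, "seg_nucleus", target="nucleus",
                              seed=stage_seed(seed, "seg_nucleus")),
            classifier=build(ClsTrainConfig, "classifier",
                             seed=stage_seed(seed, "classifier")),
            threshold=build(DecisionThreshold, "threshold"),
            comparison=build(ComparisonSpec, "comparison"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ParameterError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
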