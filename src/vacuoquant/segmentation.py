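"""Training and inference for the cell- and nucleus-mask segmentation models.

Two independent single-target U-Net models (one for the whole-cell boundary,
one for the nucleus) are trained with a soft-dice loss on synthetic crops
with ground-truth masks, evaluated by mean dice over a held-out validation
split, and combined at inference time: cytoplasm = predicted cell mask minus
predicted nucleus mask, applied to the image by blacking out everything else.
An empty predicted cell or cytoplasm mask raises a segmentation failure so
the affected cell can be excluded (and counted) downstream rather than fed to
the classifier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import masks as mask_ops
from .errors import (
    DataError,
    ParameterError,
    SegmentationFailureError,
    ShapeError,
)
from .masks import BinaryMask
from .nn import Adam, UNet, soft_dice_loss
from .synthetic import CellImage

__all__ = [
    "SegTrainConfig",
    "SegModelBundle",
    "split_dataset",
    "train_segmenter",
    "predict_mask",
    "predict_masks",
    "mask_with_predicted_cytoplasm",
    "segment_cytoplasm",
]

_TARGET_ATTR = {"cell": "cell_mask", "nucleus": "nucleus_mask"}


@dataclass(frozen=True)
class SegTrainConfig:
    """Hyperparameters of one segmentation training run.

    ``target`` selects which ground-truth mask is learned.  The default
    architecture scale (depth 3, 16 base filters) trains on one CPU in
    minutes at 64-128 px crops.
    """

    target: str = "cell"
    split_fraction: float = 0.8
    epochs: int = 18
    batch_size: int = 8
    learning_rate: float = 1e-3
    binarization_threshold: float = 0.5
    depth: int = 3
    base_filters: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target not in _TARGET_ATTR:
            raise ParameterError(f"target must be one of {sorted(_TARGET_ATTR)}")
        if not 0.0 < self.split_fraction < 1.0:
            raise ParameterError("split_fraction must lie in (0, 1)")
        if not 0.0 < self.binarization_threshold < 1.0:
            raise ParameterError("binarization_threshold must lie in (0, 1)")
        if self.batch_size < 1 or self.base_filters < 1 or self.depth < 2:
            raise ParameterError("invalid architecture/batch configuration")


@dataclass
class SegModelBundle:
    """A trained segmenter: network, config, history and validation dice."""

    model: UNet
    config: SegTrainConfig
    history: list[dict] = field(default_factory=list)
    validation_dice: float = float("nan")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", *self.model.state_arrays())
        sidecar = {
            "kind": "segmenter",
            "config": asdict(self.config),
            "validation_dice": self.validation_dice,
            "history": self.history,
        }
        (directory / "bundle.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "SegModelBundle":
        directory = Path(directory)
        sidecar = json.loads((directory / "bundle.json").read_text())
        config = SegTrainConfig(**sidecar["config"])
        model = UNet(
            base_filters=config.base_filters, depth=config.depth, seed=config.seed
        )
        with np.load(directory / "weights.npz") as data:
            model.load_state_arrays([data[k] for k in data.files])
        return cls(
            model=model,
            config=config,
            history=sidecar["history"],
            validation_dice=float(sidecar["validation_dice"]),
        )


def split_dataset(examples: Sequence, split_fraction: float, seed: int) -> tuple[list, list]:
    """Random disjoint train/validation split; train size = floor(n * fraction)."""
    n = len(examples)
    if n < 2:
        raise ParameterError("need at least 2 examples to split")
    if not 0.0 < split_fraction < 1.0:
        raise ParameterError("split_fraction must lie in (0, 1)")
    n_train = int(np.floor(n * split_fraction))
    if n_train < 1:
        raise ParameterError("split leaves no training examples")
    order = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5711])).permutation(n)
    train = [examples[i] for i in order[:n_train]]
    val = [examples[i] for i in order[n_train:]]
    return train, val


def _stack_images(examples: Sequence[CellImage]) -> np.ndarray:
    return np.stack([np.moveaxis(ex.pixels, -1, 0) for ex in examples]).astype(np.float32)


def _stack_targets(examples: Sequence[CellImage], attr: str) -> np.ndarray:
    return np.stack(
        [getattr(ex, attr).grid[None].astype(np.float32) for ex in examples]
    )


def train_segmenter(examples: Sequence[CellImage], config: SegTrainConfig) -> SegModelBundle:
    """Train a single-target U-Net and report mean validation dice.

    Training minimizes 1 − soft dice with Adam; the per-epoch history records
    the training loss and the mean validation dice of the binarized masks.
    """
    if config.epochs < 1:
        raise ParameterError("epochs must be >= 1: no training would be performed")
    attr = _TARGET_ATTR[config.target]
    missing = [i for i, ex in enumerate(examples) if getattr(ex, attr) is None]
    if missing:
        raise DataError(f"{len(missing)} examples lack the {config.target} ground-truth mask")

    train, val = split_dataset(list(examples), config.split_fraction, config.seed)
    x_train, y_train = _stack_images(train), _stack_targets(train, attr)
    x_val = _stack_images(val)
    val_masks = [getattr(ex, attr) for ex in val]

    model = UNet(base_filters=config.base_filters, depth=config.depth, seed=config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    epoch_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE90C]))
    history: list[dict] = []
    n = len(train)
    for epoch in range(config.epochs):
        order = epoch_rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            probs = model.forward(x_train[idx])
            loss = soft_dice_loss(probs, y_train[idx])
            if not np.isfinite(loss.data):
                raise ArithmeticError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_dice = _mean_validation_dice(model, x_val, val_masks, config.binarization_threshold)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_dice": val_dice}
        )
    return SegModelBundle(
        model=model, config=config, history=history, validation_dice=history[-1]["val_dice"]
    )


def _mean_validation_dice(
    model: UNet, x_val: np.ndarray, val_masks: list[BinaryMask], threshold: float
) -> float:
    scores = []
    for start in range(0, len(x_val), 16):
        probs = model.forward(x_val[start : start + 16]).data
        for j in range(probs.shape[0]):
            pred = BinaryMask(probs[j, 0] >= threshold)
            truth = val_masks[start + j]
            if pred.is_empty and truth.is_empty:
                continue
            if pred.is_empty or truth.is_empty:
                scores.append(0.0)
            else:
                scores.append(mask_ops.dice(pred, truth).value)
    return float(np.mean(scores)) if scores else float("nan")


def predict_masks(bundle: SegModelBundle, images: Sequence[CellImage],
                  batch_size: int = 16) -> list[BinaryMask]:
    """Batched mask prediction for a sequence of equally sized images."""
    f = bundle.model.pool_factor
    for image in images:
        h, w = image.shape
        if h % f or w % f:
            raise ShapeError(
                f"image size {(h, w)} incompatible with the architecture (needs % {f} == 0)"
            )
    out: list[BinaryMask] = []
    x = _stack_images(images)
    thr = bundle.config.binarization_threshold
    for start in range(0, len(images), batch_size):
        probs = bundle.model.forward(x[start : start + batch_size]).data
        out.extend(BinaryMask(probs[j, 0] >= thr) for j in range(probs.shape[0]))
    return out


def predict_mask(bundle: SegModelBundle, image: CellImage) -> BinaryMask:
    """Probability map of the bundle's target, binarized at its threshold."""
    return predict_masks(bundle, [image])[0]


def mask_with_predicted_cytoplasm(
    cell_bundle: SegModelBundle,
    nucleus_bundle: SegModelBundle,
    images: Sequence[CellImage],
) -> list[CellImage | None]:
    """Batched cytoplasm masking with the trained segmenters.

    Returns one predicted-cytoplasm-masked image per input, or ``None`` where
    segmentation failed (empty cell or cytoplasm mask).  Used to prepare
    classifier training data the same way inference-time data is prepared,
    so the classifier sees segmentation artifacts during training.
    """
    cell_masks = predict_masks(cell_bundle, images)
    nucleus_masks = predict_masks(nucleus_bundle, images)
    out: list[CellImage | None] = []
    for image, cmask, nmask in zip(images, cell_masks, nucleus_masks):
        if cmask.is_empty:
            out.append(None)
            continue
        cyto = mask_ops.cytoplasm_mask(cmask, nmask)
        out.append(None if cyto.is_empty else mask_ops.apply_mask(image, cyto))
    return out


def segment_cytoplasm(
    cell_bundle: SegModelBundle,
    nucleus_bundle: SegModelBundle,
    image: CellImage,
) -> tuple[BinaryMask, CellImage]:
    """Predict cell and nucleus masks, subtract, and black out the rest.

    Raises :class:`SegmentationFailureError` when the predicted cell mask or
    the resulting cytoplasm mask is empty; callers count such cells as
    excluded instead of classifying them.
    """
    cell_mask = predict_mask(cell_bundle, image)
    if cell_mask.is_empty:
        raise SegmentationFailureError("predicted cell mask is empty")
    nucleus_mask = predict_mask(nucleus_bundle, image)
    cyto = mask_ops.cytoplasm_mask(cell_mask, nucleus_mask)
    if cyto.is_empty:
        raise SegmentationFailureError("predicted cytoplasm mask is empty")
    return cyto, mask_ops.apply_mask(image, cyto)
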