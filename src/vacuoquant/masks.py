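"""Binary masks and the mask-level operations of the pipeline.

Masks follow one coordinate convention throughout the package: row-major
arrays, origin at the top-left corner, 0-based indices.  On disk a mask is an
8-bit grayscale PNG with 0 = background and 255 = foreground; on read any
pixel >= 128 counts as foreground so the round trip is robust to resampling
artifacts introduced by other imaging tools.

The cytoplasm mask of a leukocyte is constructed by subtracting the nucleus
mask from the whole-cell mask, and segmentation quality is scored with the
dice similarity coefficient

    dice = 2 * |A ∩ B| / (|A| + |B|)

where |A| and |B| are the foreground pixel counts of the two masks: 0 means
no spatial overlap and 1 means identical masks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from PIL import Image

from .errors import EmptyMaskError, ShapeError

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import CellImage

__all__ = [
    "BinaryMask",
    "DiceScore",
    "dice",
    "cytoplasm_mask",
    "apply_mask",
]


@dataclass(frozen=True)
class BinaryMask:
    """A strictly two-valued 2-D pixel field aligned to an image."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2 or grid.shape[0] < 1 or grid.shape[1] < 1:
            raise ShapeError(f"mask grid must be 2-D and non-empty, got shape {grid.shape}")
        object.__setattr__(self, "grid", grid.astype(bool, copy=False))

    @property
    def height(self) -> int:
        return int(self.grid.shape[0])

    @property
    def width(self) -> int:
        return int(self.grid.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())

    @property
    def is_empty(self) -> bool:
        return not bool(self.grid.any())

    @classmethod
    def from_array(cls, array: np.ndarray, threshold: float = 128.0) -> "BinaryMask":
        """Binarize an intensity array; values >= ``threshold`` are foreground."""
        return cls(np.asarray(array) >= threshold)

    @classmethod
    def read_png(cls, path: str | Path) -> "BinaryMask":
        with Image.open(path) as img:
            arr = np.asarray(img.convert("L"))
        return cls.from_array(arr)

    def write_png(self, path: str | Path) -> None:
        Image.fromarray(np.where(self.grid, 255, 0).astype(np.uint8), mode="L").save(path)

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_shape(self, other)
        return BinaryMask(self.grid & other.grid)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_shape(self, other)
        return BinaryMask(self.grid | other.grid)

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(~self.grid)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(np.array_equal(self.grid, other.grid))


@dataclass(frozen=True)
class DiceScore:
    """Dice similarity with the raw pixel counts that produced it."""

    value: float
    overlap_pixels: int
    total_pixels: int

    def __post_init__(self) -> None:
        if self.total_pixels > 0:
            expected = 2.0 * self.overlap_pixels / self.total_pixels
            if abs(self.value - expected) > 1e-12:
                raise ValueError("dice value inconsistent with pixel counts")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"dice value {self.value} outside [0, 1]")


def _check_same_shape(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")


def dice(a: BinaryMask, b: BinaryMask) -> DiceScore:
    """Dice similarity coefficient between two binary masks.

    Raises
    ------
    ShapeError
        If the masks have different dimensions.
    EmptyMaskError
        If both masks are empty; an empty predicted mask signals a
        segmentation failure and must surface rather than score silently.
    """
    _check_same_shape(a, b)
    total = a.foreground_count + b.foreground_count
    if total == 0:
        raise EmptyMaskError("dice undefined: both masks have no foreground")
    overlap = int((a.grid & b.grid).sum())
    return DiceScore(value=2.0 * overlap / total, overlap_pixels=overlap, total_pixels=total)


def cytoplasm_mask(cell: BinaryMask, nucleus: BinaryMask) -> BinaryMask:
    """Cytoplasm = cell foreground minus nucleus foreground."""
    _check_same_shape(cell, nucleus)
    return BinaryMask(cell.grid & ~nucleus.grid)


def apply_mask(image: "CellImage", mask: BinaryMask) -> "CellImage":
    """Black out every pixel outside the mask foreground, all channels.

    Returns a new image; pixels inside the mask keep their original values.
    Used to restrict the classifier's view to the cytoplasm.
    """
    pixels = image.pixels
    if pixels.shape[:2] != mask.shape:
        raise ShapeError(
            f"image spatial shape {pixels.shape[:2]} does not match mask {mask.shape}"
        )
    masked = np.where(mask.grid[:, :, None], pixels, 0.0).astype(pixels.dtype)
    return dataclasses.replace(image, pixels=masked)
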