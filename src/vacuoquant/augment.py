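"""Geometric augmentation of labeled cell images and their masks.

Expands a training set by a fixed multiplicative factor using five transform
families — rotation, shifting, shearing, zooming and flipping — drawn
uniformly within configurable ranges.  Every transform is applied jointly to
the image and all attached ground-truth masks: bilinear interpolation for the
image, nearest-neighbor for masks so they stay strictly binary and their
subset relations (nucleus ⊂ cell, vacuoles ⊂ cytoplasm) survive unchanged.

Out-of-frame regions created by shifts and zooms are filled with the image's
own background color, estimated from its border pixels; masks are filled with
background (False).  The augmented output consists of ``factor`` transformed
copies per original; originals are not separately included, so n inputs yield
exactly n x factor examples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

from .errors import ParameterError
from .masks import BinaryMask
from .synthetic import CellImage

__all__ = ["AugmentationConfig", "augment_example", "augment_dataset"]


@dataclass(frozen=True)
class AugmentationConfig:
    """Ranges for the five transform families; all draws are uniform."""

    factor: int = 20
    rotation_max_deg: float = 30.0
    shift_max_fraction: float = 0.10
    shear_max_deg: float = 10.0
    zoom_range: tuple[float, float] = (0.9, 1.1)
    allow_horizontal_flip: bool = True
    allow_vertical_flip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ParameterError("factor must be >= 1")
        zmin, zmax = self.zoom_range
        if not (0 < zmin <= zmax):
            raise ParameterError("zoom_range must satisfy 0 < min <= max")
        if self.rotation_max_deg < 0 or self.shear_max_deg < 0 or self.shift_max_fraction < 0:
            raise ParameterError("transform ranges must be non-negative")


def _border_color(pixels: np.ndarray) -> np.ndarray:
    border = np.concatenate(
        [pixels[0], pixels[-1], pixels[:, 0], pixels[:, -1]], axis=0
    )
    return np.median(border, axis=0)


def augment_example(image: CellImage, config: AugmentationConfig, seed: int) -> CellImage:
    """One randomly transformed copy of a cell image and its masks.

    Deterministic in ``(config.seed, seed)``; the label and subject id are
    preserved untouched.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, int(seed), 0xA06]))
    h, w = image.shape
    angle = np.deg2rad(rng.uniform(-config.rotation_max_deg, config.rotation_max_deg))
    shear = np.deg2rad(rng.uniform(-config.shear_max_deg, config.shear_max_deg))
    zoom = rng.uniform(*config.zoom_range)
    shift = rng.uniform(-config.shift_max_fraction, config.shift_max_fraction, size=2) * (w, h)
    flip_h = config.allow_horizontal_flip and bool(rng.integers(2))
    flip_v = config.allow_vertical_flip and bool(rng.integers(2))

    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tform = (
        AffineTransform(translation=-center)
        + AffineTransform(rotation=angle, shear=shear, scale=(zoom, zoom))
        + AffineTransform(translation=center + shift)
    )
    inv = tform.inverse

    pixels = image.pixels
    if flip_h:
        pixels = pixels[:, ::-1]
    if flip_v:
        pixels = pixels[::-1]
    fill = _border_color(pixels)
    warped = np.empty_like(pixels, dtype=np.float64)
    for c in range(3):
        warped[:, :, c] = warp(
            pixels[:, :, c].astype(np.float64), inv, order=1, cval=float(fill[c]),
            preserve_range=True,
        )
    warped = warped.astype(pixels.dtype)

    def warp_mask(mask: BinaryMask | None) -> BinaryMask | None:
        if mask is None:
            return None
        grid = mask.grid
        if flip_h:
            grid = grid[:, ::-1]
        if flip_v:
            grid = grid[::-1]
        out = warp(grid.astype(np.float64), inv, order=0, cval=0.0, preserve_range=True)
        return BinaryMask(out > 0.5)

    return dataclasses.replace(
        image,
        pixels=warped,
        cell_mask=warp_mask(image.cell_mask),
        nucleus_mask=warp_mask(image.nucleus_mask),
        vacuole_mask=warp_mask(image.vacuole_mask),
    )


def augment_dataset(images: list[CellImage], config: AugmentationConfig) -> list[CellImage]:
    """``factor`` transformed copies per input image, in source order.

    Output index ``i * factor + j`` is the j-th augmented copy of input i, so
    every example is traceable to its source.
    """
    if not images:
        raise ParameterError("augment_dataset requires a non-empty input list")
    out: list[CellImage] = []
    for i, image in enumerate(images):
        for j in range(config.factor):
            out.append(augment_example(image, config, seed=i * config.factor + j))
    return out
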