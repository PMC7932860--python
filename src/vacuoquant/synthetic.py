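"""Synthetic stained-lymphocyte image generator with pixel-perfect ground truth.

Emulates single-cell crops as produced by digital morphology analyzers from
May-Grünwald-Giemsa stained peripheral blood smears: a roughly circular cell
on a pale background, a large dark nucleus occupying most of the cell, a thin
pale-blue cytoplasm rim, and — in vacuolated lymphocytes — small round pale
clearings confined to the cytoplasm.  Every generated cell carries exact
cell / nucleus / vacuole masks, so segmentation and classification models can
be trained and scored without any patient material.

The generator is deliberately simple: radially perturbed discs for cell and
nucleus, discs for vacuoles, one mean color per compartment plus slight
per-cell color jitter, Gaussian blur for soft compartment edges and additive
Gaussian pixel noise.  It makes no attempt at photorealistic stain texture.

Reproducibility: one global seed expands into per-smear and per-cell seeds
through a fixed counter scheme (`numpy.random.SeedSequence`), so identical
parameters always reproduce bit-identical images and manifests, including
under partial regeneration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import ParameterError
from .masks import BinaryMask

__all__ = [
    "StainPalette",
    "SyntheticParams",
    "CellImage",
    "generate_cell",
    "generate_smear",
    "generate_dataset",
]

LABEL_VACUOLATED = "vacuolated"
LABEL_HEALTHY = "healthy"

#: fraction of the image side used as maximum cell-center jitter
_CENTER_JITTER_FRACTION = 0.03


@dataclass(frozen=True)
class StainPalette:
    """Mean RGB color (in [0,1]) per compartment of the stained crop."""

    background: tuple[float, float, float] = (0.93, 0.92, 0.95)
    cytoplasm: tuple[float, float, float] = (0.62, 0.70, 0.85)
    nucleus: tuple[float, float, float] = (0.33, 0.22, 0.46)
    vacuole: tuple[float, float, float] = (0.90, 0.91, 0.95)


@dataclass(frozen=True)
class SyntheticParams:
    """Generative knobs for synthetic stained-cell crops.

    Defaults describe a 128 px crop; :meth:`for_image_size` rescales all
    pixel-valued geometry proportionally for other crop sizes.
    """

    image_size: int = 128
    cell_radius_range: tuple[float, float] = (34.0, 46.0)
    nucleus_area_fraction_range: tuple[float, float] = (0.45, 0.62)
    vacuole_count_range: tuple[int, int] = (1, 4)
    vacuole_radius_range: tuple[float, float] = (3.0, 6.0)
    boundary_irregularity: float = 0.08
    stain_palette: StainPalette = field(default_factory=StainPalette)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.image_size < 16:
            raise ParameterError("image_size must be at least 16 pixels")
        for name in ("cell_radius_range", "vacuole_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ParameterError(f"{name} must satisfy 0 < min <= max, got {(lo, hi)}")
        lo, hi = self.nucleus_area_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ParameterError("nucleus_area_fraction_range must lie within (0, 1)")
        cmin, cmax = self.vacuole_count_range
        if cmin < 1 or cmin > cmax:
            raise ParameterError("vacuole_count_range must satisfy 1 <= min <= max")
        if self.boundary_irregularity < 0:
            raise ParameterError("boundary_irregularity must be non-negative")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        max_extent = (
            self.cell_radius_range[1] * (1.0 + self.boundary_irregularity)
            + _CENTER_JITTER_FRACTION * self.image_size
        )
        if max_extent >= self.image_size / 2:
            raise ParameterError(
                "cell cannot fit: max radius plus perturbation exceeds half the image size"
            )

    @classmethod
    def for_image_size(cls, image_size: int, **overrides) -> "SyntheticParams":
        """Defaults with all pixel-valued geometry scaled to ``image_size``."""
        s = image_size / 128.0
        base = dict(
            image_size=image_size,
            cell_radius_range=(34.0 * s, 46.0 * s),
            vacuole_radius_range=(max(1.5, 3.0 * s), max(2.0, 6.0 * s)),
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class CellImage:
    """An RGB single-cell crop with optional ground-truth masks and label."""

    pixels: np.ndarray
    cell_mask: BinaryMask | None = None
    nucleus_mask: BinaryMask | None = None
    vacuole_mask: BinaryMask | None = None
    label: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        if pixels.ndim != 3 or pixels.shape[2] != 3:
            raise ParameterError(f"pixels must be H x W x 3, got shape {pixels.shape}")
        object.__setattr__(self, "pixels", pixels)
        shape = pixels.shape[:2]
        for name in ("cell_mask", "nucleus_mask", "vacuole_mask"):
            mask = getattr(self, name)
            if mask is not None and mask.shape != shape:
                raise ParameterError(f"{name} shape {mask.shape} != image shape {shape}")
        if self.label is not None and self.label not in (LABEL_VACUOLATED, LABEL_HEALTHY):
            raise ParameterError(f"unknown label {self.label!r}")
        if self.nucleus_mask is not None and self.cell_mask is not None:
            if (self.nucleus_mask.grid & ~self.cell_mask.grid).any():
                raise ParameterError("nucleus mask extends outside the cell mask")
        if (
            self.vacuole_mask is not None
            and self.cell_mask is not None
            and self.nucleus_mask is not None
        ):
            cyto = self.cell_mask.grid & ~self.nucleus_mask.grid
            if (self.vacuole_mask.grid & ~cyto).any():
                raise ParameterError("vacuole mask extends outside the cytoplasm")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def write_png(self, path: str | Path) -> None:
        arr = np.clip(np.asarray(self.pixels, dtype=np.float64) * 255.0, 0, 255)
        Image.fromarray(arr.round().astype(np.uint8), mode="RGB").save(path)

    @classmethod
    def read_png(cls, path: str | Path, **fields) -> "CellImage":
        with Image.open(path) as img:
            arr = np.asarray(img.convert("RGB"), dtype=np.float32) / 255.0
        return cls(pixels=arr, **fields)


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def _perturbed_disc(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    irregularity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rasterize a disc whose boundary radius varies smoothly with angle."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    dist = np.hypot(dy, dx)
    if irregularity <= 0:
        return dist <= radius
    theta = np.arctan2(dy, dx)
    harmonics = np.arange(2, 6)
    amps = rng.uniform(-1.0, 1.0, size=harmonics.size)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=harmonics.size)
    norm = np.abs(amps).sum()
    if norm == 0:
        return dist <= radius
    pert = np.zeros_like(dist)
    for k, a, p in zip(harmonics, amps / norm, phases):
        pert += a * np.cos(k * theta + p)
    return dist <= radius * (1.0 + irregularity * pert)


def _place_vacuoles(
    cytoplasm: np.ndarray,
    count: int,
    radius_range: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Place non-overlapping vacuole discs fully inside the cytoplasm.

    Containment is decided with the exact Euclidean distance transform of the
    cytoplasm: a disc of radius r centered at c fits iff the distance from c
    to the cytoplasm boundary exceeds r.  A sampled radius that nowhere fits
    shrinks in 0.5 px steps; if even the minimum fails, the disc is placed at
    the deepest cytoplasm point with the largest radius that fits there, so a
    vacuolated cell always receives the most evident clearing its geometry
    allows.  Guarantees the vacuole ⊂ cytoplasm invariant by construction.
    """
    yy, xx = np.mgrid[0 : cytoplasm.shape[0], 0 : cytoplasm.shape[1]]
    vacuoles = np.zeros_like(cytoplasm)
    occupied_dist = np.full(cytoplasm.shape, np.inf)
    depth = ndimage.distance_transform_edt(cytoplasm)
    for _ in range(count):
        radius = float(rng.uniform(*radius_range))
        placed = False
        while not placed:
            admissible = (depth > radius + 0.5) & (occupied_dist > radius)
            centers = np.flatnonzero(admissible)
            if centers.size:
                cy, cx = np.unravel_index(centers[int(rng.integers(centers.size))],
                                          cytoplasm.shape)
            elif radius > 1.0:
                radius = max(1.0, radius - 0.5)
                continue
            else:
                # deepest reachable point; the largest disc that fits there
                pool = np.where(occupied_dist > 1.0, depth, 0.0)
                if pool.max() <= 1.0:
                    break
                cy, cx = np.unravel_index(int(pool.argmax()), pool.shape)
                radius = max(1.0, float(depth[cy, cx]) - 0.5)
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius
            vacuoles |= disc & cytoplasm
            d = np.hypot(yy - cy, xx - cx) - radius
            occupied_dist = np.minimum(occupied_dist, d)
            placed = True
    return vacuoles


def generate_cell(params: SyntheticParams, vacuolated: bool, seed: int) -> CellImage:
    """Generate one synthetic stained-cell crop with full ground truth.

    The cell and nucleus are radially perturbed discs; the nucleus is clipped
    to the 1-px-eroded cell so a cytoplasm rim always exists.  Vacuolated
    cells receive at least one round clearing strictly inside the cytoplasm.
    Identical ``(params, vacuolated, seed)`` give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, int(seed), 0x5EED]))
    n = params.image_size
    jitter = _CENTER_JITTER_FRACTION * n
    center = (
        n / 2.0 + rng.uniform(-jitter, jitter),
        n / 2.0 + rng.uniform(-jitter, jitter),
    )
    cell_radius = float(rng.uniform(*params.cell_radius_range))
    cell = _perturbed_disc((n, n), center, cell_radius, params.boundary_irregularity, rng)

    area_fraction = float(rng.uniform(*params.nucleus_area_fraction_range))
    nucleus_radius = cell_radius * np.sqrt(area_fraction)
    max_offset = max(0.0, (cell_radius - nucleus_radius) * 0.5)
    offset_angle = rng.uniform(0.0, 2.0 * np.pi)
    offset_mag = rng.uniform(0.0, max_offset)
    nucleus_center = (
        center[0] + offset_mag * np.sin(offset_angle),
        center[1] + offset_mag * np.cos(offset_angle),
    )
    nucleus = _perturbed_disc(
        (n, n), nucleus_center, nucleus_radius, params.boundary_irregularity, rng
    )
    # clip to the eroded cell: nucleus ⊂ cell with at least a 1-px rim
    nucleus &= ndimage.binary_erosion(cell, structure=_disk(1))
    cytoplasm = cell & ~nucleus

    if vacuolated:
        count = int(rng.integers(params.vacuole_count_range[0], params.vacuole_count_range[1] + 1))
        vacuoles = _place_vacuoles(cytoplasm, count, params.vacuole_radius_range, rng)
        if not vacuoles.any():
            # thin-rim fallback: a single minimal clearing wherever it fits
            admissible = ndimage.binary_erosion(cytoplasm, structure=_disk(1))
            pool = admissible if admissible.any() else cytoplasm
            idx = int(rng.integers(np.flatnonzero(pool).size))
            cy, cx = np.unravel_index(np.flatnonzero(pool)[idx], pool.shape)
            yy, xx = np.mgrid[0:n, 0:n]
            vacuoles = ((yy - cy) ** 2 + (xx - cx) ** 2 <= 1) & cytoplasm
    else:
        vacuoles = np.zeros_like(cell)

    palette = params.stain_palette
    img = np.empty((n, n, 3), dtype=np.float64)
    compartments = (
        (~cell, palette.background),
        (cytoplasm, palette.cytoplasm),
        (nucleus, palette.nucleus),
        (vacuoles, palette.vacuole),
    )
    for mask, color in compartments:
        shade = np.asarray(color) + rng.uniform(-0.02, 0.02, size=3)
        img[mask] = shade
    for c in range(3):
        img[:, :, c] = ndimage.gaussian_filter(img[:, :, c], sigma=0.6)
    img += rng.normal(0.0, params.noise_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)

    return CellImage(
        pixels=img.astype(np.float32),
        cell_mask=BinaryMask(cell),
        nucleus_mask=BinaryMask(nucleus),
        vacuole_mask=BinaryMask(vacuoles),
        label=LABEL_VACUOLATED if vacuolated else LABEL_HEALTHY,
    )


def generate_smear(
    n_cells: int,
    vacuolated_fraction: float,
    params: SyntheticParams,
    seed: int,
    smear_id: str = "smear_000",
) -> tuple[list[CellImage], pd.DataFrame]:
    """Generate one synthetic smear: a list of cells plus its manifest.

    Exactly ``round(n_cells * vacuolated_fraction)`` cells are vacuolated; the
    order is shuffled deterministically by the seed.  The manifest records
    smear_id, cell_id, file name, label and vacuole count per cell.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if not 0.0 <= vacuolated_fraction <= 1.0:
        raise ParameterError("vacuolated_fraction must lie in [0, 1]")
    n_vac = int(np.rint(n_cells * vacuolated_fraction))
    flags = np.zeros(n_cells, dtype=bool)
    flags[:n_vac] = True
    order_rng = np.random.default_rng(np.random.SeedSequence([params.seed, int(seed), 0x0DDE]))
    order_rng.shuffle(flags)

    cells: list[CellImage] = []
    rows = []
    for i, flag in enumerate(flags):
        cell_seed = int(seed) * 100_000 + i  # fixed counter scheme
        cell = generate_cell(params, vacuolated=bool(flag), seed=cell_seed)
        cell = dataclasses.replace(cell, subject_id=smear_id)
        cells.append(cell)
        cell_id = f"cell_{i:04d}"
        rows.append(
            {
                "smear_id": smear_id,
                "cell_id": cell_id,
                "file": f"{smear_id}/{cell_id}.png",
                "label": cell.label,
                "vacuole_count": _component_count(cell.vacuole_mask),
            }
        )
    return cells, pd.DataFrame(rows)


def _component_count(mask: BinaryMask | None) -> int:
    if mask is None or mask.is_empty:
        return 0
    _, n = ndimage.label(mask.grid)
    return int(n)


def generate_dataset(
    n_smears: int,
    fractions: list[float],
    params: SyntheticParams,
    seed: int,
    out_dir: str | Path,
    cells_per_smear: int = 30,
) -> pd.DataFrame:
    """Write a multi-smear dataset of PNG images, mask PNGs and one manifest.

    Directory layout::

        out_dir/
          manifest.csv
          smear_000/cell_0000.png
          smear_000/cell_0000.mask_cell.png   (and .mask_nucleus / .mask_vacuole)
          ...

    Re-running with identical arguments reproduces identical files.
    """
    if len(fractions) != n_smears:
        raise ParameterError(
            f"fractions length {len(fractions)} must equal n_smears {n_smears}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifests = []
    for s, fraction in enumerate(fractions):
        smear_id = f"smear_{s:03d}"
        smear_seed = int(seed) * 1_000 + s  # fixed counter scheme
        cells, manifest = generate_smear(
            cells_per_smear, float(fraction), params, seed=smear_seed, smear_id=smear_id
        )
        smear_dir = out / smear_id
        smear_dir.mkdir(exist_ok=True)
        for cell, row in zip(cells, manifest.itertuples()):
            stem = smear_dir / row.cell_id
            cell.write_png(stem.with_suffix(".png"))
            cell.cell_mask.write_png(stem.with_suffix(".mask_cell.png"))
            cell.nucleus_mask.write_png(stem.with_suffix(".mask_nucleus.png"))
            cell.vacuole_mask.write_png(stem.with_suffix(".mask_vacuole.png"))
        manifests.append(manifest)
    full = pd.concat(manifests, ignore_index=True)
    full.to_csv(out / "manifest.csv", index=False)
    return full
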