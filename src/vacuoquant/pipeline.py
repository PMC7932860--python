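"""End-to-end vacuolization quantification: crops → masks → decisions → %.

Each cell image passes through cytoplasm segmentation (cell U-Net minus
nucleus U-Net), is blacked out to its cytoplasm, classified by the softmax
CNN, and called vacuolated when P(vacuolated) reaches the decision
threshold.  Per smear the pipeline reports

    percent_vacuolated = 100 * n_vacuolated / (n_total - n_excluded)

where excluded cells are segmentation failures (empty predicted cell or
cytoplasm mask); they are counted and reported, never silently dropped.
Per-cell probabilities are persisted so the threshold can be re-applied
without re-running inference.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import (
    ClsModelBundle,
    DecisionThreshold,
    classify_batch,
    is_vacuolated,
)
from .errors import ParameterError, QuantificationFailureError
from .masks import apply_mask, cytoplasm_mask
from .segmentation import SegModelBundle, predict_masks
from .synthetic import LABEL_VACUOLATED, CellImage

__all__ = ["CellCall", "VacuolizationResult", "quantify_smear", "quantify_dataset"]


@dataclass(frozen=True)
class CellCall:
    """Per-cell outcome: probability of vacuolization and the decision."""

    cell_id: str
    p_vacuolated: float
    decision: bool
    excluded: bool = False


@dataclass(frozen=True)
class VacuolizationResult:
    """Per-smear vacuolization counts and percentage."""

    smear_id: str
    n_cells_total: int
    n_cells_excluded: int
    n_vacuolated: int
    percent_vacuolated: float
    per_cell: tuple[CellCall, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        denom = self.n_cells_total - self.n_cells_excluded
        if denom <= 0:
            raise ParameterError("no assessable cells in result")
        if not 0.0 <= self.percent_vacuolated <= 100.0:
            raise ParameterError("percent_vacuolated outside [0, 100]")
        if abs(self.percent_vacuolated - 100.0 * self.n_vacuolated / denom) > 1e-9:
            raise ParameterError("percent inconsistent with counts")
        decided = [c for c in self.per_cell if not c.excluded]
        if self.per_cell and (
            len(decided) != denom
            or sum(c.decision for c in decided) != self.n_vacuolated
        ):
            raise ParameterError("per-cell calls inconsistent with counts")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VacuolizationResult":
        per_cell = tuple(CellCall(**c) for c in d.get("per_cell", ()))
        return cls(**{**d, "per_cell": per_cell})


def quantify_smear(
    cell_images: Sequence[CellImage],
    cell_bundle: SegModelBundle,
    nucleus_bundle: SegModelBundle,
    cls_bundle: ClsModelBundle,
    threshold: DecisionThreshold = DecisionThreshold(),
    smear_id: str = "smear",
    cell_ids: Sequence[str] | None = None,
) -> VacuolizationResult:
    """Quantify the vacuolated percentage of one smear's cell images."""
    if not cell_images:
        raise ParameterError("quantify_smear requires at least one cell image")
    if cell_ids is None:
        cell_ids = [f"cell_{i:04d}" for i in range(len(cell_images))]

    cell_masks = predict_masks(cell_bundle, cell_images)
    nucleus_masks = predict_masks(nucleus_bundle, cell_images)
    masked_images: list[CellImage] = []
    keep_idx: list[int] = []
    excluded_ids: list[str] = []
    for i, (image, cmask, nmask) in enumerate(zip(cell_images, cell_masks, nucleus_masks)):
        if cmask.is_empty:
            excluded_ids.append(cell_ids[i])
            continue
        cyto = cytoplasm_mask(cmask, nmask)
        if cyto.is_empty:
            excluded_ids.append(cell_ids[i])
            continue
        keep_idx.append(i)
        masked_images.append(apply_mask(image, cyto))

    if not masked_images:
        raise QuantificationFailureError(
            f"all {len(cell_images)} cells of {smear_id} were excluded by segmentation"
        )
    probs = classify_batch(cls_bundle, masked_images)

    calls = [CellCall(cid, float("nan"), False, excluded=True) for cid in excluded_ids]
    n_vac = 0
    for i, p in zip(keep_idx, probs):
        decision = is_vacuolated(p, threshold)
        n_vac += int(decision)
        calls.append(CellCall(cell_ids[i], p.p_vacuolated, decision))
    calls.sort(key=lambda c: c.cell_id)

    n_total = len(cell_images)
    n_excluded = len(excluded_ids)
    return VacuolizationResult(
        smear_id=smear_id,
        n_cells_total=n_total,
        n_cells_excluded=n_excluded,
        n_vacuolated=n_vac,
        percent_vacuolated=100.0 * n_vac / (n_total - n_excluded),
        per_cell=tuple(calls),
    )


def quantify_dataset(
    manifest: pd.DataFrame,
    image_root: str | Path,
    cell_bundle: SegModelBundle,
    nucleus_bundle: SegModelBundle,
    cls_bundle: ClsModelBundle,
    threshold: DecisionThreshold = DecisionThreshold(),
) -> tuple[list[VacuolizationResult], pd.DataFrame]:
    """Quantify every smear of a manifest; returns results and a report table.

    The report has one row per smear (n_total, n_excluded, n_vacuolated,
    percent); when the manifest carries ground-truth labels a
    ``true_percent`` column is added for method comparison.
    """
    if manifest.empty:
        raise ParameterError("manifest is empty")
    root = Path(image_root)
    results: list[VacuolizationResult] = []
    rows = []
    for smear_id, group in manifest.groupby("smear_id", sort=True):
        images = [CellImage.read_png(root / f) for f in group["file"]]
        result = quantify_smear(
            images,
            cell_bundle,
            nucleus_bundle,
            cls_bundle,
            threshold,
            smear_id=str(smear_id),
            cell_ids=list(group["cell_id"].astype(str)),
        )
        results.append(result)
        row = {
            "smear_id": result.smear_id,
            "n_total": result.n_cells_total,
            "n_excluded": result.n_cells_excluded,
            "n_vacuolated": result.n_vacuolated,
            "percent": result.percent_vacuolated,
        }
        if "label" in group:
            row["true_percent"] = 100.0 * (group["label"] == LABEL_VACUOLATED).mean()
        rows.append(row)
    return results, pd.DataFrame(rows)
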