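"""The full reproducible workflow: synth → augment → train → quantify → compare.

Every stage logs its input/output counts and writes its artifacts together
with a deterministic JSON provenance sidecar (stage name, config hash, seed,
package and numpy versions) so a rerun with the same configuration produces
byte-identical reports.

The method-comparison stage validates the pipeline the way an automated
method is validated against human readers: two simulated manual raters read
each smear as the true vacuolated percentage plus independent Gaussian error
(default SD 2 percentage points), and the automated percentages are compared
against their consensus with Passing-Bablok, Bland-Altman, Pearson and
Levene statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .augment import augment_dataset
from .classifier import train_classifier
from .comparison import compare_methods
from .config import PipelineConfig, stage_seed
from .errors import VacuoquantError
from .manifests import read_manifest, write_report
from .masks import apply_mask, cytoplasm_mask
from .pipeline import quantify_dataset
from .segmentation import train_segmenter
from .synthetic import generate_cell, generate_dataset

__all__ = ["run_full_workflow"]

logger = logging.getLogger("vacuoquant")


class StageError(VacuoquantError):
    """A workflow stage failed; partial artifacts are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_provenance(path: Path, stage: str, config: PipelineConfig, **extra) -> None:
    payload = {
        "stage": stage,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "vacuoquant_version": __version__,
        "numpy_version": np.__version__,
        **extra,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_full_workflow(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns a summary of artifact paths.

    Any stage failure raises :class:`StageError` naming the stage; artifacts
    written by earlier stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.synthetic
    summary: dict = {"out_dir": str(out)}

    stage = "synth"
    try:
        logger.info("[synth] generating %d training cells and %d smears",
                    config.dataset.n_seg_cells + config.dataset.n_cls_cells,
                    len(config.dataset.smear_fractions))
        synth_seed = stage_seed(config.seed, "synth")
        seg_pool = [
            generate_cell(params, vacuolated=i % 2 == 0, seed=synth_seed * 1_000_000 + i)
            for i in range(config.dataset.n_seg_cells)
        ]
        cls_pool = [
            generate_cell(params, vacuolated=i % 2 == 0,
                          seed=synth_seed * 1_000_000 + 500_000 + i)
            for i in range(config.dataset.n_cls_cells)
        ]
        smear_dir = out / "smears"
        generate_dataset(
            n_smears=len(config.dataset.smear_fractions),
            fractions=list(config.dataset.smear_fractions),
            params=params,
            seed=stage_seed(config.seed, "quantify"),
            out_dir=smear_dir,
            cells_per_smear=config.dataset.cells_per_smear,
        )
        _write_provenance(smear_dir / "provenance.json", stage, config,
                          n_smears=len(config.dataset.smear_fractions),
                          cells_per_smear=config.dataset.cells_per_smear)
        summary["smears"] = str(smear_dir)

        stage = "augment"
        if config.dataset.augment_segmentation:
            logger.info("[augment] factor %d on %d segmentation examples",
                        config.augmentation.factor, len(seg_pool))
            seg_pool = augment_dataset(seg_pool, config.augmentation)

        stage = "train-seg"
        logger.info("[train-seg] cell target on %d examples", len(seg_pool))
        cell_bundle = train_segmenter(seg_pool, config.seg_cell)
        cell_bundle.save(out / "models" / "seg_cell")
        logger.info("[train-seg] nucleus target; cell val dice %.4f",
                    cell_bundle.validation_dice)
        nucleus_bundle = train_segmenter(seg_pool, config.seg_nucleus)
        nucleus_bundle.save(out / "models" / "seg_nucleus")
        _write_provenance(out / "models" / "provenance.json", stage, config,
                          cell_validation_dice=cell_bundle.validation_dice,
                          nucleus_validation_dice=nucleus_bundle.validation_dice)

        stage = "train-cls"
        masked = [
            apply_mask(c, cytoplasm_mask(c.cell_mask, c.nucleus_mask)) for c in cls_pool
        ]
        logger.info("[train-cls] %d masked examples", len(masked))
        cls_bundle = train_classifier(masked, config.classifier)
        cls_bundle.save(out / "models" / "classifier")
        logger.info("[train-cls] validation accuracy %.4f", cls_bundle.validation_accuracy)
        summary["models"] = str(out / "models")

        stage = "quantify"
        manifest = read_manifest(smear_dir / "manifest.csv")
        results, report = quantify_dataset(
            manifest, smear_dir, cell_bundle, nucleus_bundle, cls_bundle, config.threshold
        )
        report_path = out / "reports" / "quantification.json"
        write_report(results, report_path)
        report.to_csv(out / "reports" / "per_smear.csv", index=False)
        _write_provenance(out / "reports" / "quantification.provenance.json", stage,
                          config, n_smears=len(results),
                          n_excluded=int(sum(r.n_cells_excluded for r in results)))
        summary["reports"] = str(out / "reports")

        stage = "compare"
        rng = np.random.default_rng(
            np.random.SeedSequence([stage_seed(config.seed, "compare"), 0x4A7E])
        )
        truth = report["true_percent"].to_numpy()
        noise_sd = config.comparison.manual_noise_sd
        manual1 = np.clip(truth + rng.normal(0, noise_sd, truth.size), 0, 100)
        manual2 = np.clip(truth + rng.normal(0, noise_sd, truth.size), 0, 100)
        auto = report["percent"].to_numpy()
        comparison = compare_methods(
            auto, manual1, manual2,
            bootstrap_samples=config.comparison.bootstrap_samples,
            seed=stage_seed(config.seed, "compare"),
        )
        (out / "reports" / "method_comparison.json").write_text(comparison.to_json())
        _write_provenance(out / "reports" / "method_comparison.provenance.json", stage,
                          config, n_smears=int(truth.size))
        summary["method_comparison"] = str(out / "reports" / "method_comparison.json")
        logger.info("[compare] PB slope %.3f, r %s",
                    comparison.passing_bablok_auto_vs_consensus.slope,
                    comparison.pearson_r_auto_vs_consensus)
    except VacuoquantError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
        raise StageError(stage, exc) from exc
    return summary
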