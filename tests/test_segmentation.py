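"""Segmentation training, prediction and cytoplasm construction."""

import numpy as np
import pytest

from vacuoquant import dice
from vacuoquant.errors import (
    DataError,
    ParameterError,
    SegmentationFailureError,
    ShapeError,
)
from vacuoquant.nn import UNet
from vacuoquant.segmentation import (
    SegModelBundle,
    SegTrainConfig,
    predict_mask,
    segment_cytoplasm,
    split_dataset,
    train_segmenter,
)

TINY = dict(epochs=4, base_filters=8, depth=2, batch_size=8, seed=0)


@pytest.fixture(scope="module")
def trained_cell_bundle(small_cell_pool):
    return train_segmenter(small_cell_pool, SegTrainConfig(target="cell", **TINY))


class TestSplitDataset:
    def test_eighty_twenty(self):
        train, val = split_dataset(list(range(100)), 0.8, seed=0)
        assert (len(train), len(val)) == (80, 20)
        assert set(train).isdisjoint(val)

    def test_floor_rule_small_n(self):
        train, val = split_dataset(list(range(5)), 0.8, seed=0)
        assert (len(train), len(val)) == (4, 1)

    def test_seeded_reproducibility(self):
        a = split_dataset(list(range(20)), 0.7, seed=4)
        b = split_dataset(list(range(20)), 0.7, seed=4)
        assert a == b

    def test_too_few_examples(self):
        with pytest.raises(ParameterError):
            split_dataset([1], 0.8, seed=0)


class TestTrainSegmenter:
    def test_zero_epochs_rejected(self, small_cell_pool):
        with pytest.raises(ParameterError):
            train_segmenter(small_cell_pool, SegTrainConfig(target="cell", epochs=0))

    def test_missing_masks_rejected(self, small_cell_pool):
        import dataclasses

        broken = [dataclasses.replace(c, vacuole_mask=None, nucleus_mask=None, cell_mask=None)
                  for c in small_cell_pool]
        with pytest.raises(DataError):
            train_segmenter(broken, SegTrainConfig(target="cell", **TINY))

    def test_training_beats_untrained_model(self, small_cell_pool, trained_cell_bundle):
        untrained = SegModelBundle(
            model=UNet(base_filters=8, depth=2, seed=0),
            config=trained_cell_bundle.config,
        )
        val_cell = small_cell_pool[-1]
        trained_dice = dice(predict_mask(trained_cell_bundle, val_cell), val_cell.cell_mask)
        pred_untrained = predict_mask(untrained, val_cell)
        if pred_untrained.is_empty:
            untrained_value = 0.0
        else:
            untrained_value = dice(pred_untrained, val_cell.cell_mask).value
        assert trained_dice.value > untrained_value

    def test_history_losses_finite_and_recorded(self, trained_cell_bundle):
        assert len(trained_cell_bundle.history) == TINY["epochs"]
        assert all(np.isfinite(h["train_loss"]) for h in trained_cell_bundle.history)
        assert trained_cell_bundle.validation_dice > 0.5

    def test_save_load_roundtrip_preserves_predictions(
        self, tmp_path, trained_cell_bundle, small_cell_pool
    ):
        trained_cell_bundle.save(tmp_path / "bundle")
        loaded = SegModelBundle.load(tmp_path / "bundle")
        assert loaded.validation_dice == trained_cell_bundle.validation_dice
        image = small_cell_pool[0]
        assert predict_mask(loaded, image) == predict_mask(trained_cell_bundle, image)


class TestPredictMask:
    def test_output_binary_and_dimension_matched(self, trained_cell_bundle, healthy_cell):
        mask = predict_mask(trained_cell_bundle, healthy_cell)
        assert mask.shape == healthy_cell.shape
        assert mask.grid.dtype == bool

    def test_uniform_background_image_is_handled(self, trained_cell_bundle, small_params):
        from vacuoquant.synthetic import CellImage

        blank = CellImage(
            pixels=np.full((small_params.image_size, small_params.image_size, 3), 0.93,
                           dtype=np.float32)
        )
        mask = predict_mask(trained_cell_bundle, blank)  # no error
        assert mask.shape == blank.shape

    def test_incompatible_dimensions_rejected(self, trained_cell_bundle):
        from vacuoquant.synthetic import CellImage

        odd = CellImage(pixels=np.zeros((15, 15, 3), dtype=np.float32))
        with pytest.raises(ShapeError):
            predict_mask(trained_cell_bundle, odd)


class _StubModel:
    """Constant-probability model standing in for a trained U-Net."""

    pool_factor = 1

    def __init__(self, value: float):
        self.value = value

    def forward(self, x):
        from vacuoquant.nn import Tensor

        n, _, h, w = np.asarray(x).shape
        return Tensor(np.full((n, 1, h, w), self.value, dtype=np.float32))


def _stub_bundle(value: float) -> SegModelBundle:
    return SegModelBundle(model=_StubModel(value), config=SegTrainConfig(target="cell"))


class TestMaskWithPredictedCytoplasm:
    def test_failures_become_none_and_successes_are_masked(self, small_cell_pool):
        from vacuoquant.segmentation import mask_with_predicted_cytoplasm

        images = small_cell_pool[:3]
        full = mask_with_predicted_cytoplasm(_stub_bundle(1.0), _stub_bundle(0.0), images)
        assert all(m is not None for m in full)
        assert np.array_equal(full[0].pixels, images[0].pixels)  # full-cytoplasm mask
        failed = mask_with_predicted_cytoplasm(_stub_bundle(0.0), _stub_bundle(0.0), images)
        assert failed == [None, None, None]


class TestSegmentCytoplasm:
    def test_ground_truth_masks_reduce_to_mask_ops(self, vacuolated_cell):
        from vacuoquant.masks import apply_mask, cytoplasm_mask

        cyto = cytoplasm_mask(vacuolated_cell.cell_mask, vacuolated_cell.nucleus_mask)
        masked = apply_mask(vacuolated_cell, cyto)
        kept = masked.pixels[cyto.grid]
        assert np.array_equal(kept, vacuolated_cell.pixels[cyto.grid])
        assert np.all(masked.pixels[~cyto.grid] == 0)

    def test_empty_cell_prediction_raises_failure(self, vacuolated_cell):
        with pytest.raises(SegmentationFailureError):
            segment_cytoplasm(_stub_bundle(0.0), _stub_bundle(0.0), vacuolated_cell)

    def test_nucleus_covering_cell_raises_failure(self, vacuolated_cell):
        with pytest.raises(SegmentationFailureError):
            segment_cytoplasm(_stub_bundle(1.0), _stub_bundle(1.0), vacuolated_cell)
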