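"""The vacuolization classifier: residual CNN, decision rule, and Grad-CAM.

The classifier consumes cytoplasm-masked cell crops and ends in a 2-neuron
softmax giving the probability that the cell is a vacuolated lymphocyte
versus healthy.  A cell is called vacuolated when that probability reaches
the decision threshold (default tau = 0.65, inclusive).  Grad-CAM exposes
which image regions drive the class score: gradients of the target-class
logit are average-pooled over the final convolutional stage's feature maps
to weight them, and the rectified weighted sum is upsampled and normalized
to a [0, 1] heatmap.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import resize

from .errors import DataError, ModelError, ParameterError, ShapeError
from .nn import Adam, ResNetClassifier, Tensor, softmax, softmax_cross_entropy
from .segmentation import split_dataset
from .synthetic import LABEL_HEALTHY, LABEL_VACUOLATED, CellImage

__all__ = [
    "ClsTrainConfig",
    "ClsModelBundle",
    "ProbabilityVector",
    "DecisionThreshold",
    "GradCamMap",
    "train_classifier",
    "classify",
    "classify_batch",
    "is_vacuolated",
    "gradcam",
]

#: class indices of the 2-neuron softmax head
CLASS_HEALTHY, CLASS_VACUOLATED = 0, 1


@dataclass(frozen=True)
class ClsTrainConfig:
    split_fraction: float = 0.8
    epochs: int = 21
    batch_size: int = 16
    learning_rate: float = 1e-3
    #: learning rate is multiplied by 0.1 at these fractions of the epoch budget
    lr_decay_milestones: tuple[float, ...] = (0.5, 0.8)
    base_filters: int = 16
    blocks_per_stage: tuple[int, ...] = (2, 2, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ParameterError("split_fraction must lie in (0, 1)")
        if self.batch_size < 1 or self.base_filters < 1 or len(self.blocks_per_stage) < 1:
            raise ParameterError("invalid architecture/batch configuration")


@dataclass(frozen=True)
class ProbabilityVector:
    """Softmax output for one cell: P(vacuolated) and P(healthy)."""

    p_vacuolated: float
    p_healthy: float

    def __post_init__(self) -> None:
        for p in (self.p_vacuolated, self.p_healthy):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"probability {p} outside [0, 1]")
        if abs(self.p_vacuolated + self.p_healthy - 1.0) > 1e-6:
            raise ParameterError("probabilities must sum to 1 within 1e-6")


@dataclass(frozen=True)
class DecisionThreshold:
    """Probability cut for calling a cell vacuolated; inclusive at tau."""

    tau: float = 0.65

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ParameterError("tau must lie in (0, 1)")


@dataclass(frozen=True)
class GradCamMap:
    """A [0, 1] attribution heatmap at input resolution."""

    heatmap: np.ndarray
    target_class: str


@dataclass
class ClsModelBundle:
    """A trained classifier: network, config, history, validation accuracy."""

    model: ResNetClassifier
    config: ClsTrainConfig
    history: list[dict] = field(default_factory=list)
    validation_accuracy: float = float("nan")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", *self.model.state_arrays())
        sidecar = {
            "kind": "classifier",
            "config": asdict(self.config),
            "validation_accuracy": self.validation_accuracy,
            "history": self.history,
        }
        (directory / "bundle.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ClsModelBundle":
        directory = Path(directory)
        sidecar = json.loads((directory / "bundle.json").read_text())
        cfg = dict(sidecar["config"])
        cfg["blocks_per_stage"] = tuple(cfg["blocks_per_stage"])
        config = ClsTrainConfig(**cfg)
        model = ResNetClassifier(
            base_filters=config.base_filters,
            blocks_per_stage=config.blocks_per_stage,
            seed=config.seed,
        )
        with np.load(directory / "weights.npz") as data:
            model.load_state_arrays([data[k] for k in data.files])
        return cls(
            model=model,
            config=config,
            history=sidecar["history"],
            validation_accuracy=float(sidecar["validation_accuracy"]),
        )


def _labels_to_ints(examples: Sequence[CellImage]) -> np.ndarray:
    labels = []
    for i, ex in enumerate(examples):
        if ex.label == LABEL_VACUOLATED:
            labels.append(CLASS_VACUOLATED)
        elif ex.label == LABEL_HEALTHY:
            labels.append(CLASS_HEALTHY)
        else:
            raise DataError(f"example {i} has no class label")
    return np.asarray(labels, dtype=np.int64)


def _stack(examples: Sequence[CellImage]) -> np.ndarray:
    return np.stack([np.moveaxis(ex.pixels, -1, 0) for ex in examples]).astype(np.float32)


def train_classifier(examples: Sequence[CellImage], config: ClsTrainConfig) -> ClsModelBundle:
    """Train the residual classifier on labeled (cytoplasm-masked) cells.

    Runs a fixed number of epochs, tracking validation accuracy after each,
    and returns the weights of the best-validation-accuracy epoch (additional
    epochs beyond the best checkpoint do not degrade the reported model).
    """
    if config.epochs < 1:
        raise ParameterError("epochs must be >= 1: no training would be performed")
    labels = _labels_to_ints(examples)
    train, val = split_dataset(list(zip(examples, labels)), config.split_fraction, config.seed)
    y_train = np.asarray([lab for _, lab in train], dtype=np.int64)
    y_val = np.asarray([lab for _, lab in val], dtype=np.int64)
    if len(np.unique(y_train)) < 2:
        raise DataError("training portion must contain both classes")
    x_train = _stack([ex for ex, _ in train])
    x_val = _stack([ex for ex, _ in val])

    model = ResNetClassifier(
        base_filters=config.base_filters,
        blocks_per_stage=config.blocks_per_stage,
        seed=config.seed,
    )
    opt = Adam(model.parameters(), lr=config.learning_rate)
    epoch_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE90C]))
    history: list[dict] = []
    best_acc, best_state = -1.0, None
    n = len(train)
    milestones = {int(np.ceil(m * config.epochs)) for m in config.lr_decay_milestones}
    for epoch in range(config.epochs):
        if epoch in milestones:
            opt.lr *= 0.1
        order = epoch_rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits, _ = model.forward(x_train[idx], train=True)
            loss = softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss.data):
                raise ArithmeticError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        acc = _accuracy(model, x_val, y_val)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_acc": acc})
        if acc > best_acc:
            best_acc = acc
            best_state = [a.copy() for a in model.state_arrays()]
    model.load_state_arrays(best_state)
    return ClsModelBundle(
        model=model, config=config, history=history, validation_accuracy=best_acc
    )


def _accuracy(model: ResNetClassifier, x: np.ndarray, y: np.ndarray) -> float:
    preds = []
    for start in range(0, len(x), 32):
        logits, _ = model.forward(x[start : start + 32])
        preds.append(logits.data.argmax(axis=1))
    return float((np.concatenate(preds) == y).mean())


def classify_batch(bundle: ClsModelBundle, images: Sequence[CellImage],
                   batch_size: int = 32) -> list[ProbabilityVector]:
    """Softmax probability vectors for a sequence of equally sized images."""
    _check_compatible(bundle, images)
    x = _stack(images)
    out: list[ProbabilityVector] = []
    for start in range(0, len(images), batch_size):
        logits, _ = bundle.model.forward(x[start : start + batch_size])
        probs = softmax(logits.data)
        out.extend(
            ProbabilityVector(
                p_vacuolated=float(p[CLASS_VACUOLATED]), p_healthy=float(p[CLASS_HEALTHY])
            )
            for p in probs
        )
    return out


def classify(bundle: ClsModelBundle, image: CellImage) -> ProbabilityVector:
    """Probability that one cytoplasm-masked cell is vacuolated vs healthy."""
    return classify_batch(bundle, [image])[0]


def is_vacuolated(p: ProbabilityVector, threshold: DecisionThreshold) -> bool:
    """Decision rule: vacuolated iff P(vacuolated) >= tau (inclusive)."""
    return p.p_vacuolated >= threshold.tau


def _check_compatible(bundle: ClsModelBundle, images: Sequence[CellImage]) -> None:
    factor = 2 ** len(bundle.config.blocks_per_stage)
    for image in images:
        h, w = image.shape
        if h % factor or w % factor:
            raise ShapeError(
                f"image size {(h, w)} incompatible with classifier (needs % {factor} == 0)"
            )


def gradcam(bundle: ClsModelBundle, image: CellImage,
            target_class: str = LABEL_VACUOLATED) -> GradCamMap:
    """Grad-CAM attribution of one class score over the last conv stage.

    Channel weights are the spatial means of the class-logit gradients on the
    final stage's feature maps; the rectified weighted sum is upsampled to
    input resolution and normalized to a maximum of 1, or returned as all
    zeros when the raw map is identically zero.
    """
    if target_class == LABEL_VACUOLATED:
        class_idx = CLASS_VACUOLATED
    elif target_class == LABEL_HEALTHY:
        class_idx = CLASS_HEALTHY
    else:
        raise ParameterError(f"unknown target class {target_class!r}")
    try:
        _check_compatible(bundle, [image])
    except ShapeError as exc:
        raise ModelError(str(exc)) from exc

    x = _stack([image])
    logits, feat = bundle.model.forward(x)
    score = Tensor(logits.data[0, class_idx], parents=(logits,))

    def _seed_backward(grad):
        g = np.zeros_like(logits.data)
        g[0, class_idx] = grad
        logits._accumulate(g)

    score._backward = _seed_backward
    score.backward(np.asarray(1.0, dtype=logits.data.dtype))
    if feat.grad is None:  # pragma: no cover - defensive
        raise ModelError("no gradient reached the final convolutional stage")

    weights = feat.grad[0].mean(axis=(1, 2))  # (C,)
    cam = np.maximum((weights[:, None, None] * feat.data[0]).sum(axis=0), 0.0)
    cam = resize(cam, image.shape, order=1, preserve_range=True, anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return GradCamMap(heatmap=cam.astype(np.float64), target_class=target_class)
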