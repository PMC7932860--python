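"""Residual CNN classifier ending in a 2-neuron softmax head.

A reduced residual network in the ResNet family: a convolutional stem, three
stages of batch-normalized identity residual blocks (conv-BN-ReLU-conv-BN-
add-ReLU) with pooling transitions that halve resolution and double channel
width, a global average pool, and a dense layer to 2 logits.  The defining
design element is the 2-neuron softmax output giving the probability that
the input cell is a vacuolated lymphocyte versus healthy.

Batch normalization is essential here: the vacuolization signal occupies a
few bright pixels in an otherwise masked-out image, and the normalized
residual stack lets that sparse signal survive global average pooling.

The final stage's feature maps are exposed by the forward pass so Grad-CAM
can pool class-score gradients over them.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, add, global_avg_pool, maxpool2, relu
from .layers import BatchNorm, Conv, Dense, Module

__all__ = ["ResNetClassifier"]


class _ResidualBlock:
    def __init__(self, channels: int, rng: np.random.Generator):
        self.c1 = Conv(channels, channels, rng)
        self.n1 = BatchNorm(channels)
        self.c2 = Conv(channels, channels, rng)
        # zero-init gamma: the block starts as the identity mapping
        self.n2 = BatchNorm(channels, gamma_init=0.0)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        t = relu(self.n1(self.c1(x), train))
        t = self.n2(self.c2(t), train)
        return relu(add(t, x))

    def parameters(self):
        return (
            self.c1.parameters() + self.n1.parameters()
            + self.c2.parameters() + self.n2.parameters()
        )

    def buffers(self):
        return self.n1.buffers() + self.n2.buffers()


class ResNetClassifier(Module):
    """Three-stage residual classifier over (N, 3, H, W) inputs, H, W % 8 == 0."""

    def __init__(self, in_channels: int = 3, base_filters: int = 16,
                 blocks_per_stage: tuple[int, ...] = (2, 2, 2), n_classes: int = 2,
                 seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1A5]))
        self.stem = Conv(in_channels, base_filters, rng)
        self.stem_norm = BatchNorm(base_filters)
        self.stages = []
        self.transitions = []
        ch = base_filters
        for s, n_blocks in enumerate(blocks_per_stage):
            if s > 0:
                self.transitions.append(Conv(ch, ch * 2, rng, kernel=1))
                ch *= 2
            self.stages.append([_ResidualBlock(ch, rng) for _ in range(n_blocks)])
        self.fc = Dense(ch, n_classes, rng)
        self._all = [self.stem, self.stem_norm, *self.transitions, self.fc]
        self._all += [b for stage in self.stages for b in stage]

    def forward(self, x: np.ndarray | Tensor, train: bool = False) -> tuple[Tensor, Tensor]:
        """Return (logits (N, 2), last-stage feature maps) for the batch."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        t = maxpool2(relu(self.stem_norm(self.stem(x), train)))
        for s, stage in enumerate(self.stages):
            if s > 0:
                t = self.transitions[s - 1](maxpool2(t))
            for block in stage:
                t = block(t, train)
        logits = self.fc(global_avg_pool(t))
        return logits, t
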