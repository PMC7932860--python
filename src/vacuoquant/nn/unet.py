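"""U-Net-style encoder-decoder for binary segmentation of single-cell crops.

A classic contracting/expanding architecture with skip connections: each
encoder level applies two 3x3 convolutions + ReLU and halves the spatial
resolution by max pooling; the decoder mirrors it with nearest-neighbor
upsampling and channel concatenation of the matching encoder features.  A
final 1x1 convolution with sigmoid yields a per-pixel foreground probability.

Default scale (depth 3, 16 base filters) is deliberately small: it trains on
a CPU in minutes at 64-128 px while comfortably segmenting stained-cell
morphology; both knobs are configurable upward.
"""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    concat_channels,
    maxpool2,
    relu,
    sigmoid,
    upsample2,
)
from .layers import Conv, Module

__all__ = ["UNet"]


class UNet(Module):
    def __init__(self, in_channels: int = 3, base_filters: int = 16, depth: int = 3,
                 seed: int = 0):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0E71]))
        self.depth = depth
        chans = [base_filters * 2**i for i in range(depth)]
        self.enc = []
        prev = in_channels
        for ch in chans:
            self.enc.append([Conv(prev, ch, rng), Conv(ch, ch, rng)])
            prev = ch
        self.dec = []
        for i in range(depth - 2, -1, -1):
            ch = chans[i]
            self.dec.append(
                {
                    "up": Conv(chans[i + 1], ch, rng),
                    "merge": [Conv(2 * ch, ch, rng), Conv(ch, ch, rng)],
                }
            )
        self.head = Conv(chans[0], 1, rng, kernel=1)
        # flat registration for Module.parameters()
        self._all = [c for lvl in self.enc for c in lvl]
        self._all += [d["up"] for d in self.dec]
        self._all += [c for d in self.dec for c in d["merge"]]
        self._all.append(self.head)

    @property
    def pool_factor(self) -> int:
        return 2 ** (self.depth - 1)

    def forward(self, x: np.ndarray | Tensor, requires_grad: bool = False) -> Tensor:
        """Per-pixel foreground probabilities, shape (N, 1, H, W)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        h, w = x.data.shape[2:]
        f = self.pool_factor
        if h % f or w % f:
            raise ValueError(
                f"input spatial size {(h, w)} must be divisible by {f} for depth {self.depth}"
            )
        skips = []
        t = x
        for i, (c1, c2) in enumerate(self.enc):
            t = relu(c1(t))
            t = relu(c2(t))
            if i < self.depth - 1:
                skips.append(t)
                t = maxpool2(t)
        for block, skip in zip(self.dec, reversed(skips)):
            t = relu(block["up"](upsample2(t)))
            t = concat_channels(t, skip)
            t = relu(block["merge"][0](t))
            t = relu(block["merge"][1](t))
        return sigmoid(self.head(t))
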