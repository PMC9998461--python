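"""Micro-CNN tile classifier backbone.

A stack of conv-ReLU-pool blocks followed by global average pooling and a
linear head; stands in for the large residual backbones of GPU-scale
training while keeping the same training interface (softmax probabilities
over the three ordered grades).
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, GlobalAvgPool, Linear, MaxPool2, ReLU, softmax


class MicroCNN:
    def __init__(self, in_channels: int = 3, n_classes: int = 3,
                 widths: tuple[int, ...] = (8, 16, 32),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.widths = tuple(widths)
        self.blocks = []
        cin = in_channels
        for wd in widths:
            self.blocks.append((Conv2d(cin, wd, rng=rng), ReLU(), MaxPool2()))
            cin = wd
        self.gap = GlobalAvgPool()
        self.fc = Linear(cin, n_classes, rng=rng)

    def params(self):
        ps = []
        for conv, _, _ in self.blocks:
            ps += conv.params()
        ps += self.fc.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        for conv, relu, pool in self.blocks:
            x = pool.forward(relu.forward(conv.forward(x)))
        return self.fc.forward(self.gap.forward(x))

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.gap.backward(self.fc.backward(dlogits))
        for conv, relu, pool in reversed(self.blocks):
            dx = conv.backward(relu.backward(pool.backward(dx)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x), axis=1)

    def config(self) -> dict:
        return {"in_channels": self.in_channels, "n_classes": self.n_classes,
                "widths": list(self.widths)}
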