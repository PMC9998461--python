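"""U-Net for binary segmentation: double-conv encoder blocks, 2x2 max-pool
downsampling, transposed-conv upsampling with skip concatenation, and a
1x1 sigmoid head. Depth and width are configurable so the same model runs
at desk scale on CPU."""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, ConvTranspose2x2, MaxPool2, ReLU


class DoubleConv:
    def __init__(self, cin: int, cout: int, rng):
        self.c1 = Conv2d(cin, cout, rng=rng)
        self.r1 = ReLU()
        self.c2 = Conv2d(cout, cout, rng=rng)
        self.r2 = ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dy):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))

    def params(self):
        return self.c1.params() + self.c2.params()


class UNet:
    """Returns logits; apply a sigmoid for probabilities.

    Input spatial size must be divisible by 2**depth.
    """

    def __init__(self, in_channels: int = 3, depth: int = 4, base_filters: int = 64,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.depth = depth
        self.base_filters = base_filters
        widths = [base_filters * 2**i for i in range(depth + 1)]
        self.encoders = []
        cin = in_channels
        for wd in widths[:-1]:
            self.encoders.append(DoubleConv(cin, wd, rng))
            cin = wd
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = DoubleConv(widths[-2], widths[-1], rng)
        self.ups = []
        self.decoders = []
        for wd in reversed(widths[:-1]):
            self.ups.append(ConvTranspose2x2(wd * 2, wd, rng))
            self.decoders.append(DoubleConv(wd * 2, wd, rng))
        self.head = Conv2d(widths[0], 1, k=1, rng=rng)

    def params(self):
        ps = []
        for enc in self.encoders:
            ps += enc.params()
        ps += self.bottleneck.params()
        for up, dec in zip(self.ups, self.decoders):
            ps += up.params() + dec.params()
        ps += self.head.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.shape[2] % 2**self.depth or x.shape[3] % 2**self.depth:
            raise ValueError(f"input spatial size must be divisible by {2**self.depth}")
        skips = []
        for enc, pool in zip(self.encoders, self.pools):
            x = enc.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.decoders, reversed(skips)):
            u = up.forward(x)
            self._skip_channels.append(skip.shape[1])
            x = dec.forward(np.concatenate([skip, u], axis=1))
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for up, dec, c_skip in zip(reversed(self.ups), reversed(self.decoders),
                                   reversed(self._skip_channels)):
            dcat = dec.backward(dx)
            dskips.append(dcat[:, :c_skip])
            dx = up.backward(dcat[:, c_skip:])
        dx = self.bottleneck.backward(dx)
        dskips.reverse()  # now ordered bottom-of-decoder .. top; matches encoder order reversed
        for enc, pool, dskip in zip(reversed(self.encoders), reversed(self.pools), dskips):
            dx = pool.backward(dx) + dskip
            dx = enc.backward(dx)

    def config(self) -> dict:
        return {"in_channels": self.in_channels, "depth": self.depth,
                "base_filters": self.base_filters}
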