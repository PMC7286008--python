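"""2D U-Net with explicit backward pass.

Encoder levels apply a block of 3x3 convolutions (each with batch
normalisation and ReLU) followed by 2x2 max pooling; the decoder mirrors
them with 2x2 transposed convolutions, skip concatenation, two 3x3
convolutions per level and dropout on the first decoder convolution.  A
final 1x1 convolution with a sigmoid maps to a single output channel in
[0, 1].
"""

from __future__ import annotations

import numpy as np

from .layers import (
    Layer, Conv2d, ConvTranspose2d, MaxPool2d, BatchNorm2d, ReLU, Sigmoid,
    Dropout, Sequential,
)

__all__ = ["UNet"]


def _conv_block(c_in: int, c_out: int, n_convs: int, k: int, rng) -> Sequential:
    layers = []
    for i in range(n_convs):
        layers += [Conv2d(c_in if i == 0 else c_out, c_out, k=k, rng=rng),
                   BatchNorm2d(c_out), ReLU()]
    return Sequential(*layers)


class UNet(Layer):
    def __init__(self, depth: int = 3, base_filters: int = 8, convs_per_block: int = 3,
                 kernel_size: int = 3, dropout_rate: float = 0.5,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        ch = [base_filters * 2**l for l in range(depth + 1)]
        self.depth = depth
        self.enc = [_conv_block(1 if l == 0 else ch[l - 1], ch[l], convs_per_block, kernel_size, rng)
                    for l in range(depth)]
        self.pools = [MaxPool2d() for _ in range(depth)]
        self.bottom = _conv_block(ch[depth - 1], ch[depth], convs_per_block, kernel_size, rng)
        self.ups = [ConvTranspose2d(ch[l + 1], ch[l], rng=rng) for l in reversed(range(depth))]
        # after concatenation: 2*ch[l] -> ch[l] -> ch[l]; dropout on the first conv
        self.dec = []
        for l in reversed(range(depth)):
            self.dec.append(Sequential(
                Conv2d(2 * ch[l], ch[l], k=kernel_size, rng=rng), BatchNorm2d(ch[l]), ReLU(),
                Dropout(dropout_rate, rng=np.random.default_rng(rng.integers(2**31 - 1))),
                Conv2d(ch[l], ch[l], k=kernel_size, rng=rng), BatchNorm2d(ch[l]), ReLU(),
            ))
        self.head = Sequential(Conv2d(ch[0], 1, k=1, rng=rng), Sigmoid())
        self._skip_channels = list(reversed(ch[:depth]))

    def _blocks(self):
        return self.enc + [self.bottom] + self.ups + self.dec + [self.head]

    def params(self):
        return [p for block in self._blocks() for p in block.params()]

    def batchnorms(self):
        """Batch-normalisation layers in deterministic order (their running
        statistics are inference state and must be serialised with the
        weights)."""
        out = []
        for block in self._blocks():
            for layer in getattr(block, "layers", []):
                if isinstance(layer, BatchNorm2d):
                    out.append(layer)
        return out

    def forward(self, x, training=False):
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, training=training)
            skips.append(x)
            x = pool.forward(x, training=training)
        x = self.bottom.forward(x, training=training)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, training=training)
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, training=training)
        return self.head.forward(x, training=training)

    def backward(self, dy):
        dy = self.head.backward(dy)
        dskips = []
        # decoder in reverse order; dec[i] sits at encoder level depth-1-i,
        # so the skip gradients come out already indexed like self.enc
        for i in reversed(range(self.depth)):
            d = self.dec[i].backward(dy)
            c = self._skip_channels[i]
            dskip, dup = d[:, :c], d[:, c:]
            dskips.append(dskip)
            dy = self.ups[i].backward(dup)
        dy = self.bottom.backward(dy)
        for l in reversed(range(self.depth)):
            dy = self.pools[l].backward(dy)
            dy = dy + dskips[l]
            dy = self.enc[l].backward(dy)
        return dy
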