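"""Residual-in-residual dense blocks (RRDB), the convolutional backbone.

A Dense Block chains five 3x3 convolutions with dense concatenative
connectivity and leaky-ReLU activations; its output is residual-scaled by
``beta`` (0.2) and added to the block input.  An RRDB stacks three Dense
Blocks under an outer residual connection, also scaled by ``beta``.

Two optional additive shortcuts inside each Dense Block (``extra_skips``)
improve feature mobility: the first conv's activation is added onto the
third's, and the second's onto the fourth's (all growth-channel tensors).
Their exact placement is a design choice of this package; the ablation flag
lets the effect be isolated.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, Module, Tensor, concat

__all__ = ["DenseBlock", "RRDB"]


class DenseBlock(Module):
    def __init__(
        self,
        channels: int,
        growth: int,
        beta: float = 0.2,
        extra_skips: bool = True,
        rng: np.random.Generator | None = None,
        zero_last: bool = False,
    ):
        rng = rng or np.random.default_rng(0)
        c, g = channels, growth
        self.beta = beta
        self.extra_skips = extra_skips
        self.conv1 = Conv2d(c, g, rng=rng)
        self.conv2 = Conv2d(c + g, g, rng=rng)
        self.conv3 = Conv2d(c + 2 * g, g, rng=rng)
        self.conv4 = Conv2d(c + 3 * g, g, rng=rng)
        self.conv5 = Conv2d(c + 4 * g, c, rng=rng, init="zero" if zero_last else "he",
                            gain=0.1)

    def forward(self, x: Tensor) -> Tensor:
        h1 = self.conv1(x).leaky_relu()
        h2 = self.conv2(concat([x, h1])).leaky_relu()
        h3 = self.conv3(concat([x, h1, h2])).leaky_relu()
        if self.extra_skips:
            h3 = h3 + h1
        h4 = self.conv4(concat([x, h1, h2, h3])).leaky_relu()
        if self.extra_skips:
            h4 = h4 + h2
        h5 = self.conv5(concat([x, h1, h2, h3, h4]))
        return x + h5 * self.beta


class RRDB(Module):
    """Three Dense Blocks under an outer residual scaled by ``beta``."""

    def __init__(
        self,
        channels: int,
        growth: int,
        beta: float = 0.2,
        extra_skips: bool = True,
        rng: np.random.Generator | None = None,
    ):
        self.beta = beta
        self.blocks = [
            DenseBlock(channels, growth, beta, extra_skips, rng=rng) for _ in range(3)
        ]

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for blk in self.blocks:
            h = blk(h)
        # residual-of-residuals: the trunk's deviation from its input is
        # scaled by beta, so an identity trunk gives an exact identity block
        return x + (h - x) * self.beta
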