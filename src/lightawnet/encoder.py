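"""Encoder blocks: inverted-bottleneck depthwise blocks with pixel gating.

Each encoder block applies, in order: a 7x7 depthwise convolution, a 1x1
expansion to four times the channels (BN + GELU), a single-channel sigmoid
pixel gate multiplied back onto the expanded map, concatenation of the
expanded and gated maps, a 1x1 projection back to the input width (BN), a
residual sum with the block input, and finally a dynamic convolution to the
output width. Spatial dimensions are preserved; downsampling is a separate
2x2 max pool between stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (BatchNorm2d, Conv2d, Module, Tensor, concat, gelu,
                       maxpool2, mul, sigmoid)
from .dynconv import DynConv2d, DynConvSpec


@dataclass(frozen=True)
class DyCISSpec:
    """Geometry of one encoder block."""

    c_in: int
    c_out: int
    dw_kernel: int = 7
    expansion: int = 4
    dyconv_kernel: int = 3
    K: int = 4

    def __post_init__(self):
        if self.dw_kernel % 2 == 0:
            raise ValueError("depthwise kernel must be odd")


class DyCISBlock(Module):
    """Dynamic-convolution inverted-bottleneck block with spatial gating."""

    def __init__(self, spec: DyCISSpec, *, rng: np.random.Generator,
                 dynamic: bool = True):
        super().__init__()
        self.spec = spec
        c, e = spec.c_in, spec.expansion
        self.dw = Conv2d(c, c, spec.dw_kernel, groups=c, rng=rng)
        self.c1 = Conv2d(c, e * c, 1, rng=rng)
        self.bn1 = BatchNorm2d(e * c)
        self.c2 = Conv2d(e * c, 1, 1, rng=rng)
        self.c3 = Conv2d(2 * e * c, c, 1, rng=rng)
        self.bn3 = BatchNorm2d(c)
        self.dyconv = DynConv2d(
            DynConvSpec(c, spec.c_out, k=spec.dyconv_kernel, K=spec.K),
            rng=rng, dynamic=dynamic)

    def dw_then_expand(self, x: Tensor) -> Tensor:
        """Depthwise 7x7 then 1x1 expansion: X1 with 4*c_in channels."""
        if x.shape[1] != self.spec.c_in:
            raise ValueError(
                f"input has {x.shape[1]} channels, block expects "
                f"{self.spec.c_in}")
        return gelu(self.bn1(self.c1(self.dw(x))))

    def pixel_gate(self, x1: Tensor) -> Tensor:
        """X2 = X1 * sigmoid(C2(X1)): per-pixel gate broadcast over channels."""
        return mul(x1, sigmoid(self.c2(x1)))

    def forward(self, x: Tensor) -> Tensor:
        x1 = self.dw_then_expand(x)
        x2 = self.pixel_gate(x1)
        x3 = self.bn3(self.c3(concat([x1, x2], axis=1)))
        return self.dyconv(x + x3)


def downsample(x: Tensor) -> Tensor:
    """2x2 max pool, stride 2 (stage transition). Requires even dims."""
    return maxpool2(x)
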