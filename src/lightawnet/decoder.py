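"""Decoder blocks: progressive upsampling with SE and dynamic-conv fusion.

Progressive upsampling replaces transposed convolution: a 1x1 convolution
first halves the channel count, then bilinear interpolation doubles the
spatial size, then squeeze-excitation recalibrates the channels. Doing the
channel compression *before* the resize is what makes the operation cheap;
the two ablation modes (resize-before-compress, and a stride-2 transposed
convolution) are kept selectable for comparison. The upsampled map is
concatenated with the skip connection from the matching encoder stage and
passed through a dynamic convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (BatchNorm2d, Conv2d, ConvTranspose2d, Linear, Module,
                       Tensor, concat, gelu, mean, mul, relu, reshape,
                       sigmoid)
from .dynconv import DynConv2d, DynConvSpec
from .fusion import resize_linear

UPSAMPLE_MODES = ("channel_then_size", "size_then_channel", "transposed")


@dataclass(frozen=True)
class PFFSpec:
    """Geometry of one decoder block."""

    c_in: int
    c_skip: int
    c_out: int
    upsample_mode: str = "channel_then_size"
    se_enabled: bool = True
    se_reduction: int = 4
    dyconv_kernel: int = 3
    K: int = 4
    trans_kernel: int = 4

    def __post_init__(self):
        if self.upsample_mode not in UPSAMPLE_MODES:
            raise ValueError(f"unknown upsample mode {self.upsample_mode!r}")
        if self.c_in % 2:
            raise ValueError("decoder input channels must be even")
        if self.se_enabled and (self.c_in // 2) % self.se_reduction:
            raise ValueError(
                f"SE reduction {self.se_reduction} must divide "
                f"{self.c_in // 2} channels")


class SEBlock(Module):
    """Squeeze-excitation: per-channel sigmoid scales from pooled statistics."""

    def __init__(self, channels: int, reduction: int = 4, *,
                 rng: np.random.Generator):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"reduction {reduction} must divide {channels} channels")
        self.channels = channels
        self.squeeze = Linear(channels, channels // reduction, rng=rng)
        self.excite = Linear(channels // reduction, channels, rng=rng)

    def scales(self, x: Tensor) -> Tensor:
        pooled = mean(x, axes=(2, 3))
        return sigmoid(self.excite(relu(self.squeeze(pooled))))

    def forward(self, x: Tensor) -> Tensor:
        s = self.scales(x)
        return mul(x, reshape(s, (x.shape[0], self.channels, 1, 1)))


def se_recalibrate(x: Tensor, se: SEBlock) -> Tensor:
    return se(x)


class ProgressiveUpsample(Module):
    """Halve channels, double spatial size; order set by the upsample mode."""

    def __init__(self, spec: PFFSpec, *, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        c, c2 = spec.c_in, spec.c_in // 2
        if spec.upsample_mode == "transposed":
            self.up = ConvTranspose2d(c, c2, spec.trans_kernel, rng=rng)
        else:
            self.compress = Conv2d(c, c2, 1, rng=rng)
        if spec.se_enabled:
            self.se = SEBlock(c2, spec.se_reduction, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.c_in:
            raise ValueError(
                f"input has {x.shape[1]} channels, block expects "
                f"{self.spec.c_in}")
        h2, w2 = 2 * x.shape[2], 2 * x.shape[3]
        mode = self.spec.upsample_mode
        if mode == "channel_then_size":
            out = resize_linear(self.compress(x), h2, w2)
        elif mode == "size_then_channel":
            out = self.compress(resize_linear(x, h2, w2))
        else:
            out = self.up(x)
        if self.spec.se_enabled:
            out = self.se(out)
        return out


def progressive_upsample(x: Tensor, up: ProgressiveUpsample) -> Tensor:
    return up(x)


class PFFBlock(Module):
    """Decoder block: upsample F1, fuse with skip F2, dynamic convolution."""

    def __init__(self, spec: PFFSpec, *, rng: np.random.Generator,
                 dynamic: bool = True):
        super().__init__()
        self.spec = spec
        self.upsample = ProgressiveUpsample(spec, rng=rng)
        self.dyconv = DynConv2d(
            DynConvSpec(spec.c_in // 2 + spec.c_skip, spec.c_out,
                        k=spec.dyconv_kernel, K=spec.K),
            rng=rng, dynamic=dynamic)
        self.bn = BatchNorm2d(spec.c_out)

    def forward(self, f1: Tensor, f2: Tensor) -> Tensor:
        f1u = self.upsample(f1)
        if f1u.shape[2:] != f2.shape[2:]:
            raise ValueError(
                f"skip spatial dims {f2.shape[2:]} do not match upsampled "
                f"map {f1u.shape[2:]} — wrong skip pairing")
        fused = concat([f1u, f2], axis=1)
        return gelu(self.bn(self.dyconv(fused)))


def pff_forward(f1: Tensor, f2: Tensor, block: PFFBlock) -> Tensor:
    return block(f1, f2)
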