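"""Dual-branch fusion at 1/8 scale (the feature enhancement module, FEM).

After the third encoder stage the network splits: the semantic branch keeps
downsampling (two more block+pool stages, to 1/32), while the spatial branch
is a single 3x3 convolution at 1/8 scale. The FEM fuses them by mutual
sigmoid gating: each branch is mapped to the other's channel count by a 1x1
adapter, resampled to the other's resolution, squashed through a sigmoid and
multiplied elementwise onto the other branch. The (optionally gated) pair is
then merged back at 1/8 scale by channel concatenation and a 1x1 reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (BatchNorm2d, Conv2d, Module, Tensor, concat, gelu,
                       mul, resize_bilinear, sigmoid)


@dataclass
class BranchPair:
    """Semantic (deep, low-res) and spatial (1/8-scale) feature maps."""

    semantic: Tensor
    spatial: Tensor


def resize_linear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Corner-aligned bilinear resampling (shared by fusion and decoder)."""
    if out_h < 1 or out_w < 1:
        raise ValueError("target size must be positive")
    return resize_bilinear(x, out_h, out_w)


class MutualGate(Module):
    """Cross-branch sigmoid gating with 1x1 channel adapters."""

    def __init__(self, c_sem: int, c_sp: int, *, rng: np.random.Generator):
        super().__init__()
        self.adapt_sem = Conv2d(c_sem, c_sp, 1, rng=rng)   # semantic -> gate for spatial
        self.adapt_sp = Conv2d(c_sp, c_sem, 1, rng=rng)    # spatial -> gate for semantic
        self.c_sem, self.c_sp = c_sem, c_sp

    def forward(self, pair: BranchPair) -> BranchPair:
        sem, sp = pair.semantic, pair.spatial
        if sem.shape[1] != self.c_sem or sp.shape[1] != self.c_sp:
            raise ValueError(
                f"branch channels ({sem.shape[1]}, {sp.shape[1]}) do not "
                f"match gate ({self.c_sem}, {self.c_sp})")
        gate_sp = sigmoid(resize_linear(self.adapt_sem(sem),
                                        sp.shape[2], sp.shape[3]))
        gate_sem = sigmoid(self.adapt_sp(
            resize_linear(sp, sem.shape[2], sem.shape[3])))
        return BranchPair(semantic=mul(sem, gate_sem),
                          spatial=mul(sp, gate_sp))


def mutual_gate(pair: BranchPair, gate: MutualGate) -> BranchPair:
    return gate(pair)


class BranchMerge(Module):
    """Concat-and-reduce of the branch pair at 1/8 scale."""

    def __init__(self, c_sem: int, c_sp: int, c_out: int, *,
                 rng: np.random.Generator):
        super().__init__()
        self.reduce = Conv2d(c_sem + c_sp, c_out, 1, rng=rng)
        self.bn = BatchNorm2d(c_out)

    def forward(self, pair: BranchPair) -> Tensor:
        sp = pair.spatial
        sem_up = resize_linear(pair.semantic, sp.shape[2], sp.shape[3])
        return gelu(self.bn(self.reduce(concat([sem_up, sp], axis=1))))


def merge_branches(pair: BranchPair, merge: BranchMerge) -> Tensor:
    return merge(pair)


class FusionModule(Module):
    """Branch fusion; with ``fem_enabled=False`` the pair is merged ungated."""

    def __init__(self, c_sem: int, c_sp: int, c_out: int, *,
                 fem_enabled: bool = True, rng: np.random.Generator):
        super().__init__()
        self.fem_enabled = fem_enabled
        if fem_enabled:
            self.gate = MutualGate(c_sem, c_sp, rng=rng)
        self.merge = BranchMerge(c_sem, c_sp, c_out, rng=rng)

    def forward(self, pair: BranchPair) -> Tensor:
        if self.fem_enabled:
            pair = self.gate(pair)
        return self.merge(pair)
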