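"""Dynamic convolution: attention-weighted fusion of a kernel bank.

A dynamic convolution keeps K candidate kernels. For every input sample a
tiny attention branch (global average pool -> affine C_in -> K -> sigmoid)
produces K weights in (0, 1); the candidate kernels and their biases are
linearly combined with those weights into one effective kernel, and the
sample is convolved with its own fused kernel. Weights are sigmoid-activated
rather than softmax-normalised, so candidates are gated independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (Module, Parameter, Tensor, conv2d, conv2d_per_sample,
                       fuse_banks, kaiming_uniform, matmul, mean, sigmoid)


@dataclass(frozen=True)
class DynConvSpec:
    """Geometry of one dynamic convolution layer.

    ``k`` is the (odd) spatial kernel size and ``K`` the number of candidate
    kernels in the bank. Padding defaults to (k-1)/2 so stride-1 layers
    preserve spatial dimensions.
    """

    c_in: int
    c_out: int
    k: int = 3
    K: int = 4
    stride: int = 1
    padding: int | None = None

    def __post_init__(self):
        if self.k % 2 == 0:
            raise ValueError("kernel size must be odd")
        if self.K < 1:
            raise ValueError("bank size K must be >= 1")
        if self.stride != 1:
            raise ValueError("only stride-1 dynamic convolutions are used")

    @property
    def pad(self) -> int:
        return (self.k - 1) // 2 if self.padding is None else self.padding


def attention_weights(x: Tensor, spec: DynConvSpec, affine_w: Tensor,
                      affine_b: Tensor) -> Tensor:
    """Per-sample attention weights: sigmoid(affine(GAP(x))), shape (B, K).

    ``affine_w`` is (C_in, K), ``affine_b`` is (K,). Every returned entry is
    strictly inside (0, 1).
    """
    if x.shape[1] != spec.c_in:
        raise ValueError(
            f"input has {x.shape[1]} channels, spec expects {spec.c_in}")
    pooled = mean(x, axes=(2, 3))                 # (B, C)
    logits = matmul(pooled, affine_w) + affine_b  # (B, K)
    return sigmoid(logits)


def fuse_kernels(att: Tensor, kernels: Tensor, biases: Tensor | None = None):
    """Fuse a kernel bank with attention weights.

    ``att``: (B, K); ``kernels``: (K, C_out, C_in, k, k); ``biases``:
    (K, C_out). Returns the per-sample effective kernel (B, C_out, C_in, k, k)
    and, if biases are given, the effective bias (B, C_out): a plain linear
    combination sum_k w_k * kernel_k.
    """
    if att.shape[-1] != kernels.shape[0]:
        raise ValueError(
            f"attention length {att.shape[-1]} != bank size {kernels.shape[0]}")
    fused_w = fuse_banks(att, kernels)
    if biases is None:
        return fused_w
    fused_b = fuse_banks(att, biases)
    return fused_w, fused_b


class DynConv2d(Module):
    """Dynamic convolution layer with a K-kernel bank.

    With ``dynamic=False`` the layer degrades to a single standard convolution
    of the same geometry (the static ablation); the bank then holds one kernel
    and no attention branch is created.
    """

    def __init__(self, spec: DynConvSpec, *, rng: np.random.Generator,
                 dynamic: bool = True):
        super().__init__()
        self.spec = spec
        self.dynamic = dynamic
        fan_in = spec.c_in * spec.k * spec.k
        nbank = spec.K if dynamic else 1
        self.kernels = Parameter(kaiming_uniform(
            rng, (nbank, spec.c_out, spec.c_in, spec.k, spec.k), fan_in))
        self.biases = Parameter(kaiming_uniform(rng, (nbank, spec.c_out),
                                                fan_in))
        if dynamic:
            # zero-init affine so the initial mix is neutral (all gates 0.5)
            self.att_w = Parameter(np.zeros((spec.c_in, spec.K),
                                            dtype=np.float32))
            self.att_b = Parameter(np.zeros(spec.K, dtype=np.float32))

    def attention(self, x: Tensor) -> Tensor:
        return attention_weights(x, self.spec, self.att_w, self.att_b)

    def forward(self, x: Tensor, att: Tensor | None = None) -> Tensor:
        if x.shape[1] != self.spec.c_in:
            raise ValueError(
                f"input has {x.shape[1]} channels, layer expects "
                f"{self.spec.c_in}")
        if not self.dynamic:
            return conv2d(x, self.kernels.reshape(
                self.spec.c_out, self.spec.c_in, self.spec.k, self.spec.k),
                self.biases.reshape(self.spec.c_out), padding=self.spec.pad)
        if att is None:
            att = self.attention(x)
        fused_w, fused_b = fuse_kernels(att, self.kernels, self.biases)
        return conv2d_per_sample(x, fused_w, fused_b, padding=self.spec.pad)
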