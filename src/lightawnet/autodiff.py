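"""Reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core of the package: a small define-by-run tape with
exactly the operators the segmentation network needs (stride-1 grouped and
per-sample convolutions, transposed convolution via zero-stuffing, 2x2 max
pooling, corner-aligned bilinear resampling, batch normalization, the usual
pointwise nonlinearities) plus a ``Module`` container and an Adam optimizer.
All arithmetic is float32.

Convolutions are evaluated tap-by-tap as batched matrix products, which keeps
peak memory proportional to the feature maps rather than to an im2col buffer
and routes the heavy lifting through BLAS.
"""

from __future__ import annotations

import math
from typing import Callable, Iterator, Sequence

import numpy as np
from scipy.special import erf

DTYPE = np.float32

# ---------------------------------------------------------------------------
# Tape
# ---------------------------------------------------------------------------


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autograd -----------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def reshape(self, *shape):
        return reshape(self, shape)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_grad(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None for t in ts)


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], None] | None) -> Tensor:
    out = Tensor(data)
    if backward is not None and _needs_grad(*parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a gradient back to the shape of a broadcast operand."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Pointwise and reduction ops
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def reshape(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(old))

    return _make(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, gi in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(gi)

    return _make(data, tensors, backward)


def mean(a: Tensor, axes=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.mean(axis=axes, keepdims=keepdims)
    n = a.data.size / data.size

    def backward(g):
        if not keepdims and axes is not None:
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g / n, a.shape).astype(DTYPE))

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def relu(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def backward(g):
        a._accumulate(g * (a.data > 0))

    return _make(data, (a,), backward)


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(a: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = _as_tensor(a)
    x = a.data
    phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    data = (x * phi).astype(DTYPE)

    def backward(g):
        pdf = np.exp(-0.5 * x * x) * _INV_SQRT2PI
        a._accumulate(g * (phi + x * pdf).astype(DTYPE))

    return _make(data, (a,), backward)


def log(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through the interior."""
    a = _as_tensor(a)
    data = np.clip(a.data, lo, hi)
    inside = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accumulate(g * inside)

    return _make(data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return _make(data, (a, b), backward)


# ---------------------------------------------------------------------------
# Convolution family (stride 1; pooling and zero-stuffing handle resampling)
# ---------------------------------------------------------------------------


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           padding: int = 0, groups: int = 1) -> Tensor:
    """Stride-1 grouped 2D cross-correlation.

    ``x``: (B, G*Cg, H, W); ``weight``: (G*Og, Cg, kh, kw); output
    (B, G*Og, Ho, Wo) with Ho = H + 2*padding - kh + 1.
    """
    x, weight = _as_tensor(x), _as_tensor(weight)
    B, C, H, W = x.shape
    OC, Cg, kh, kw = weight.shape
    if C != groups * Cg or OC % groups:
        raise ValueError(
            f"channel mismatch: x has {C} channels, weight expects "
            f"{groups}x{Cg} (groups={groups})")
    Og = OC // groups
    xp = _pad_hw(x.data, padding)
    Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    w6 = weight.data.reshape(groups, Og, Cg, kh, kw)
    out = np.zeros((B, groups, Og, Ho * Wo), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i:i + Ho, j:j + Wo].reshape(B, groups, Cg, -1)
            out += np.matmul(w6[:, :, :, i, j], patch)
    data = out.reshape(B, OC, Ho, Wo)
    if bias is not None:
        data = data + bias.data.reshape(1, OC, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g4 = g.reshape(B, groups, Og, Ho * Wo)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.zeros_like(w6)
            for i in range(kh):
                for j in range(kw):
                    patch = xp[:, :, i:i + Ho, j:j + Wo].reshape(
                        B, groups, Cg, -1)
                    gw[:, :, :, i, j] = np.einsum(
                        'bgol,bgcl->goc', g4, patch, optimize=True)
            weight._accumulate(gw.reshape(OC, Cg, kh, kw))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    contrib = np.matmul(
                        np.swapaxes(w6[:, :, :, i, j], -1, -2), g4)
                    gxp[:, :, i:i + Ho, j:j + Wo] += contrib.reshape(
                        B, C, Ho, Wo)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return _make(data, parents, backward)


def conv2d_per_sample(x: Tensor, weight: Tensor,
                      bias: Tensor | None = None, padding: int = 0) -> Tensor:
    """Stride-1 convolution with one kernel per batch element.

    ``weight``: (B, Cout, Cin, kh, kw); ``bias``: (B, Cout). Each sample is
    convolved with its own kernel — the observable contract of a dynamic
    convolution evaluated at batch size one.
    """
    x, weight = _as_tensor(x), _as_tensor(weight)
    B, C, H, W = x.shape
    Bw, OC, Cin, kh, kw = weight.shape
    if Bw != B or Cin != C:
        raise ValueError("per-sample weight must be (B, Cout, Cin, kh, kw) "
                         f"matching x (B={B}, C={C}); got {weight.shape}")
    xp = _pad_hw(x.data, padding)
    Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    out = np.zeros((B, OC, Ho * Wo), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i:i + Ho, j:j + Wo].reshape(B, C, -1)
            out += np.matmul(weight.data[:, :, :, i, j], patch)
    data = out.reshape(B, OC, Ho, Wo)
    if bias is not None:
        data = data + bias.data.reshape(B, OC, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g3 = g.reshape(B, OC, Ho * Wo)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(2, 3)))
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            for i in range(kh):
                for j in range(kw):
                    patch = xp[:, :, i:i + Ho, j:j + Wo].reshape(B, C, -1)
                    gw[:, :, :, i, j] = np.matmul(
                        g3, np.swapaxes(patch, -1, -2))
            weight._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    contrib = np.matmul(
                        np.swapaxes(weight.data[:, :, :, i, j], -1, -2), g3)
                    gxp[:, :, i:i + Ho, j:j + Wo] += contrib.reshape(
                        B, C, Ho, Wo)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return _make(data, parents, backward)


def dilate2(a: Tensor) -> Tensor:
    """Insert one zero between neighbouring pixels (stride-2 zero-stuffing)."""
    a = _as_tensor(a)
    B, C, H, W = a.shape
    data = np.zeros((B, C, 2 * H - 1, 2 * W - 1), dtype=DTYPE)
    data[:, :, ::2, ::2] = a.data

    def backward(g):
        a._accumulate(g[:, :, ::2, ::2])

    return _make(data, (a,), backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     kernel: int = 4, padding: int = 1) -> Tensor:
    """Stride-2 transposed convolution.

    ``weight``: (Cin, Cout, k, k). Implemented as zero-stuffing
    followed by a stride-1 convolution with the spatially flipped, transposed
    kernel; output spatial size is exactly 2x the input when k = 2*padding + 2.
    """
    Cin, Cout, kh, kw = weight.shape
    if kh != kernel or kh != kw:
        raise ValueError("weight kernel does not match declared size")
    wt = transpose01(weight)
    wt = flip_hw(wt)
    xz = dilate2(x)
    # stuffed length 2H-1 plus padding (k-1-p) each side gives exactly 2H
    # output when k = 2p + 2
    return conv2d(xz, wt, bias=bias, padding=kernel - 1 - padding)


def transpose01(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    data = np.swapaxes(a.data, 0, 1)

    def backward(g):
        a._accumulate(np.swapaxes(g, 0, 1))

    return _make(data, (a,), backward)


def flip_hw(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    data = a.data[..., ::-1, ::-1].copy()

    def backward(g):
        a._accumulate(g[..., ::-1, ::-1])

    return _make(data, (a,), backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Spatial dims must be even."""
    x = _as_tensor(x)
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2 requires even spatial dims, got {H}x{W}")
    x6 = x.data.reshape(B, C, H // 2, 2, W // 2, 2)
    tiles = x6.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
    idx = tiles.argmax(axis=-1)
    data = np.take_along_axis(tiles, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gt = np.zeros_like(tiles)
        np.put_along_axis(gt, idx[..., None], g[..., None], axis=-1)
        gx = gt.reshape(B, C, H // 2, W // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(B, C, H, W)
        x._accumulate(gx)

    return _make(data, (x,), backward)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1D corner-aligned linear interpolation matrix (n_out, n_in)."""
    A = np.zeros((n_out, n_in), dtype=DTYPE)
    if n_out == 1:
        A[0, 0] = 1.0
        return A
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    pos = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    lo = np.minimum(pos.astype(int), n_in - 2)
    frac = (pos - lo).astype(DTYPE)
    A[np.arange(n_out), lo] = 1.0 - frac
    A[np.arange(n_out), lo + 1] = frac
    return A


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Corner-aligned bilinear resampling to (out_h, out_w)."""
    x = _as_tensor(x)
    B, C, H, W = x.shape
    if (H, W) == (out_h, out_w):
        return x
    Ah = _interp_matrix(H, out_h)
    Aw = _interp_matrix(W, out_w)
    data = np.einsum('ph,bchw,qw->bcpq', Ah, x.data, Aw, optimize=True)

    def backward(g):
        x._accumulate(np.einsum('ph,bcpq,qw->bchw', Ah, g, Aw,
                                optimize=True).astype(DTYPE))

    return _make(data.astype(DTYPE), (x,), backward)


def fuse_banks(att: Tensor, bank: Tensor) -> Tensor:
    """Per-sample linear combination of a kernel bank.

    ``att``: (B, K) attention weights; ``bank``: (K, ...) stacked candidate
    kernels (or biases). Returns (B, ...) fused parameters.
    """
    att, bank = _as_tensor(att), _as_tensor(bank)
    K = bank.shape[0]
    if att.shape[-1] != K:
        raise ValueError(f"attention length {att.shape[-1]} != bank size {K}")
    data = np.tensordot(att.data, bank.data, axes=1)

    def backward(g):
        if att.requires_grad:
            axes = tuple(range(1, bank.data.ndim))
            att._accumulate(np.tensordot(g, bank.data, axes=(axes, axes)))
        if bank.requires_grad:
            bank._accumulate(np.tensordot(att.data.T, g, axes=1))

    return _make(data, (att, bank), backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Minimal parameter container with train/eval state."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Parameter]:
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                yield v
            elif isinstance(v, Module):
                yield from v.parameters()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Parameter):
                        yield item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix.rstrip("."), self
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v.named_modules(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{key}.{i}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Fan-in scaled uniform init (He et al. style, a=sqrt(5) convention)."""
    bound = math.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv2d(Module):
    """Standard stride-1 grouped convolution layer."""

    def __init__(self, c_in: int, c_out: int, kernel: int, *,
                 padding: int | None = None, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.padding = (kernel - 1) // 2 if padding is None else padding
        self.groups = groups
        fan_in = (c_in // groups) * kernel * kernel
        self.weight = Parameter(kaiming_uniform(
            rng, (c_out, c_in // groups, kernel, kernel), fan_in))
        self.bias = Parameter(kaiming_uniform(rng, (c_out,), fan_in)) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      padding=self.padding, groups=self.groups)


class ConvTranspose2d(Module):
    """Stride-2 transposed convolution (kernel k, padding (k-2)/2)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, *,
                 rng: np.random.Generator):
        super().__init__()
        if kernel % 2:
            raise ValueError("even kernel required for exact 2x upsampling")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.padding = (kernel - 2) // 2
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(kaiming_uniform(
            rng, (c_in, c_out, kernel, kernel), fan_in))
        self.bias = Parameter(kaiming_uniform(rng, (c_out,), fan_in))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias,
                                kernel=self.kernel, padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(channels, dtype=DTYPE))
        self.bias = Parameter(np.zeros(channels, dtype=DTYPE))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            m = x.data.mean(axis=(0, 2, 3))
            v = x.data.var(axis=(0, 2, 3))
            n = x.data.size / self.channels
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * m).astype(DTYPE)
            unbiased = v * n / max(n - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(DTYPE)
        else:
            m, v = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(v + self.eps)
        scale = (self.weight.data * inv).reshape(1, -1, 1, 1)
        xm = x.data - m.reshape(1, -1, 1, 1)
        data = xm * scale + self.bias.data.reshape(1, -1, 1, 1)
        training = self.training
        weight, bias = self.weight, self.bias
        xt = x

        def backward(g):
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            xhat = xm * inv.reshape(1, -1, 1, 1)
            if weight.requires_grad:
                weight._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if not xt.requires_grad:
                return
            gs = g * weight.data.reshape(1, -1, 1, 1)
            if training:
                n = g.size / g.shape[1]
                t1 = gs.sum(axis=(0, 2, 3), keepdims=True) / n
                t2 = (gs * xhat).sum(axis=(0, 2, 3), keepdims=True) / n
                gx = (gs - t1 - xhat * t2) * inv.reshape(1, -1, 1, 1)
            else:
                gx = gs * inv.reshape(1, -1, 1, 1)
            xt._accumulate(gx.astype(DTYPE))

        return _make(data.astype(DTYPE), (x, self.weight, self.bias), backward)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, *, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        if zero_init:
            self.weight = Parameter(np.zeros((n_in, n_out), dtype=DTYPE))
            self.bias = Parameter(np.zeros(n_out, dtype=DTYPE))
        else:
            self.weight = Parameter(kaiming_uniform(rng, (n_in, n_out), n_in))
            self.bias = Parameter(kaiming_uniform(rng, (n_out,), n_in))

    def forward(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.weight), self.bias)


class Adam:
    """Adam optimizer with the conventional defaults."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
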