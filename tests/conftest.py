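"""Shared fixtures and independent numerical oracles for the test suite."""

from dataclasses import replace

import numpy as np
import pytest

from lightawnet import NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A narrow configuration for fast end-to-end tests (32x32 inputs)."""
    return replace(NetworkConfig(),
                   stage_widths=(2, 4, 4, 4, 4, 8, 4, 8, 8, 8, 2))


# ---------------------------------------------------------------------------
# Brute-force oracles, written independently of the package's conv code:
# plain quadruple loops over output positions and kernel taps.
# ---------------------------------------------------------------------------


def naive_conv2d(x, w, b=None, pad=0, groups=1):
    """Direct sliding-window convolution, float64 accumulation."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    B, C, H, W = x.shape
    OC, Cg, kh, kw = w.shape
    og = OC // groups
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    out = np.zeros((B, OC, Ho, Wo))
    for bi in range(B):
        for o in range(OC):
            g = o // og
            for i in range(Ho):
                for j in range(Wo):
                    acc = 0.0
                    for c in range(Cg):
                        for u in range(kh):
                            for v in range(kw):
                                acc += (w[o, c, u, v]
                                        * xp[bi, g * Cg + c, i + u, j + v])
                    out[bi, o, i, j] = acc
            if b is not None:
                out[bi, o] += b[o]
    return out


def naive_conv_transpose2d(x, w, b=None, kernel=4, padding=1, stride=2):
    """Direct transposed convolution by input-scatter accumulation."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    B, C, H, W = x.shape
    Cin, Cout, kh, kw = w.shape
    Ho = (H - 1) * stride - 2 * padding + kernel
    Wo = (W - 1) * stride - 2 * padding + kernel
    full = np.zeros((B, Cout, Ho + 2 * padding, Wo + 2 * padding))
    for bi in range(B):
        for c in range(Cin):
            for i in range(H):
                for j in range(W):
                    full[bi, :, i * stride:i * stride + kh,
                         j * stride:j * stride + kw] += (
                        x[bi, c, i, j] * w[c])
    out = full[:, :, padding:padding + Ho, padding:padding + Wo]
    if b is not None:
        out = out + b.reshape(1, -1, 1, 1)
    return out


def naive_bilinear(x, out_h, out_w):
    """Corner-aligned bilinear resize evaluated pointwise."""
    x = np.asarray(x, dtype=np.float64)
    B, C, H, W = x.shape
    out = np.zeros((B, C, out_h, out_w))
    for p in range(out_h):
        ys = p * (H - 1) / (out_h - 1) if out_h > 1 else 0.0
        y0 = min(int(ys), H - 2) if H > 1 else 0
        fy = ys - y0
        for q in range(out_w):
            xs = q * (W - 1) / (out_w - 1) if out_w > 1 else 0.0
            x0 = min(int(xs), W - 2) if W > 1 else 0
            fx = xs - x0
            if H == 1:
                top = x[:, :, 0, x0] if W == 1 else (
                    (1 - fx) * x[:, :, 0, x0] + fx * x[:, :, 0, x0 + 1])
                out[:, :, p, q] = top
                continue
            if W == 1:
                out[:, :, p, q] = ((1 - fy) * x[:, :, y0, 0]
                                   + fy * x[:, :, y0 + 1, 0])
                continue
            top = (1 - fx) * x[:, :, y0, x0] + fx * x[:, :, y0, x0 + 1]
            bot = (1 - fx) * x[:, :, y0 + 1, x0] + fx * x[:, :, y0 + 1, x0 + 1]
            out[:, :, p, q] = (1 - fy) * top + fy * bot
    return out


def numeric_grad(f, arr, eps=1e-3):
    """Central finite differences of scalar f with respect to ``arr``."""
    g = np.zeros_like(arr, dtype=np.float64)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + eps
        hi = f()
        arr[i] = orig - eps
        lo = f()
        arr[i] = orig
        g[i] = (hi - lo) / (2 * eps)
    return g
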