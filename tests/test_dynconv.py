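"""Dynamic convolution: attention weights, bank fusion, per-sample conv."""

import numpy as np
import pytest

from lightawnet.autodiff import Tensor, conv2d, mean
from lightawnet.dynconv import (DynConv2d, DynConvSpec, attention_weights,
                                fuse_kernels)
from conftest import naive_conv2d


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestAttentionWeights:
    def test_zero_input_and_zero_bias_gives_neutral_half_weights(self):
        spec = DynConvSpec(c_in=3, c_out=2, K=4)
        x = Tensor(np.zeros((2, 3, 4, 4), dtype=np.float32))
        w = Tensor(np.random.default_rng(0).standard_normal(
            (3, 4)).astype(np.float32))
        b = Tensor(np.zeros(4, dtype=np.float32))
        out = attention_weights(x, spec, w, b)
        np.testing.assert_allclose(out.data, 0.5, atol=1e-7)

    def test_default_bank_size_yields_four_weights_per_sample(self, rng):
        spec = DynConvSpec(c_in=5, c_out=3)          # K defaults to 4
        layer = DynConv2d(spec, rng=rng)
        x = Tensor(rng.random((3, 5, 6, 6), dtype=np.float32))
        att = layer.attention(x)
        assert att.shape == (3, 4)
        assert np.all((att.data > 0) & (att.data < 1))

    def test_matches_hand_computed_pooled_affine_sigmoid(self):
        """(1,2,2,2) input with hand-set affine: direct arithmetic oracle."""
        spec = DynConvSpec(c_in=2, c_out=1, K=2)
        x = np.arange(8, dtype=np.float32).reshape(1, 2, 2, 2)
        pooled = x.mean(axis=(2, 3))[0]              # [1.5, 5.5]
        w = np.array([[1.0, -0.5], [0.25, 0.1]], dtype=np.float32)
        b = np.array([0.1, -0.2], dtype=np.float32)
        expected = _sigmoid(pooled @ w + b)
        out = attention_weights(Tensor(x), spec, Tensor(w), Tensor(b))
        np.testing.assert_allclose(out.data[0], expected, rtol=1e-5)

    def test_channel_mismatch_is_rejected(self, rng):
        spec = DynConvSpec(c_in=3, c_out=2, K=4)
        with pytest.raises(ValueError):
            attention_weights(Tensor(np.zeros((1, 5, 4, 4))), spec,
                              Tensor(np.zeros((3, 4))),
                              Tensor(np.zeros(4)))


class TestFuseKernels:
    def test_one_hot_selects_a_single_bank_entry(self, rng):
        bank = rng.standard_normal((3, 2, 2, 3, 3)).astype(np.float32)
        biases = rng.standard_normal((3, 2)).astype(np.float32)
        for j in range(3):
            att = np.zeros((1, 3), dtype=np.float32)
            att[0, j] = 1.0
            fw, fb = fuse_kernels(Tensor(att), Tensor(bank), Tensor(biases))
            np.testing.assert_allclose(fw.data[0], bank[j], atol=1e-7)
            np.testing.assert_allclose(fb.data[0], biases[j], atol=1e-7)

    def test_identical_entries_scale_by_weight_sum(self, rng):
        entry = rng.standard_normal((2, 2, 3, 3)).astype(np.float32)
        bank = np.stack([entry] * 4)
        att = rng.random((2, 4)).astype(np.float32)
        fw = fuse_kernels(Tensor(att), Tensor(bank))
        for i in range(2):
            np.testing.assert_allclose(
                fw.data[i], att[i].sum() * entry, rtol=1e-5)

    def test_two_scalar_kernels_hand_arithmetic(self):
        """1x1 kernels {2, 6} with weights (0.25, 0.5) fuse to 3.5."""
        bank = np.array([2.0, 6.0], dtype=np.float32).reshape(2, 1, 1, 1, 1)
        att = np.array([[0.25, 0.5]], dtype=np.float32)
        fw = fuse_kernels(Tensor(att), Tensor(bank))
        assert fw.data[0, 0, 0, 0, 0] == pytest.approx(3.5)

    def test_length_mismatch_is_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse_kernels(Tensor(np.ones((1, 3))),
                         Tensor(np.zeros((4, 1, 1, 1, 1))))


class TestDynamicConv:
    def test_one_hot_attention_reduces_to_static_convolution(self, rng):
        """Forcing a one-hot mix must reproduce a plain conv with that
        kernel to within float tolerance."""
        spec = DynConvSpec(c_in=3, c_out=4, K=4)
        layer = DynConv2d(spec, rng=rng)
        x = rng.standard_normal((2, 3, 6, 6)).astype(np.float32)
        for j in range(4):
            att = np.zeros((2, 4), dtype=np.float32)
            att[:, j] = 1.0
            out = layer(Tensor(x), att=Tensor(att))
            ref = conv2d(Tensor(x), Tensor(layer.kernels.data[j]),
                         Tensor(layer.biases.data[j]), padding=1)
            np.testing.assert_allclose(out.data, ref.data, atol=1e-6)

    def test_single_kernel_with_unit_weight_is_standard_conv(self, rng):
        spec = DynConvSpec(c_in=2, c_out=3, K=1)
        layer = DynConv2d(spec, rng=rng)
        x = rng.standard_normal((1, 2, 5, 5)).astype(np.float32)
        out = layer(Tensor(x), att=Tensor(np.ones((1, 1), dtype=np.float32)))
        ref = naive_conv2d(x, layer.kernels.data[0], layer.biases.data[0],
                           pad=1)
        np.testing.assert_allclose(out.data, ref, rtol=1e-4, atol=1e-5)

    def test_batch_equals_concatenated_single_sample_passes(self, rng):
        """Per-sample weight generation: a batch forward is exactly the
        stack of independent single-sample forwards."""
        spec = DynConvSpec(c_in=2, c_out=3, K=4)
        layer = DynConv2d(spec, rng=rng)
        layer.att_w.data = rng.standard_normal((2, 4)).astype(np.float32)
        layer.att_b.data = rng.standard_normal(4).astype(np.float32)
        x = rng.standard_normal((5, 2, 6, 6)).astype(np.float32)
        full = layer(Tensor(x)).data
        singles = np.concatenate(
            [layer(Tensor(x[i:i + 1])).data for i in range(5)])
        np.testing.assert_allclose(full, singles, atol=1e-6)

    def test_matches_full_brute_force_oracle(self, rng):
        """1x4x4 input, K=2: pooled-affine-sigmoid weights, numerically
        fused kernel, naive sliding-window convolution."""
        spec = DynConvSpec(c_in=1, c_out=2, K=2)
        layer = DynConv2d(spec, rng=rng)
        layer.att_w.data = np.array([[0.5, -1.0]], dtype=np.float32)
        layer.att_b.data = np.array([0.2, 0.0], dtype=np.float32)
        x = rng.standard_normal((1, 1, 4, 4)).astype(np.float32)
        pooled = x.mean(axis=(2, 3))
        att = _sigmoid(pooled @ layer.att_w.data + layer.att_b.data)
        kern = np.einsum('bk,kocij->bocij', att, layer.kernels.data)[0]
        bias = (att @ layer.biases.data)[0]
        ref = naive_conv2d(x, kern, bias, pad=1)
        out = layer(Tensor(x))
        np.testing.assert_allclose(out.data, ref, rtol=1e-4, atol=1e-5)

    def test_all_bank_entries_and_attention_receive_gradient(self, rng):
        """A scalar loss on a generic input must touch every candidate
        kernel and the attention affine."""
        spec = DynConvSpec(c_in=2, c_out=2, K=3)
        layer = DynConv2d(spec, rng=rng)
        layer.att_w.data = rng.standard_normal((2, 3)).astype(np.float32)
        x = Tensor(rng.standard_normal((2, 2, 5, 5)).astype(np.float32))
        loss = mean(layer(x) * layer(x))
        loss.backward()
        for k in range(3):
            assert np.abs(layer.kernels.grad[k]).max() > 0
            assert np.abs(layer.biases.grad[k]).max() > 0
        assert np.abs(layer.att_w.grad).max() > 0
        assert np.abs(layer.att_b.grad).max() > 0

    def test_parameter_count_is_affine_in_bank_size(self, rng):
        def nparams(K):
            layer = DynConv2d(DynConvSpec(c_in=3, c_out=4, K=K), rng=rng)
            return sum(p.data.size for p in layer.parameters())

        deltas = [nparams(K + 1) - nparams(K) for K in (1, 2, 5, 9)]
        assert len(set(deltas)) == 1
        bank_entry = 3 * 4 * 9 + 4        # one kernel + bias
        assert deltas[0] == bank_entry + 3 + 1   # plus one affine column
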