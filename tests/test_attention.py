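"""Attention contracts: gate ranges, closed-form oracles, shape preservation."""

import numpy as np
import pytest

from canopyseg import nn
from canopyseg.attention import (
    CAS,
    ECA,
    AttentionSpec,
    AxialEnhance,
    ChannelAttention,
    SpatialAttention,
    build_attention,
)
from canopyseg.nn.tensor import Tensor


def zero_params(module):
    for p in module.parameters():
        p.data = np.zeros_like(p.data)


def run(module, fmap):
    return module(Tensor(np.asarray(fmap, dtype=np.float32)[None])).data[0]


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestChannelAttention:
    def test_zero_mlp_gate_is_exactly_half(self, rng):
        m = ChannelAttention(8, reduction_ratio=2)
        zero_params(m)
        f = rng.normal(size=(8, 5, 5)).astype(np.float32)
        assert np.array_equal(run(m, f), 0.5 * f)

    def test_shape_and_gate_shape(self, rng):
        m = ChannelAttention(8, reduction_ratio=4)
        f = Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32))
        assert m(f).shape == (1, 8, 16, 16)
        assert m.gate(f).shape == (1, 8, 1, 1)

    def test_constant_channels_identity_mlp(self):
        """Channels constant at +1 / -1, identity MLP: avg = max pooled
        descriptors pass the bottleneck ReLU, so the positive channel gates
        at sigmoid(1+1) and the clamped negative one at sigmoid(0)."""
        m = ChannelAttention(2, reduction_ratio=1)
        m.fc1.weight.data = np.eye(2, dtype=np.float32)
        m.fc2.weight.data = np.eye(2, dtype=np.float32)
        f = np.stack([np.ones((3, 3)), -np.ones((3, 3))]).astype(np.float32)
        out = run(m, f)
        assert np.allclose(out[0], sigmoid(2.0) * 1.0, atol=1e-6)
        assert np.allclose(out[1], sigmoid(0.0) * -1.0, atol=1e-6)

    def test_reduction_exceeding_channels_is_an_error(self):
        with pytest.raises(ValueError, match="16.*8|8.*16"):
            ChannelAttention(8, reduction_ratio=16)


class TestAxialEnhance:
    def test_uniform_attention_equals_row_plus_column_means(self):
        m = AxialEnhance(1)
        m.wq.weight.data = np.zeros((1, 1), dtype=np.float32)
        m.wk.weight.data = np.zeros((1, 1), dtype=np.float32)
        m.wv.weight.data = np.eye(1, dtype=np.float32)
        f = np.array([[[1.0, 3.0], [5.0, 7.0]]], dtype=np.float32)
        out = run(m, f)
        assert np.allclose(out, [[[5.0, 7.0], [9.0, 11.0]]], atol=1e-6)

    def test_uniform_attention_oracle_random_maps(self, rng):
        """Zero Q/K + identity V reduces to row-mean + column-mean broadcast."""
        C = 3
        m = AxialEnhance(C)
        m.wq.weight.data = np.zeros((C, C), dtype=np.float32)
        m.wk.weight.data = np.zeros((C, C), dtype=np.float32)
        m.wv.weight.data = np.eye(C, dtype=np.float32)
        f = rng.normal(size=(C, 5, 5)).astype(np.float32)
        expected = f.mean(axis=2, keepdims=True) + f.mean(axis=1, keepdims=True)
        assert np.allclose(run(m, f), expected, atol=1e-5)

    def test_length_one_sequences(self, rng):
        m = AxialEnhance(4)
        f = rng.normal(size=(4, 1, 1)).astype(np.float32)
        out = run(m, f)
        # each attention attends only to itself: output = 2 * V f
        expected = 2.0 * (m.wv.weight.data.T @ f[:, 0, 0])
        assert np.allclose(out[:, 0, 0], expected, atol=1e-5)

    def test_shape_preserved(self, rng):
        m = AxialEnhance(4)
        assert run(m, rng.normal(size=(4, 5, 7)).astype(np.float32)).shape == (4, 5, 7)


class TestSpatialAttention:
    def test_zero_conv_gate_is_exactly_half(self, rng):
        m = SpatialAttention(7)
        zero_params(m)
        f = rng.normal(size=(16, 32, 32)).astype(np.float32)
        assert np.array_equal(run(m, f), 0.5 * f)
        assert m.gate(Tensor(f[None])).shape == (1, 1, 32, 32)

    def test_gate_matches_pixel_loop_oracle(self, rng):
        """Literal loop over pixels: gate = sigmoid(conv([mean;max]))."""
        k = 3
        m = SpatialAttention(k)
        w = m.conv.weight.data
        b = float(m.conv.bias.data[0])
        f = rng.normal(size=(4, 6, 6)).astype(np.float32)
        desc = np.stack([f.mean(axis=0), f.max(axis=0)])
        pad = np.pad(desc, ((0, 0), (1, 1), (1, 1)))
        gate = np.empty((6, 6))
        for i in range(6):
            for j in range(6):
                gate[i, j] = sigmoid((pad[:, i : i + k, j : j + k] * w[0]).sum() + b)
        assert np.allclose(run(m, f), f * gate[None], atol=1e-5)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SpatialAttention(4)
        with pytest.raises(ValueError, match="odd"):
            AttentionSpec(kind="cas", spatial_kernel=6)


class TestECA:
    def test_zero_weights_gate_half(self, rng):
        m = ECA(8, kernel=3)
        zero_params(m)
        f = rng.normal(size=(8, 4, 4)).astype(np.float32)
        assert np.array_equal(run(m, f), 0.5 * f)

    def test_impulse_kernel_gates_at_channel_mean(self, rng):
        m = ECA(6, kernel=3)
        m.weight.data = np.array([0.0, 1.0, 0.0], dtype=np.float32).reshape(1, 1, 3, 1)
        f = rng.normal(size=(6, 4, 4)).astype(np.float32)
        f[2] = 0.0  # constant-zero channel gates at exactly 0.5
        out = run(m, f)
        gates = sigmoid(f.mean(axis=(1, 2)))
        assert np.allclose(out, f * gates[:, None, None], atol=1e-5)
        assert np.allclose(out[2], 0.0)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ECA(8, kernel=4)


class TestCAS:
    def test_composition_with_trivial_parameters(self, rng):
        """Zero gates + identity value projection: closed-form composite."""
        m = CAS(2, AttentionSpec(kind="cas", reduction_ratio=1, spatial_kernel=3))
        zero_params(m)
        m.axial.wv.weight.data = np.eye(2, dtype=np.float32)
        f = rng.normal(size=(2, 4, 4)).astype(np.float32)
        half = 0.5 * f
        axial = half.mean(axis=2, keepdims=True) + half.mean(axis=1, keepdims=True)
        assert np.allclose(run(m, f), 0.5 * axial, atol=1e-5)

    @pytest.mark.parametrize("shape", [(8, 5, 5), (4, 7, 3), (16, 6, 6), (2, 2, 9), (12, 4, 8)])
    def test_shape_preserved_and_finite(self, rng, shape):
        nn.manual_seed(1)
        m = CAS(shape[0], AttentionSpec(kind="cas", reduction_ratio=2))
        out = run(m, rng.normal(size=shape).astype(np.float32))
        assert out.shape == shape
        assert np.isfinite(out).all()

    def test_deterministic_forward(self, rng):
        nn.manual_seed(3)
        m = CAS(4, AttentionSpec(kind="cas", reduction_ratio=2))
        f = rng.normal(size=(4, 6, 6)).astype(np.float32)
        assert np.array_equal(run(m, f), run(m, f))

    def test_wide_stage5_shape(self, rng):
        """ResNet-50 stage-5 width (2048 channels) passes shape-preserving."""
        nn.manual_seed(0)
        m = CAS(2048, AttentionSpec(kind="cas"))
        f = rng.normal(size=(2048, 4, 4)).astype(np.float32)
        assert run(m, f).shape == (2048, 4, 4)


def test_gates_strictly_inside_unit_interval(rng):
    nn.manual_seed(5)
    f = Tensor(rng.normal(size=(2, 8, 6, 6)).astype(np.float32) * 3)
    for m in (ChannelAttention(8, 2), SpatialAttention(3), ECA(8, 3)):
        g = m.gate(f).data
        assert (g > 0).all() and (g < 1).all()


def test_build_attention_factory():
    spec = AttentionSpec(kind="none")
    assert isinstance(build_attention(8, spec), nn.Identity)
    for kind, cls in (("cas", CAS), ("eca", ECA), ("axial", AxialEnhance)):
        assert isinstance(build_attention(8, AttentionSpec(kind=kind, reduction_ratio=2)), cls)
    with pytest.raises(ValueError, match="kind"):
        AttentionSpec(kind="senet")
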