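"""DS-MLP: split/shift/gate oracles, split-attention convexity, and the
shape contract of the assembled block."""

import numpy as np
import pytest
from scipy.special import erf, expit

from heanet.autodiff import Tensor
from heanet.ds_mlp import (
    ChannelShift,
    DualShiftMLP,
    SplitAttention,
    spatial_shift,
    split_channels,
)


def spatial_shift_oracle(x: np.ndarray) -> np.ndarray:
    """Literal slice-assignment semantics, channel quarters in 4 directions."""
    out = x.copy()
    c = x.shape[0]
    q = c // 4
    out[0:q, :, 1:] = x[0:q, :, :-1]  # +1 along width
    out[q : 2 * q, :, :-1] = x[q : 2 * q, :, 1:]  # −1 along width
    out[2 * q : 3 * q, 1:, :] = x[2 * q : 3 * q, :-1, :]  # +1 along height
    out[3 * q : 4 * q, :-1, :] = x[3 * q : 4 * q, 1:, :]  # −1 along height
    return out


def channel_shift_oracle(t2: np.ndarray, w: np.ndarray, b: float) -> np.ndarray:
    """Explicit max loop + explicit length-3 sliding dot product + sigmoid."""
    C = t2.shape[0]
    gmp = np.array([t2[c].max() for c in range(C)])
    padded = np.concatenate([[0.0], gmp, [0.0]])
    conv = np.array(
        [padded[i] * w[0] + padded[i + 1] * w[1] + padded[i + 2] * w[2] + b for i in range(C)]
    )
    gate = expit(conv)
    return gate[:, None, None] * t2


class TestSplit:
    def test_definition_of_split(self, rng):
        x = rng.standard_normal((4, 3, 3))
        t1, t2 = split_channels(Tensor(x))
        np.testing.assert_array_equal(t1.data, x[:2])
        np.testing.assert_array_equal(t2.data, x[2:])

    def test_concat_round_trip_is_lossless(self, rng):
        x = rng.standard_normal((2, 6, 4, 5))
        t1, t2 = split_channels(Tensor(x))
        np.testing.assert_array_equal(np.concatenate([t1.data, t2.data], axis=1), x)

    def test_odd_channel_count_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            split_channels(Tensor(rng.standard_normal((3, 2, 2))))


class TestSpatialShift:
    def test_matches_slice_assignment_oracle_on_numbered_grid(self):
        x = np.arange(1.0, 17.0).reshape(4, 2, 2)
        np.testing.assert_array_equal(
            spatial_shift(Tensor(x)).data, spatial_shift_oracle(x)
        )

    @pytest.mark.parametrize("shape", [(4, 1, 1), (4, 5, 5), (8, 5, 5), (8, 3, 4)])
    def test_matches_oracle_on_random_tensors(self, shape, rng):
        x = rng.standard_normal(shape)
        np.testing.assert_array_equal(
            spatial_shift(Tensor(x)).data, spatial_shift_oracle(x)
        )

    def test_constant_input_is_invariant(self):
        x = np.full((8, 4, 4), 2.5)
        np.testing.assert_array_equal(spatial_shift(Tensor(x)).data, x)

    def test_batched_matches_unbatched(self, rng):
        x = rng.standard_normal((2, 4, 3, 3))
        out = spatial_shift(Tensor(x)).data
        for b in range(2):
            np.testing.assert_array_equal(out[b], spatial_shift_oracle(x[b]))

    def test_interior_multiset_preserved_per_channel(self, rng):
        # a single shift permutes interior values; only boundary cells differ
        x = rng.standard_normal((4, 6, 6))
        out = spatial_shift(Tensor(x)).data
        for c in range(4):
            inner_in = np.sort(x[c, 1:-1, 1:-1].ravel())
            # the shifted interior came from somewhere inside the original
            assert np.isin(out[c, 2:-2, 2:-2], x[c]).all()
            assert inner_in.size > 0

    def test_indivisible_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible by 4"):
            spatial_shift(Tensor(rng.standard_normal((6, 3, 3))))


class TestChannelShift:
    @pytest.mark.usefixtures("f64")
    def test_zero_input_annihilated(self):
        cs = ChannelShift(np.random.default_rng(0))
        out = cs(Tensor(np.zeros((6, 4, 4))))
        np.testing.assert_array_equal(out.data, 0.0)

    @pytest.mark.usefixtures("f64")
    def test_gate_bounds_output(self, rng):
        cs = ChannelShift(np.random.default_rng(1))
        x = rng.standard_normal((8, 5, 5))
        out = cs(Tensor(x)).data
        assert np.all(np.abs(out) <= np.abs(x) + 1e-12)

    @pytest.mark.usefixtures("f64")
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cs = ChannelShift(rng)
        x = rng.standard_normal((8, 4, 6))
        w = cs.kernel.weight.data.ravel()
        b = float(cs.kernel.bias.data[0])
        np.testing.assert_allclose(
            cs(Tensor(x)).data, channel_shift_oracle(x, w, b), atol=1e-6
        )


def split_attention_oracle(t1: np.ndarray, t2: np.ndarray, sa: SplitAttention) -> np.ndarray:
    """Per-channel loop re-implementation of the split-attention fusion."""
    Cp = t1.shape[0]
    alpha = np.array([t1[c].mean() + t2[c].mean() for c in range(Cp)])
    h = alpha @ sa.mlp1.weight.data + sa.mlp1.bias.data
    h = h * 0.5 * (1.0 + erf(h / np.sqrt(2.0)))  # GELU
    logits = (h @ sa.mlp2.weight.data + sa.mlp2.bias.data).reshape(2, Cp)
    e = np.exp(logits - logits.max(axis=0, keepdims=True))
    w = e / e.sum(axis=0, keepdims=True)
    out = np.empty_like(t1)
    for c in range(Cp):
        out[c] = w[0, c] * t1[c] + w[1, c] * t2[c]
    return out


class TestSplitAttention:
    @pytest.mark.usefixtures("f64")
    def test_weights_are_convex_per_channel(self, rng):
        sa = SplitAttention(8, np.random.default_rng(3))
        ab = sa.attention_weights(
            Tensor(rng.standard_normal((8, 4, 4))), Tensor(rng.standard_normal((8, 4, 4)))
        )
        np.testing.assert_allclose(ab.data.sum(axis=-2), 1.0, atol=1e-12)

    @pytest.mark.usefixtures("f64")
    def test_zero_logits_give_even_blend(self, rng):
        sa = SplitAttention(4, np.random.default_rng(4))
        sa.mlp2.weight.data[:] = 0.0
        sa.mlp2.bias.data[:] = 0.0
        t1 = rng.standard_normal((4, 3, 3))
        t2 = rng.standard_normal((4, 3, 3))
        np.testing.assert_allclose(
            sa(Tensor(t1), Tensor(t2)).data, 0.5 * t1 + 0.5 * t2, atol=1e-12
        )

    @pytest.mark.usefixtures("f64")
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_per_channel_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sa = SplitAttention(8, rng)
        t1 = rng.standard_normal((8, 5, 5))
        t2 = rng.standard_normal((8, 5, 5))
        np.testing.assert_allclose(
            sa(Tensor(t1), Tensor(t2)).data, split_attention_oracle(t1, t2, sa), atol=1e-6
        )

    def test_shape_mismatch_rejected(self, rng):
        sa = SplitAttention(4, np.random.default_rng(5))
        with pytest.raises(ValueError, match="differ"):
            sa(Tensor(rng.standard_normal((4, 3, 3))), Tensor(rng.standard_normal((4, 2, 3))))


class TestDualShiftMLP:
    @pytest.mark.usefixtures("f64")
    def test_shape_contract(self, rng):
        block = DualShiftMLP(64, np.random.default_rng(0))
        x = rng.standard_normal((64, 14, 14))
        assert block(Tensor(x)).shape == (64, 14, 14)

    def test_channels_not_divisible_by_8_rejected(self):
        with pytest.raises(ValueError, match="divisible by 8"):
            DualShiftMLP(12, np.random.default_rng(0))

    @pytest.mark.usefixtures("f64")
    def test_zero_input_gives_bias_image(self):
        block = DualShiftMLP(16, np.random.default_rng(1))
        out = block(Tensor(np.zeros((16, 4, 4)))).data
        # all-zero input survives the shifts/gates as zero, so the output is
        # the output-MLP bias, constant over space
        expected = np.broadcast_to(block.out_mlp.bias.data[:, None, None], out.shape)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    @pytest.mark.usefixtures("f64")
    def test_gradients_finite_and_nonzero(self, rng):
        block = DualShiftMLP(16, np.random.default_rng(2))
        x = Tensor(rng.standard_normal((1, 16, 8, 8)), requires_grad=True)
        (block(x) ** 2.0).sum().backward()
        for name, p in block.named_parameters():
            assert p.grad is not None, name
            assert np.all(np.isfinite(p.grad)), name
        grads = np.concatenate([p.grad.ravel() for _, p in block.named_parameters()])
        assert np.any(grads != 0.0)
        assert np.all(np.isfinite(x.grad))
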