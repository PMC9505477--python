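"""Dual-channel Shift MLP (DS-MLP) bottleneck block.

The block splits the C input channels into two halves and enhances each
with a different, nearly parameter-free mixing operation before fusing
them back:

* the first half goes through a **spatial shift**: its channels are split
  into four quarters displaced by one pixel (+w, −w, +h, −h), mixing
  information between neighbouring spatial positions without convolutions;
* the second half goes through a **channel shift**: a global-max-pooled
  channel descriptor is passed through a kernel-3 1-D convolution (cross-
  channel interaction without dimensionality reduction) and a sigmoid, and
  the resulting gate re-weights the half multiplicatively;
* the two enhanced halves are fused by **split attention**: a bottleneck
  MLP on the pooled sum of both branches emits per-channel softmax weights
  over the two splits, and the output is the weighted convex combination;
* a final linear channel projection C/2 → C restores the input width, so
  the block maps [C, H, W] → [C, H, W].

C must be divisible by 8 (two halves, four shift quarters).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, stack
from .nn import Linear, Module, global_max_pool, softmax

__all__ = ["DualShiftMLP", "SplitAttention", "split_channels", "spatial_shift", "ChannelShift"]


def split_channels(t: Tensor) -> tuple[Tensor, Tensor]:
    """Split [.., C, H, W] into two [.., C/2, H, W] halves along channels."""
    c_axis = t.ndim - 3
    C = t.shape[c_axis]
    if C % 2:
        raise ValueError(f"channel count must be even to split, got C={C}")
    sl = [slice(None)] * t.ndim
    sl[c_axis] = slice(0, C // 2)
    t1 = t[tuple(sl)]
    sl[c_axis] = slice(C // 2, C)
    t2 = t[tuple(sl)]
    return t1, t2


def spatial_shift(t1: Tensor) -> Tensor:
    """Shift the four channel quarters one pixel in four directions.

    Quarter 1 moves +1 along width, quarter 2 −1 along width, quarter 3 +1
    along height, quarter 4 −1 along height.  Boundary rows/columns that
    the shift does not write keep their original values, matching
    slice-assignment semantics.  Shape is preserved.
    """
    c_axis = t1.ndim - 3
    c = t1.shape[c_axis]
    if c % 4:
        raise ValueError(f"spatial_shift needs channels divisible by 4, got c={c}")
    q = c // 4

    def chans(a, b):
        sl = [slice(None)] * t1.ndim
        sl[c_axis] = slice(a, b)
        return t1[tuple(sl)]

    def wslice(x, s):
        sl = [slice(None)] * x.ndim
        sl[-1] = s
        return x[tuple(sl)]

    def hslice(x, s):
        sl = [slice(None)] * x.ndim
        sl[-2] = s
        return x[tuple(sl)]

    q1, q2, q3, q4 = (chans(i * q, (i + 1) * q) for i in range(4))
    # out[1:] = in[:-1]; out[0] stays
    s1 = concat([wslice(q1, slice(0, 1)), wslice(q1, slice(0, -1))], axis=t1.ndim - 1)
    # out[:-1] = in[1:]; out[-1] stays
    s2 = concat([wslice(q2, slice(1, None)), wslice(q2, slice(-1, None))], axis=t1.ndim - 1)
    s3 = concat([hslice(q3, slice(0, 1)), hslice(q3, slice(0, -1))], axis=t1.ndim - 2)
    s4 = concat([hslice(q4, slice(1, None)), hslice(q4, slice(-1, None))], axis=t1.ndim - 2)
    return concat([s1, s2, s3, s4], axis=c_axis)


class ChannelShift(Module):
    """GMP → kernel-3 1-D conv over channels → sigmoid gate ⊗ input.

    The 1-D convolution is a single filter with stride 1 and zero
    same-padding, so the gate vector keeps the input's channel length; no
    channel reduction happens anywhere in the branch.
    """

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.kernel = Linear(3, 1, rng)  # the 3 taps of the 1-D convolution

    def forward(self, t2: Tensor) -> Tensor:
        if t2.ndim == 3:
            return self.forward(t2.reshape(1, *t2.shape)).reshape(t2.shape)
        B, C, H, W = t2.shape
        v = global_max_pool(t2)  # [B, C]
        zero = Tensor(np.zeros((B, 1), dtype=t2.dtype))
        vp = concat([zero, v, zero], axis=1)  # zero same-padding
        taps = stack(
            [vp[:, 0:C], vp[:, 1 : C + 1], vp[:, 2 : C + 2]], axis=2
        )  # [B, C, 3]
        g = self.kernel(taps).reshape(B, C).sigmoid()
        return g.reshape(B, C, 1, 1) * t2


class SplitAttention(Module):
    """Two-way split attention: softmax convex combination of branches.

    α ∈ R^{C'} sums the per-branch spatial means; a bottleneck MLP
    (C' → max(C'/4, 4) → 2C', GELU in between) produces logits reshaped to
    [2, C']; a softmax over the split axis yields per-channel weights that
    sum to one, and the output is the weighted sum of the two branches.
    """

    def __init__(self, half_ch: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(half_ch // 4, 4)
        self.mlp1 = Linear(half_ch, hidden, rng)
        self.mlp2 = Linear(hidden, 2 * half_ch, rng)
        self.half_ch = half_ch

    def attention_weights(self, t1p: Tensor, t2p: Tensor) -> Tensor:
        """Return ᾱ [.., 2, C']: softmax over the split axis."""
        a = t1p.mean(axis=(-2, -1)) + t2p.mean(axis=(-2, -1))  # [.., C']
        logits = self.mlp2(self.mlp1(a).gelu())  # [.., 2C']
        logits = logits.reshape(*logits.shape[:-1], 2, self.half_ch)
        return softmax(logits, axis=-2)

    def forward(self, t1p: Tensor, t2p: Tensor) -> Tensor:
        if t1p.shape != t2p.shape:
            raise ValueError(f"split shapes differ: {t1p.shape} vs {t2p.shape}")
        ab = self.attention_weights(t1p, t2p)
        sl = [slice(None)] * ab.ndim
        sl[-2] = 0
        w1 = ab[tuple(sl)]
        sl[-2] = 1
        w2 = ab[tuple(sl)]
        w1 = w1.reshape(*w1.shape, 1, 1)
        w2 = w2.reshape(*w2.shape, 1, 1)
        return w1 * t1p + w2 * t2p


class DualShiftMLP(Module):
    """Full DS-MLP block: split → (spatial shift, channel shift) → split
    attention → linear channel re-expansion C/2 → C.  Shape preserving."""

    def __init__(self, n_ch: int, rng: np.random.Generator):
        super().__init__()
        if n_ch % 8:
            raise ValueError(f"DS-MLP needs channels divisible by 8, got {n_ch}")
        self.n_ch = n_ch
        self.channel_shift = ChannelShift(rng)
        self.split_attention = SplitAttention(n_ch // 2, rng)
        self.out_mlp = Linear(n_ch // 2, n_ch, rng)

    def forward(self, t: Tensor) -> Tensor:
        if t.ndim == 3:
            return self.forward(t.reshape(1, *t.shape)).reshape(
                self.n_ch, *t.shape[-2:]
            )
        t1, t2 = split_channels(t)
        fused = self.split_attention(spatial_shift(t1), self.channel_shift(t2))
        B, Ch, H, W = fused.shape
        tokens = fused.reshape(B, Ch, H * W).transpose(0, 2, 1)  # [B, N, C/2]
        out = self.out_mlp(tokens)  # [B, N, C]
        return out.transpose(0, 2, 1).reshape(B, self.n_ch, H, W)
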