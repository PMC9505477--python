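"""Channel-wise cross fusion transformer (CCT) skips and channel-wise
cross attention (CCA) decoder gates.

The four encoder scales are patch-embedded to token matrices sharing one
token count d, concatenated along channels, and refined by L transformer
layers whose attention runs along the *channel* axis: queries from one
scale attend over the channels of all scales at once, so each skip
connection can borrow information from every other resolution before the
decoder consumes it.  Per layer and scale, N independent heads are
averaged,

    MCA_i = (CA_i^1 + … + CA_i^N) / N,
    O_i   = MCA_i + MLP(LN(Q_i + MCA_i)),

with layer normalisation applied before attention and before the MLP, and
attention logits instance-normalised before the channel-axis softmax.

On the decoder side, CCA re-weights each (de-tokenised) skip with a
per-channel sigmoid gate computed from the globally average-pooled decoder
feature, then concatenates decoder and gated skip along channels.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .nn import LayerNorm, Linear, Module, global_avg_pool, softmax

__all__ = ["tokenize", "detokenize", "ChannelCrossTransformer", "ChannelCrossAttentionGate"]


def tokenize(x: Tensor, patch: int) -> Tensor:
    """Average-pool patch embedding: [B, C, H, W] → [B, d, C], d = (H/p)(W/p)."""
    B, C, H, W = x.shape
    if H % patch or W % patch:
        raise ValueError(f"spatial dims {H}x{W} not divisible by patch size {patch}")
    dh, dw = H // patch, W // patch
    t = x.reshape(B, C, dh, patch, dw, patch).mean(axis=5).mean(axis=3)
    return t.reshape(B, C, dh * dw).transpose(0, 2, 1)


def detokenize(tokens: Tensor, patch: int, H: int, W: int) -> Tensor:
    """Nearest up-broadcast of [B, d, C] tokens back to [B, C, H, W]."""
    B, d, C = tokens.shape
    dh, dw = H // patch, W // patch
    if dh * dw != d:
        raise ValueError(f"token count {d} inconsistent with {H}x{W}/patch {patch}")
    grid = tokens.transpose(0, 2, 1).reshape(B, C, dh, 1, dw, 1)
    ones = Tensor(np.ones((1, 1, 1, patch, 1, patch), dtype=tokens.dtype))
    return (grid * ones).reshape(B, C, H, W)


class _CctLayer(Module):
    """One CCT layer over the four scales (shared K/V, per-scale queries)."""

    def __init__(self, widths: list[int], n_heads: int, rng: np.random.Generator):
        super().__init__()
        total = sum(widths)
        self.widths = widths
        self.n_heads = n_heads
        self.ln_scales = [LayerNorm(c) for c in widths]
        self.ln_all = LayerNorm(total)
        # Eq-style multi-head: each head carries full-width projections and
        # the head outputs are averaged.
        self.w_q = [[Linear(c, c, rng) for c in widths] for _ in range(n_heads)]
        self.w_k = [Linear(total, total, rng) for _ in range(n_heads)]
        self.w_v = [Linear(total, total, rng) for _ in range(n_heads)]
        self.ln_out = [LayerNorm(c) for c in widths]
        self.mlp = [
            [Linear(c, 2 * c, rng), Linear(2 * c, c, rng)] for c in widths
        ]

    def _children(self):  # nested lists of modules
        yield from super()._children()
        for k in range(self.n_heads):
            for i, m in enumerate(self.w_q[k]):
                yield f"w_q.{k}.{i}", m
        for name, group in (("ln_scales", self.ln_scales), ("ln_out", self.ln_out)):
            for i, m in enumerate(group):
                yield f"{name}.{i}", m
        for k, m in enumerate(self.w_k):
            yield f"w_k.{k}", m
        for k, m in enumerate(self.w_v):
            yield f"w_v.{k}", m
        for i, pair in enumerate(self.mlp):
            yield f"mlp.{i}.0", pair[0]
            yield f"mlp.{i}.1", pair[1]

    @staticmethod
    def _psi(m: Tensor) -> Tensor:
        """Instance-normalise attention logits over their last two axes."""
        mu = m.mean(axis=(-2, -1), keepdims=True)
        mc = m - mu
        var = (mc * mc).mean(axis=(-2, -1), keepdims=True)
        return mc / (var + 1e-6).sqrt()

    def forward(self, tokens: list[Tensor], return_attn: bool = False):
        d = tokens[0].shape[1]
        normed = [ln(t) for ln, t in zip(self.ln_scales, tokens)]
        all_tok = self.ln_all(concat(tokens, axis=2))
        keys = [self.w_k[k](all_tok) for k in range(self.n_heads)]  # [B, d, ΣC]
        values = [self.w_v[k](all_tok) for k in range(self.n_heads)]
        attn_maps: list[Tensor] = []
        outs = []
        for i, t in enumerate(normed):
            heads = None
            q_i = None
            for k in range(self.n_heads):
                Q = self.w_q[k][i](t)  # [B, d, C_i]
                if k == 0:
                    q_i = Q
                sim = Q.transpose(0, 2, 1) @ keys[k] * (1.0 / np.sqrt(d))  # [B, C_i, ΣC]
                A = softmax(self._psi(sim), axis=-1)
                if return_attn:
                    attn_maps.append(A)
                ca = (A @ values[k].transpose(0, 2, 1)).transpose(0, 2, 1)  # [B, d, C_i]
                heads = ca if heads is None else heads + ca
            mca = heads * (1.0 / self.n_heads)
            # residual token stream around both attention and MLP, as in the
            # channel-transformer design this skip fusion follows
            res = tokens[i] + mca
            h = self.mlp[i][1](self.mlp[i][0](self.ln_out[i](res)).gelu())
            outs.append(res + h)
        if return_attn:
            return outs, attn_maps
        return outs


class ChannelCrossTransformer(Module):
    """L stacked CCT layers over the 4-scale token set; shape preserving."""

    def __init__(
        self,
        widths: list[int],
        n_heads: int,
        n_layers: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.layers = [_CctLayer(widths, n_heads, rng) for _ in range(n_layers)]
        self.widths = widths

    def forward(self, tokens: list[Tensor], return_attn: bool = False):
        attn: list[Tensor] = []
        for layer in self.layers:
            if return_attn:
                tokens, maps = layer(tokens, return_attn=True)
                attn.extend(maps)
            else:
                tokens = layer(tokens)
        if return_attn:
            return tokens, attn
        return tokens


class ChannelCrossAttentionGate(Module):
    """CCA: pooled decoder feature gates the skip, then channel concat.

    gate = sigmoid(W · GAP(decoder) + b) ∈ (0,1)^{C_skip}; the output is
    concat([decoder, gate ⊗ skip]) with C_dec + C_skip channels.
    """

    def __init__(self, dec_ch: int, skip_ch: int, rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(dec_ch, skip_ch, rng)

    def forward(self, decoder_feat: Tensor, skip_feat: Tensor) -> Tensor:
        if decoder_feat.shape[-2:] != skip_feat.shape[-2:]:
            raise ValueError(
                f"spatial mismatch: {decoder_feat.shape[-2:]} vs {skip_feat.shape[-2:]}"
            )
        gate = self.proj(global_avg_pool(decoder_feat)).sigmoid()  # [B, C_skip]
        gate = gate.reshape(*gate.shape, 1, 1)
        return concat([decoder_feat, gate * skip_feat], axis=1)
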