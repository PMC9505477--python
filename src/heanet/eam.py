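"""Efficient Attention Module (EAM).

The block gates a feature map with the elementwise product of two
parameter-light importance estimates:

* **Channel weights** — batch-norm scale factors γ already measure how much
  variance each channel is allowed to carry, so a normalised
  ``ω_γ,i = |γ_i| / Σ_j |γ_j|`` ranks channels for free.  The channel map is
  ``ω_C = sigmoid(ω_γ ⊗ BN(x))`` with ω_γ broadcast per channel.  The
  absolute value keeps the weights a convex combination even when γ turns
  negative during training.
* **Spatial weights** — each pixel (neuron) ``t`` of a channel is scored by
  the closed-form minimum of an energy measuring its linear separability
  from the channel's other pixels,

  ``e_t* = 4(σ̂² + λ) / ((t − μ̂)² + 2σ̂² + 2λ)``,

  with μ̂ and σ̂² the channel mean and biased variance over its M = H·W
  pixels and λ > 0 a regulariser (default 1e-4).  Importance is ``1/e_t*``:
  pixels far from the channel mean — typically edges and foreground — get
  large weights.  On a constant channel every pixel scores e* = 2, i.e. a
  flat weight of 0.5.

The gated output is ``E = sigmoid(ω_C ⊗ ω_S) ⊗ x``; since the gate lies in
(0, 1), the block can only attenuate, never amplify, the input.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .nn import BatchNorm2d, Module

__all__ = ["EfficientAttention", "spatial_energy_weights", "normalized_gamma_weights"]


def _batched(x: Tensor) -> tuple[Tensor, bool]:
    """Promote [C, H, W] to [1, C, H, W]; report whether we added the axis."""
    if x.ndim == 3:
        return x.reshape(1, *x.shape), True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"expected a [C,H,W] or [B,C,H,W] feature map, got ndim={x.ndim}")


def normalized_gamma_weights(gamma: np.ndarray) -> np.ndarray:
    """ω_γ,i = |γ_i| / Σ_j |γ_j|; raises if all scale factors vanish."""
    a = np.abs(np.asarray(gamma, dtype=np.float64))
    total = a.sum()
    if total == 0.0:
        raise ValueError("all batch-norm scale factors are zero; channel weights undefined")
    return a / total


def spatial_energy_weights(x: Tensor | np.ndarray, lambda_energy: float) -> Tensor:
    """Per-pixel importance 1/e_t* from the minimum-energy closed form.

    Statistics are per channel (and per batch element): μ̂ is the channel
    mean, σ̂² the biased (divide-by-M) variance over the channel's pixels.
    Returns a strictly positive tensor of the input's shape.
    """
    if lambda_energy <= 0:
        raise ValueError(f"lambda_energy must be > 0, got {lambda_energy}")
    if not isinstance(x, Tensor):
        x = Tensor(x)
    xb, squeezed = _batched(x)
    mu = xb.mean(axis=(2, 3), keepdims=True)
    centered = xb - mu
    var = (centered * centered).mean(axis=(2, 3), keepdims=True)
    # ω_S = 1/e* = ((t−μ̂)² + 2σ̂² + 2λ) / (4(σ̂² + λ))
    num = centered * centered + 2.0 * var + 2.0 * lambda_energy
    den = 4.0 * (var + lambda_energy)
    w = num / den
    return w.reshape(x.shape) if squeezed else w


class EfficientAttention(Module):
    """EAM block: channel×spatial importance gate, shape preserving.

    Parameters
    ----------
    n_ch
        Channel count of the incoming feature map.
    lambda_energy
        Regulariser λ of the energy score; must be positive.
    use_bn_weights
        When False (the "without BN" ablation), the channel map ω_C is
        replaced by uniform weights 1/C while the spatial branch and the
        final gating stay intact.
    """

    def __init__(self, n_ch: int, lambda_energy: float = 1e-4, use_bn_weights: bool = True):
        super().__init__()
        if lambda_energy <= 0:
            raise ValueError(f"lambda_energy must be > 0, got {lambda_energy}")
        self.n_ch = n_ch
        self.lambda_energy = lambda_energy
        self.use_bn_weights = use_bn_weights
        if use_bn_weights:
            self.bn = BatchNorm2d(n_ch)

    def channel_weight_map(self, x: Tensor) -> Tensor:
        """ω_C = sigmoid(ω_γ ⊗ BN(x)); entries strictly in (0, 1)."""
        xb, squeezed = _batched(x)
        if xb.shape[1] != self.n_ch:
            raise ValueError(f"expected {self.n_ch} channels, got {xb.shape[1]}")
        if not self.use_bn_weights:
            # ablated branch: uniform channel importance, no BN statistics
            out = Tensor(np.full(xb.shape, 1.0 / self.n_ch, dtype=xb.dtype))
        else:
            wg = self.gamma_weights().astype(xb.dtype)
            out = (Tensor(wg.reshape(1, -1, 1, 1)) * self.bn(xb)).sigmoid()
        return out.reshape(x.shape) if squeezed else out

    def gamma_weights(self) -> np.ndarray:
        return normalized_gamma_weights(self.bn.gamma.data)

    def forward(self, x: Tensor) -> Tensor:
        xb, squeezed = _batched(x)
        if xb.shape[1] != self.n_ch:
            raise ValueError(f"expected {self.n_ch} channels, got {xb.shape[1]}")
        wc = self.channel_weight_map(xb)
        ws = spatial_energy_weights(xb, self.lambda_energy)
        gate = (wc * ws).sigmoid()
        out = gate * xb
        return out.reshape(x.shape) if squeezed else out
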