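"""HEA-Net assembly: U-shaped encoder/decoder with EAM encoder attention,
DS-MLP bottleneck, CCT skip fusion and CCA decoder gates.

Topology (input resolution S, stage widths w·(1,2,4,8)):

* encoder stage i: double 3×3 conv (+BN+ReLU) → EAM (optional) → skip tap
  → 2×2 max-pool; skips live at S, S/2, S/4, S/8;
* bottleneck at S/16: double conv at width 8w → DS-MLP (optional);
* skips pass through the channel-wise cross fusion transformer with patch
  sizes (8, 4, 2, 1), so all four scales share d = (S/8)²/64·… tokens —
  concretely patch p_i halves with the scale so d is constant;
* decoder stage: bilinear ×2 upsample → CCA gate + concat with skip →
  double conv down to the skip's width;
* head: 1×1 conv to a single logit channel (binary segmentation).

With ``use_eam = use_ds_mlp = False`` the network reduces to the
UCTransNet-style baseline; the ablation switches only ever add parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .autodiff import Tensor, no_grad
from .cct_cca import (
    ChannelCrossAttentionGate,
    ChannelCrossTransformer,
    detokenize,
    tokenize,
)
from .config import NetConfig
from .ds_mlp import DualShiftMLP
from .eam import EfficientAttention
from .nn import BatchNorm2d, Conv2d, Module, ReLU, Sequential, max_pool2x2, upsample_bilinear2x

__all__ = ["HEANet", "build_hea_net", "save_checkpoint", "load_checkpoint"]

PATCH_SIZES = (8, 4, 2, 1)


def _double_conv(cin: int, cout: int, rng: np.random.Generator) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, 3, rng),
        BatchNorm2d(cout),
        ReLU(),
        Conv2d(cout, cout, 3, rng),
        BatchNorm2d(cout),
        ReLU(),
    )


class HEANet(Module):
    def __init__(self, cfg: NetConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = list(cfg.stage_widths)
        self.enc = [
            _double_conv(cin, cout, rng)
            for cin, cout in zip([cfg.in_channels] + widths[:-1], widths)
        ]
        if cfg.use_eam:
            self.eams = [
                EfficientAttention(c, cfg.lambda_energy, cfg.use_bn_in_eam)
                for c in widths
            ]
        self.bottleneck = _double_conv(widths[-1], widths[-1], rng)
        if cfg.use_ds_mlp:
            self.ds_mlp = DualShiftMLP(widths[-1], rng)
        self.cct = ChannelCrossTransformer(widths, cfg.n_heads, cfg.n_layers, rng)
        # decoder from deepest to shallowest skip
        self.cca = []
        self.dec = []
        dec_in = widths[-1]
        for c_skip in reversed(widths):
            self.cca.append(ChannelCrossAttentionGate(dec_in, c_skip, rng))
            self.dec.append(_double_conv(dec_in + c_skip, c_skip, rng))
            dec_in = c_skip
        self.head = Conv2d(widths[0], 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        want = self.head.weight.dtype
        if x.dtype != want and not x.requires_grad:
            x = Tensor(x.data.astype(want))
        if x.ndim == 3:
            return self.forward(x.reshape(1, *x.shape))[0]
        H, W = x.shape[-2:]
        if H % 16 or W % 16:
            raise ValueError(f"spatial dims must be divisible by 16, got {H}x{W}")
        skips = []
        # standardise [0,1] image input to roughly zero mean, unit variance
        h = (x - 0.5) * 4.0
        for i, stage in enumerate(self.enc):
            h = stage(h)
            if self.cfg.use_eam:
                h = self.eams[i](h)
            skips.append(h)
            h = max_pool2x2(h)
        h = self.bottleneck(h)
        if self.cfg.use_ds_mlp:
            h = self.ds_mlp(h)
        tokens = [tokenize(s, p) for s, p in zip(skips, PATCH_SIZES)]
        tokens = self.cct(tokens)
        fused = [
            detokenize(t, p, s.shape[-2], s.shape[-1])
            for t, p, s in zip(tokens, PATCH_SIZES, skips)
        ]
        for cca, dec, skip in zip(self.cca, self.dec, reversed(fused)):
            h = upsample_bilinear2x(h)
            h = cca(h, skip)
            h = dec(h)
        return self.head(h)

    def predict_proba(self, x) -> np.ndarray:
        """Inference-mode foreground probability map (sigmoid of logits)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits = self.forward(x if isinstance(x, Tensor) else Tensor(x))
                probs = logits.sigmoid().numpy()
        finally:
            self.train(was_training)
        return probs


def build_hea_net(cfg: NetConfig) -> HEANet:
    """Construct a seeded HEA-Net; identical cfg+seed gives identical weights."""
    return HEANet(cfg)


def save_checkpoint(model: HEANet, path: str | Path) -> None:
    """Single-file checkpoint: npz of all arrays with the config embedded."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> HEANet:
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    cfg = NetConfig.from_dict(json.loads(state.pop("__config__").tobytes().decode()))
    model = build_hea_net(cfg)
    model.load_state_dict(state)
    return model
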