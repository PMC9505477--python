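# heanet

A U-shaped encoder/decoder network for binary medical-image segmentation
(glands in colon histology, nuclei in multi-organ stains) whose encoder
couples convolution blocks to two light-weight enhancement modules, plus
everything needed to train and evaluate it offline: seeded synthetic data
generators, Dice/IoU metrics, a training loop and a CLI.

The package targets the regime where foreground and background tissue look
nearly alike and boundaries blur: plain convolutions under-segment, and
pure transformers lose the local detail that boundaries live in.

Everything — including reverse-mode automatic differentiation — is
implemented on numpy, so the package trains small networks on a single CPU
with no deep-learning framework installed.

## The model

HEA-Net is a four-stage U-Net variant with three additions:

* **EAM (Efficient Attention Module)**, after each encoder stage.  Channel
  importance comes for free from the batch-norm scale factors,
  `ω_γ,i = |γ_i| / Σ_j |γ_j|`, giving the channel map
  `ω_C = σ(ω_γ ⊗ BN(x))`.  Spatial importance is the closed-form minimum
  of a per-neuron energy measuring how separable a pixel is from the rest
  of its channel: with channel mean μ̂ and biased variance σ̂²,

  `e_t* = 4(σ̂² + λ) / ((t − μ̂)² + 2σ̂² + 2λ)`,   `ω_S = 1 / e_t*`,

  with λ = 1e-4.  The output gate is `E = σ(ω_C ⊗ ω_S) ⊗ x` — the block
  re-weights, never amplifies.
* **DS-MLP (Dual-channel Shift MLP)**, in the bottleneck.  Channels split
  in two: one half has its four channel quarters shifted one pixel in four
  directions (parameter-free spatial mixing); the other is re-weighted by
  `σ(conv1d_k3(GMP(·)))`, a global-max-pooled channel gate.  A split-
  attention MLP fuses the halves with per-channel softmax weights, and a
  linear projection restores the channel count.
* **CCT skips + CCA decoder gates.**  The four encoder scales are patch-
  embedded to equal-length token sets and refined by L = 4 transformer
  layers with N = 4 heads whose attention runs along the *channel* axis
  over all scales at once; the decoder re-weights each fused skip with a
  sigmoid gate driven by its own pooled features before concatenation.

Training follows the usual recipe for these benchmarks: Adam at 1e-3,
batch size 4, a combined BCE + soft-Dice loss, online flip/rotate
augmentation, evaluated by per-image Dice = 2TP/(2TP+FP+FN) and
IoU = TP/(TP+FP+FN).

## Worked example

```python
from heanet import NetConfig, SynthParams, generate_dataset, build_hea_net, train, evaluate

data = generate_dataset(SynthParams(style="gland", image_size=64, seed=0), 80)
cfg = NetConfig(base_width=16, input_size=64, seed=0, epochs=10, val_fraction=0.0)

untrained = build_hea_net(cfg)
print("untrained dice", round(evaluate(untrained, data[64:]).mean_dice, 4))

model, log = train(cfg, data[:64])
report = evaluate(model, data[64:])
print("trained dice", round(report.mean_dice, 4), "iou", round(report.mean_iou, 4))
```

prints (about two minutes on one CPU):

```
untrained dice 0.5581
trained dice 0.9789 iou 0.9588
```

The untrained network saturates to an almost uniform prediction, so its
Dice simply reflects the foreground fraction of the held-out masks; ten
epochs on 64 synthetic gland images lift held-out Dice to ≈0.98, close to
the ≈0.997 achievable given the generator's boundary blur.

The same pipeline is available from the shell:

```bash
heanet synth --style gland --n 80 --out data --seed 0 --size 64
heanet train --data data --out runs --epochs 10 --base-width 16
heanet eval  --ckpt runs/checkpoint.npz --data data
heanet ablate --data data           # the five ablation variants
```

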