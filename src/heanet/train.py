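"""Training loop, evaluation and the ablation runner.

The recipe mirrors the usual setup for small binary-segmentation
benchmarks: Adam (lr 1e-3), batch size 4, combined BCE + Dice loss,
online flip/rotate augmentation on the training split only, a fixed epoch
budget with constant learning rate, and best-checkpoint selection by
validation Dice.  Every source of randomness (split, shuffling,
augmentation, weight init) derives from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .config import NetConfig
from .metrics import MetricReport, combined_loss, evaluate_masks
from .network import HEANet, build_hea_net
from .optim import Adam
from .synthetic import SegSample, augment

__all__ = ["RunLog", "train", "evaluate", "train_val_split", "ablation_variants", "run_ablation"]

ABLATION_VARIANTS: dict[str, dict] = {
    "baseline": {"use_eam": False, "use_ds_mlp": False},
    "eam_no_bn": {"use_eam": True, "use_bn_in_eam": False, "use_ds_mlp": False},
    "eam": {"use_eam": True, "use_bn_in_eam": True, "use_ds_mlp": False},
    "ds_mlp": {"use_eam": False, "use_ds_mlp": True},
    "full": {"use_eam": True, "use_bn_in_eam": True, "use_ds_mlp": True},
}


@dataclass
class RunLog:
    """Per-epoch history plus the config snapshot that reproduces the run."""

    config: dict
    seed: int
    epochs: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.epochs.append(dict(kwargs))

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"config": self.config, "seed": self.seed}) + "\n")
            for row in self.epochs:
                fh.write(json.dumps(row) + "\n")

    @property
    def best_val_dice(self) -> float:
        return max((e["val_dice"] for e in self.epochs), default=float("nan"))


def train_val_split(
    samples: list[SegSample], val_fraction: float, seed: int
) -> tuple[list[SegSample], list[SegSample]]:
    """Seeded shuffle split; validation gets ceil(n·val_fraction) samples."""
    order = np.random.default_rng(seed).permutation(len(samples))
    n_val = int(np.ceil(len(samples) * val_fraction))
    val_idx = set(order[:n_val].tolist())
    train = [samples[i] for i in range(len(samples)) if i not in val_idx]
    val = [samples[i] for i in range(len(samples)) if i in val_idx]
    return train, val


def _batch_arrays(batch: list[SegSample]) -> tuple[np.ndarray, np.ndarray]:
    from .autodiff import default_dtype

    dt = default_dtype()
    imgs = np.stack([s.image for s in batch]).astype(dt)
    masks = np.stack([s.mask for s in batch]).astype(dt)[:, None]
    return imgs, masks


def evaluate(model: HEANet, samples: list[SegSample], threshold: float = 0.5) -> MetricReport:
    """Deterministic per-image Dice/IoU of the model on ``samples``."""
    if not samples:
        raise ValueError("empty evaluation set")
    probs = []
    for s in samples:
        probs.append(model.predict_proba(s.image[None])[0, 0])
    return evaluate_masks(probs, [s.mask for s in samples], [s.id for s in samples], threshold)


def train(
    cfg: NetConfig,
    samples: list[SegSample],
    log_path: str | Path | None = None,
    progress: bool = False,
) -> tuple[HEANet, RunLog]:
    """Train a seeded HEA-Net on ``samples``; returns the best-val model.

    Raises ``RuntimeError`` on a non-finite loss (with the offending epoch
    and step in the message) and ``ValueError`` on an empty dataset.
    """
    if not samples:
        raise ValueError("training requires a non-empty dataset")
    model = build_hea_net(cfg)
    opt = Adam(model.parameters(), lr=cfg.lr)
    tr, va = train_val_split(samples, cfg.val_fraction, cfg.seed)
    if not tr:
        raise ValueError("training split is empty; lower val_fraction")
    log = RunLog(config=cfg.to_dict(), seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    best_state, best_dice = None, -1.0
    iterator = range(cfg.epochs)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="epochs")
    for epoch in iterator:
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / cfg.epochs))
        model.train()
        order = rng.permutation(len(tr))
        losses = []
        for bstart in range(0, len(tr), cfg.batch_size):
            idx = order[bstart : bstart + cfg.batch_size]
            batch = [tr[i] for i in idx]
            if cfg.augment:
                batch = [
                    augment(s, seed=int(rng.integers(2**31))) for s in batch
                ]
            imgs, masks = _batch_arrays(batch)
            logits = model(Tensor(imgs))
            loss = combined_loss(logits, masks, cfg.w_ce, cfg.w_dice, cfg.dice_smooth)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {bstart // cfg.batch_size}: "
                    f"{loss.item()!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        if va:
            rep = evaluate(model, va, cfg.threshold)
            val_dice, val_iou = rep.mean_dice, rep.mean_iou
        else:
            val_dice = val_iou = float("nan")
        log.append(
            epoch=epoch,
            train_loss=float(np.mean(losses)),
            val_dice=val_dice,
            val_iou=val_iou,
        )
        if va and val_dice > best_dice:
            best_dice = val_dice
            best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    refresh_bn_stats(model, tr, cfg.batch_size)
    if log_path is not None:
        log.write(log_path)
    return model, log


def refresh_bn_stats(model: HEANet, samples: list[SegSample], batch_size: int = 4) -> None:
    """Recompute batch-norm running statistics over ``samples`` (precise BN).

    The exponential running estimates collected during training lag the
    final weights; replacing them with the exact average of the batch
    statistics under the trained weights makes inference-mode
    normalisation consistent with what the network saw at convergence.
    """
    from .autodiff import no_grad
    from .nn import BatchNorm2d, Module

    bns: list[BatchNorm2d] = []

    def collect(m: Module):
        if isinstance(m, BatchNorm2d):
            bns.append(m)
        for _, child in m._children():
            collect(child)

    collect(model)
    if not bns:
        return
    sums = [None] * len(bns)
    sq_sums = [None] * len(bns)
    n_batches = 0
    model.train()
    momenta = [bn.momentum for bn in bns]
    try:
        for bn in bns:
            bn.momentum = 1.0  # each forward leaves the pure batch statistics
        with no_grad():
            for start in range(0, len(samples), batch_size):
                imgs, _ = _batch_arrays(samples[start : start + batch_size])
                model(Tensor(imgs))
                for i, bn in enumerate(bns):
                    m, v = bn.running_mean.copy(), bn.running_var.copy()
                    sums[i] = m if sums[i] is None else sums[i] + m
                    sq_sums[i] = v if sq_sums[i] is None else sq_sums[i] + v
                n_batches += 1
    finally:
        for bn, mom in zip(bns, momenta):
            bn.momentum = mom
    for i, bn in enumerate(bns):
        bn.running_mean = sums[i] / n_batches
        bn.running_var = sq_sums[i] / n_batches
    model.eval()


def ablation_variants(cfg: NetConfig) -> dict[str, NetConfig]:
    """The five ablation configurations sharing every other hyperparameter."""
    out = {}
    for name, flags in ABLATION_VARIANTS.items():
        d = cfg.to_dict()
        d.update({"use_eam": True, "use_bn_in_eam": True, "use_ds_mlp": True})
        d.update(flags)
        out[name] = NetConfig.from_dict(d)
    return out


def run_ablation(
    cfg: NetConfig,
    samples: list[SegSample],
    variants: list[str] | None = None,
    progress: bool = False,
) -> dict[str, RunLog]:
    """Train every requested ablation variant on the same data and seed."""
    logs = {}
    for name, vcfg in ablation_variants(cfg).items():
        if variants is not None and name not in variants:
            continue
        _, log = train(vcfg, samples, progress=progress)
        logs[name] = log
    return logs
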