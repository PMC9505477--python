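"""Network/training configuration, loadable from YAML or JSON."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["NetConfig", "load_config", "save_config"]


@dataclass
class NetConfig:
    """Hyperparameters of the network and the training recipe.

    Stage widths are ``base_width · (1, 2, 4, 8)``; the bottleneck keeps
    the deepest width.  ``input_size`` must be divisible by 16 (four 2×2
    poolings) and ``base_width`` by at least 1 so the bottleneck width
    ``8·base_width`` is divisible by 8, as the DS-MLP split requires.
    """

    in_channels: int = 3
    base_width: int = 64
    input_size: int = 224
    n_heads: int = 4
    n_layers: int = 4
    lambda_energy: float = 1e-4
    seed: int = 0
    # ablation switches
    use_eam: bool = True
    use_bn_in_eam: bool = True
    use_ds_mlp: bool = True
    # training
    lr: float = 1e-3
    lr_schedule: str = "constant"  # or "cosine": decay to 0 over the epoch budget
    batch_size: int = 4
    epochs: int = 10
    w_ce: float = 0.5
    w_dice: float = 0.5
    dice_smooth: float = 1e-5
    threshold: float = 0.5
    augment: bool = True
    val_fraction: float = 0.2

    def __post_init__(self):
        if self.input_size % 16:
            raise ValueError(f"input_size must be divisible by 16, got {self.input_size}")
        if (8 * self.base_width) % 8:
            raise ValueError("bottleneck width must be divisible by 8")
        if self.lambda_energy <= 0:
            raise ValueError("lambda_energy must be positive")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")

    @property
    def stage_widths(self) -> tuple[int, int, int, int]:
        w = self.base_width
        return (w, 2 * w, 4 * w, 8 * w)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> NetConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return NetConfig.from_dict(data or {})


def save_config(cfg: NetConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
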