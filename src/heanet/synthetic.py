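"""Seeded synthetic histopathology-like image/mask generators.

Two styles emulate the regimes of the public gland and nucleus
segmentation benchmarks so the whole pipeline is exercisable offline:

* ``gland`` — a handful of large, deformed elliptical glands with bright
  interior lumens, Gaussian-blurred borders and a textured background
  whose mean intensity sits close to the foreground's (the
  hard-to-segment, blurred-boundary regime);
* ``nuclei`` — tens to a hundred small stained ellipses, a configurable
  fraction placed touching an existing nucleus, with stain-like colour
  jitter.

Masks are exact by construction (geometry is rasterised before any image
blurring) and strictly binary.  Identical :class:`SynthParams` (including
the seed) reproduce the dataset bit for bit.

The augmentation mirrors the usual online policy for these benchmarks:
independent 0.5-probability horizontal/vertical flips and a random
rotation, applied identically to image and mask, the mask re-binarised at
0.5 after interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["SegSample", "SynthParams", "generate_dataset", "augment", "save_dataset", "load_dataset"]


@dataclass
class SegSample:
    image: np.ndarray  # [3, H, W] float in [0, 1]
    mask: np.ndarray  # [H, W] uint8 binary
    id: str

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[0] != 3:
            raise ValueError(f"image must be [3, H, W], got {self.image.shape}")
        if self.mask.shape != self.image.shape[1:]:
            raise ValueError("image and mask are not spatially aligned")


@dataclass
class SynthParams:
    style: str = "gland"  # gland | nuclei
    image_size: int = 64
    n_objects: tuple[int, int] = (2, 6)  # gland default; nuclei uses (30, 120)
    object_scale: tuple[float, float] = (0.18, 0.32)  # radius as fraction of size
    boundary_blur_sigma: float = 1.5
    texture_amplitude: float = 0.08
    intensity_gap: float = 0.12  # |mean(fg) − mean(bg)| target, small = hard
    touching_fraction: float = 0.3  # nuclei style only
    fg_fraction_bounds: tuple[float, float] = (0.05, 0.65)
    seed: int = 0

    def __post_init__(self):
        if self.style not in ("gland", "nuclei"):
            raise ValueError(f"unknown style {self.style!r}")
        if self.image_size < 16:
            raise ValueError("image_size must be at least 16")
        if self.n_objects[0] < 1 or self.n_objects[1] < self.n_objects[0]:
            raise ValueError(f"bad n_objects range {self.n_objects}")


def nuclei_defaults(**overrides) -> SynthParams:
    """Convenience preset for the nuclei style."""
    base = dict(
        style="nuclei",
        n_objects=(30, 120),
        object_scale=(0.02, 0.05),
        boundary_blur_sigma=0.7,
        intensity_gap=0.25,
        fg_fraction_bounds=(0.01, 0.45),
    )
    base.update(overrides)
    return SynthParams(**base)


def _blob_mask(rng, size, cx, cy, rx, ry, angle, wobble=0.25, n_modes=4):
    """Rasterise a polar-perturbed ellipse; returns a boolean [size, size]."""
    yy, xx = np.mgrid[0:size, 0:size]
    x = xx - cx
    y = yy - cy
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * x + sa * y) / rx
    v = (-sa * x + ca * y) / ry
    r = np.sqrt(u * u + v * v)
    theta = np.arctan2(v, u)
    bound = np.ones_like(theta)
    for k in range(1, n_modes + 1):
        amp = wobble * rng.uniform(0, 1) / k
        phase = rng.uniform(0, 2 * np.pi)
        bound = bound + amp * np.cos(k * theta + phase)
    return r <= bound


def _texture(rng, size, amplitude, corr=6.0):
    noise = rng.normal(0, 1, (size, size))
    smooth = ndimage.gaussian_filter(noise, corr)
    smooth /= max(np.abs(smooth).max(), 1e-9)
    return amplitude * smooth


def _gland_sample(rng: np.random.Generator, p: SynthParams, idx: int) -> SegSample:
    S = p.image_size
    n = int(rng.integers(p.n_objects[0], p.n_objects[1] + 1))
    mask = np.zeros((S, S), dtype=bool)
    lumen = np.zeros((S, S), dtype=bool)
    for _ in range(n):
        r = rng.uniform(*p.object_scale) * S
        cx, cy = rng.uniform(0.15 * S, 0.85 * S, size=2)
        angle = rng.uniform(0, np.pi)
        blob = _blob_mask(rng, S, cx, cy, r, r * rng.uniform(0.6, 1.0), angle)
        mask |= blob
        if rng.uniform() < 0.85:  # interior lumen, still part of the gland mask
            lum = _blob_mask(
                rng, S, cx, cy, r * 0.45, r * 0.35, angle, wobble=0.15
            )
            lumen |= lum & blob
    # grayscale intensity field: background base + texture; glands darker by
    # a small configured gap; lumens bright
    bg = 0.62 + _texture(rng, S, p.texture_amplitude)
    intensity = bg.copy()
    intensity[mask] = 0.62 - p.intensity_gap + _texture(rng, S, p.texture_amplitude)[mask]
    intensity[lumen] = 0.88
    intensity = ndimage.gaussian_filter(intensity, p.boundary_blur_sigma)
    # H&E-ish colouring: pink background hue, purple foreground hue
    hue = ndimage.gaussian_filter(mask.astype(float), p.boundary_blur_sigma)
    r_ch = np.clip(intensity * (1.05 - 0.15 * hue), 0, 1)
    g_ch = np.clip(intensity * (0.75 - 0.10 * hue), 0, 1)
    b_ch = np.clip(intensity * (0.95 + 0.05 * hue), 0, 1)
    img = np.stack([r_ch, g_ch, b_ch])
    img += rng.normal(0, 0.01, img.shape)
    img = np.clip(img, 0, 1)
    return SegSample(image=img, mask=mask.astype(np.uint8), id=f"gland_{idx:04d}")


def _nuclei_sample(rng: np.random.Generator, p: SynthParams, idx: int) -> SegSample:
    S = p.image_size
    n = int(rng.integers(p.n_objects[0], p.n_objects[1] + 1))
    mask = np.zeros((S, S), dtype=bool)
    centers: list[tuple[float, float, float]] = []
    yy, xx = np.mgrid[0:S, 0:S]
    for k in range(n):
        r = rng.uniform(*p.object_scale) * S
        if centers and rng.uniform() < p.touching_fraction:
            cx0, cy0, r0 = centers[int(rng.integers(len(centers)))]
            ang = rng.uniform(0, 2 * np.pi)
            dist = (r0 + r) * rng.uniform(0.85, 1.0)  # adjacent/overlapping → touching
            cx, cy = cx0 + dist * np.cos(ang), cy0 + dist * np.sin(ang)
        else:
            # rejection-sample a location clear of existing nuclei so only
            # the configured fraction ends up touching
            for _ in range(30):
                cx, cy = rng.uniform(0, S, size=2)
                if all(
                    (cx - ox) ** 2 + (cy - oy) ** 2 > (1.15 * (r + orr)) ** 2
                    for ox, oy, orr in centers
                ):
                    break
        ca = rng.uniform(0, np.pi)
        rx, ry = r, r * rng.uniform(0.6, 1.0)
        u = (np.cos(ca) * (xx - cx) + np.sin(ca) * (yy - cy)) / rx
        v = (-np.sin(ca) * (xx - cx) + np.cos(ca) * (yy - cy)) / ry
        mask |= u * u + v * v <= 1.0
        centers.append((cx, cy, r))
    bg = 0.80 + _texture(rng, S, p.texture_amplitude)
    intensity = bg.copy()
    intensity[mask] = 0.80 - p.intensity_gap
    intensity = ndimage.gaussian_filter(intensity, p.boundary_blur_sigma)
    hue = ndimage.gaussian_filter(mask.astype(float), p.boundary_blur_sigma)
    jitter = rng.normal(0, 0.03, 3)  # stain-like per-image colour jitter
    r_ch = np.clip(intensity * (1.00 - 0.25 * hue) + jitter[0], 0, 1)
    g_ch = np.clip(intensity * (0.70 - 0.25 * hue) + jitter[1], 0, 1)
    b_ch = np.clip(intensity * (0.90 + 0.10 * hue) + jitter[2], 0, 1)
    img = np.stack([r_ch, g_ch, b_ch])
    img += rng.normal(0, 0.01, img.shape)
    img = np.clip(img, 0, 1)
    return SegSample(image=img, mask=mask.astype(np.uint8), id=f"nuclei_{idx:04d}")


def generate_dataset(p: SynthParams, n: int) -> list[SegSample]:
    """Generate ``n`` seeded samples; retries geometry whose foreground
    fraction leaves the configured bounds (up to 8 redraws per image)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(p.seed)
    make = _gland_sample if p.style == "gland" else _nuclei_sample
    lo, hi = p.fg_fraction_bounds
    out = []
    for i in range(n):
        for _ in range(8):
            s = make(rng, p, i)
            frac = s.mask.mean()
            if lo <= frac <= hi:
                break
        out.append(s)
    return out


def augment(s: SegSample, seed: int, max_angle: float = 30.0) -> SegSample:
    """Random flips (p=0.5 each) + uniform rotation in (−max_angle, max_angle).

    The identical geometric transform is applied to image and mask; both
    are rotated with reflect padding (so border labels match the reflected
    tissue) and the mask is re-binarised at 0.5.
    """
    rng = np.random.default_rng(seed)
    img = s.image.copy()
    mask = s.mask.astype(float)
    if rng.uniform() < 0.5:
        img = img[:, :, ::-1]
        mask = mask[:, ::-1]
    if rng.uniform() < 0.5:
        img = img[:, ::-1, :]
        mask = mask[::-1, :]
    angle = rng.uniform(-max_angle, max_angle)
    if abs(angle) > 1e-12:
        img = np.stack(
            [
                ndimage.rotate(c, angle, reshape=False, order=1, mode="reflect")
                for c in img
            ]
        )
        # same reflect geometry as the image so border labels stay
        # consistent with the reflected tissue
        mask = ndimage.rotate(mask, angle, reshape=False, order=1, mode="reflect")
    img = np.clip(np.ascontiguousarray(img), 0, 1)
    mask = (np.ascontiguousarray(mask) > 0.5).astype(np.uint8)
    return SegSample(image=img, mask=mask, id=s.id)


def save_dataset(samples: list[SegSample], out_dir: str | Path) -> None:
    """Write the images/ + masks/ folder layout (8-bit PNG, mask 0/255)."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    for s in samples:
        img8 = (s.image.transpose(1, 2, 0) * 255).round().astype(np.uint8)
        iio.imwrite(out_dir / "images" / f"{s.id}.png", img8)
        iio.imwrite(out_dir / "masks" / f"{s.id}.png", (s.mask * 255).astype(np.uint8))


def load_dataset(data_dir: str | Path) -> list[SegSample]:
    """Read paired images/*.png|tif|bmp and masks/* back into SegSamples."""
    import imageio.v3 as iio

    data_dir = Path(data_dir)
    img_dir, mask_dir = data_dir / "images", data_dir / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(f"{data_dir} lacks images/ and masks/ subfolders")
    samples = []
    for img_path in sorted(img_dir.iterdir()):
        if img_path.suffix.lower() not in (".png", ".tif", ".tiff", ".bmp"):
            continue
        matches = sorted(mask_dir.glob(img_path.stem + ".*"))
        if not matches:
            raise FileNotFoundError(f"no mask for image {img_path.name}")
        img = np.asarray(iio.imread(img_path), dtype=np.float64) / 255.0
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        mask = np.asarray(iio.imread(matches[0]))
        if mask.ndim == 3:
            mask = mask[..., 0]
        samples.append(
            SegSample(
                image=np.ascontiguousarray(img.transpose(2, 0, 1)),
                mask=(mask > 127).astype(np.uint8),
                id=img_path.stem,
            )
        )
    return samples
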