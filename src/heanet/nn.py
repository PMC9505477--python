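"""Neural-network building blocks on top of :mod:`heanet.autodiff`.

Conventions follow the usual NCHW layout: feature maps are ``[B, C, H, W]``
tensors (a missing batch axis is accepted by the higher-level blocks and
broadcast through). Modules own their parameters, expose them recursively
via :meth:`Module.parameters`, and carry a train/eval mode flag that
switches batch-norm between batch and running statistics.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, default_dtype

__all__ = [
    "Module",
    "Parameter",
    "Sequential",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "LayerNorm",
    "ReLU",
    "max_pool2x2",
    "upsample_bilinear2x",
    "global_avg_pool",
    "global_max_pool",
    "softmax",
]


class Parameter(Tensor):
    """A tensor registered as trainable state of a module."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters ignore inference mode at creation


class Module:
    """Base class: parameter registry, train/eval flag, state (de)serialisation."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # checkpointing: flat dict of arrays, suitable for np.savez
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            out["buf::" + name] = b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, arr in state.items():
            if name.startswith("buf::"):
                self._set_buffer(name[5:], np.asarray(arr))
            else:
                if params[name].shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = np.asarray(arr).copy()

    def _set_buffer(self, dotted: str, arr: np.ndarray) -> None:
        obj = self
        parts = dotted.split(".")
        for p in parts[:-1]:
            obj = obj[int(p)] if p.isdigit() else getattr(obj, p)
        setattr(obj, parts[-1], arr)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def __getitem__(self, i):
        return self.layers[i]

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(default_dtype())


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, in_features, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=default_dtype()))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """3×3 / 1×1 convolution, stride 1, zero same-padding, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, fan_in, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch, dtype=default_dtype()))
        self.kernel = kernel
        self.pad = kernel // 2

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.pad)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, pad: int) -> Tensor:
    """Stride-1 2-D convolution primitive with explicit backward pass."""
    B, C, H, W = x.shape
    O, _, kh, kw = weight.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))

    def im2col(arr):
        win = np.lib.stride_tricks.sliding_window_view(arr, (kh, kw), axis=(2, 3))
        oh, ow = win.shape[2], win.shape[3]
        return (
            np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
                B * oh * ow, C * kh * kw
            ),
            oh,
            ow,
        )

    cols, OH, OW = im2col(xp)
    wmat = weight.data.reshape(O, C * kh * kw)
    out = (cols @ wmat.T).reshape(B, OH, OW, O).transpose(0, 3, 1, 2)
    out = out + bias.data[None, :, None, None]
    del cols  # recomputed in backward; keeping it would dominate tape memory

    def backward(g):
        cols, _, _ = im2col(xp)
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * OH * OW, O)
        gw = (gmat.T @ cols).reshape(weight.shape)
        gb = g.sum(axis=(0, 2, 3))
        gcols = (gmat @ wmat).reshape(B, OH, OW, C, kh, kw).transpose(0, 3, 4, 5, 1, 2)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + OH, j : j + OW] += gcols[:, :, i, j]
        gx = gxp[:, :, pad : pad + H, pad : pad + W] if pad else gxp
        return ((x, gx), (weight, gw), (bias, gb))

    return Tensor._make(out, (x, weight, bias), backward)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with affine scale γ and shift β.

    Training mode normalises with batch statistics over (B, H, W) and
    updates exponential running estimates; eval mode uses the running
    statistics. γ is initialised to 1, β to 0.
    """

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        dt = default_dtype()
        self.gamma = Parameter(np.ones(n_ch, dtype=dt))
        self.beta = Parameter(np.zeros(n_ch, dtype=dt))
        self.running_mean = np.zeros(n_ch, dtype=dt)
        self.running_var = np.ones(n_ch, dtype=dt)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            # train mode always refreshes running stats, grad or no grad
            m = self.momentum
            rm = (1 - m) * self.running_mean + m * mu.data.ravel()
            rv = (1 - m) * self.running_var + m * var.data.ravel()
            self.running_mean = rm.astype(self.running_mean.dtype)
            self.running_var = rv.astype(self.running_var.dtype)
            xhat = xc / (var + self.eps).sqrt()
        else:
            dt = x.dtype
            mu = self.running_mean.astype(dt)[None, :, None, None]
            sd = np.sqrt(self.running_var.astype(dt) + self.eps)[None, :, None, None]
            xhat = (x - mu) * (1.0 / sd).astype(dt)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class LayerNorm(Module):
    """Normalisation over the last axis with affine parameters."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=default_dtype()))
        self.beta = Parameter(np.zeros(dim, dtype=default_dtype()))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


def max_pool2x2(x: Tensor) -> Tensor:
    """2×2, stride-2 max pooling (H and W must be even)."""
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2x2 needs even spatial dims, got {H}x{W}")
    return (
        x.reshape(B, C, H // 2, 2, W // 2, 2)
        .max(axis=5)
        .max(axis=3)
    )


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D linear-interpolation matrix (align_corners=False)."""
    M = np.zeros((n_out, n_in))
    for o in range(n_out):
        src = (o + 0.5) * n_in / n_out - 0.5
        i0 = int(np.floor(src))
        w1 = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        M[o, i0c] += 1.0 - w1
        M[o, i1c] += w1
    return M


_INTERP_CACHE: dict[tuple, np.ndarray] = {}


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear ×2 spatial upsampling as two cached 1-D linear maps."""
    B, C, H, W = x.shape
    dt = x.dtype
    key_h, key_w = (2 * H, H, dt), (2 * W, W, dt)
    for key in (key_h, key_w):
        if key not in _INTERP_CACHE:
            _INTERP_CACHE[key] = _interp_matrix(key[0], key[1]).astype(dt)
    My, Mx = _INTERP_CACHE[key_h], _INTERP_CACHE[key_w]
    out = np.einsum("oh,bchw,pw->bcop", My, x.data, Mx, optimize=True)

    def backward(g):
        gx = np.einsum("oh,bcop,pw->bchw", My, g, Mx, optimize=True)
        return ((x, gx),)

    return Tensor._make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """[B, C, H, W] → [B, C] spatial mean."""
    return x.mean(axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    """[B, C, H, W] → [B, C] spatial maximum (GMP)."""
    return x.max(axis=3).max(axis=2)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
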