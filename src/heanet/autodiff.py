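"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation network in this package is small enough to train on a CPU,
so instead of depending on a deep-learning framework the package carries its
own tape-based autodiff core: a :class:`Tensor` wraps an ``ndarray`` and
records the operations applied to it; :meth:`Tensor.backward` replays the
tape in reverse topological order accumulating vector-Jacobian products.

Only the primitives the network needs are implemented (elementwise
arithmetic, matmul, reductions, slicing, concatenation, the usual
activations, 2-D convolution, 2×2 max pooling and bilinear ×2 upsampling).
Gradients of every primitive are checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf, expit

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "no_grad",
    "is_grad_enabled",
    "default_dtype",
    "set_default_dtype",
]

_GRAD_ENABLED = [True]
_DEFAULT_DTYPE = [np.float32]


def default_dtype():
    """Dtype used for new parameters and scalar/list promotions.

    float32 keeps training fast and the tape small; switch to float64
    (``set_default_dtype(np.float64)``) when comparing against high-
    precision reference computations.
    """
    return _DEFAULT_DTYPE[-1]


class set_default_dtype:
    """Set the default dtype; usable as a call or a context manager."""

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype).type
        _DEFAULT_DTYPE.append(self.dtype)

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        _DEFAULT_DTYPE.pop()
        return False


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x
    return np.asarray(x, dtype=default_dtype())


class Tensor:
    """A numpy array with an optional gradient tape entry.

    Parameters
    ----------
    data
        Array-like payload; floats are kept at their incoming dtype
        (float64 by default).
    requires_grad
        Whether gradients should be accumulated into ``.grad`` for this
        tensor during :meth:`backward`.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad) and is_grad_enabled()
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction of derived nodes ------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if is_grad_enabled() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- basic introspection ----------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ----------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep tapes must not hit the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            elif node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        data = a.data + b.data

        def backward(g):
            return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape)))

        return Tensor._make(data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        data = a.data * b.data

        def backward(g):
            return (
                (a, _unbroadcast(g * b.data, a.shape)),
                (b, _unbroadcast(g * a.data, b.shape)),
            )

        return Tensor._make(data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        a = self

        def backward(g):
            return ((a, -g),)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        data = a.data / b.data

        def backward(g):
            return (
                (a, _unbroadcast(g / b.data, a.shape)),
                (b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape)),
            )

        return Tensor._make(data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        a = self
        data = a.data**p

        def backward(g):
            return ((a, g * p * a.data ** (p - 1)),)

        return Tensor._make(data, (a,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        data = a.data @ b.data

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))

        return Tensor._make(data, (a, b), backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def backward(g):
            return ((a, g.reshape(old)),)

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))

        def backward(g):
            return ((a, g.transpose(inv)),)

        return Tensor._make(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, idx):
        a = self
        data = a.data[idx]

        def backward(g):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return ((a, out),)

        return Tensor._make(data, (a,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return ((a, np.broadcast_to(g, a.shape).copy()),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return ((a, np.broadcast_to(g2, a.shape).copy()),)

        return Tensor._make(data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[i] for i in ax]))
        # divide (don't multiply by a rounded reciprocal): keeps the mean of
        # a constant array exact, which closed-form tests rely on
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis=None, keepdims: bool = False):
        a = self
        data = a.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            dk = a.data.max(axis=axis, keepdims=True)
            mask = (a.data == dk).astype(a.data.dtype)
            mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly
            if axis is None:
                g2 = g
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
            return ((a, mask * g2),)

        return Tensor._make(data, (a,), backward)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        a = self
        data = np.exp(a.data)

        def backward(g):
            return ((a, g * data),)

        return Tensor._make(data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            return ((a, g / a.data),)

        return Tensor._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        data = np.sqrt(a.data)

        def backward(g):
            return ((a, g * 0.5 / data),)

        return Tensor._make(data, (a,), backward)

    def abs(self):
        a = self

        def backward(g):
            return ((a, g * np.sign(a.data)),)

        return Tensor._make(np.abs(a.data), (a,), backward)

    def sigmoid(self):
        a = self
        data = expit(a.data)

        def backward(g):
            return ((a, g * data * (1.0 - data)),)

        return Tensor._make(data, (a,), backward)

    def relu(self):
        a = self
        data = np.maximum(a.data, 0.0)

        def backward(g):
            return ((a, g * (a.data > 0)),)

        return Tensor._make(data, (a,), backward)

    def gelu(self):
        """Exact Gaussian-error-linear unit x·Φ(x)."""
        a = self
        x = a.data
        phi = 0.5 * (1.0 + erf(x * 0.7071067811865476))
        data = x * phi

        def backward(g):
            pdf = np.exp(-0.5 * x * x) * 0.3989422804014327
            return ((a, g * (phi + x * pdf)),)

        return Tensor._make(data, (a,), backward)

    def tanh(self):
        a = self
        data = np.tanh(a.data)

        def backward(g):
            return ((a, g * (1.0 - data * data)),)

        return Tensor._make(data, (a,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return Tensor._make(data, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple((t, np.squeeze(p, axis=axis)) for t, p in zip(tensors, parts))

    return Tensor._make(data, tuple(tensors), backward)
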