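"""Gradient correctness of every autodiff primitive against central
finite differences, plus tape/bookkeeping behaviour."""

import numpy as np
import pytest

from heanet.autodiff import Tensor, concat, no_grad, set_default_dtype, stack
from heanet.nn import (
    BatchNorm2d,
    Conv2d,
    LayerNorm,
    Linear,
    conv2d,
    global_max_pool,
    max_pool2x2,
    softmax,
    upsample_bilinear2x,
)


def numerical_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f w.r.t. array x."""
    g = np.zeros_like(x)
    flat = x.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g


def check_op(op, shape, rng, tol=1e-6, positive=False):
    x = rng.standard_normal(shape)
    if positive:
        x = np.abs(x) + 0.5
    t = Tensor(x.copy(), requires_grad=True)
    # weight the output so the scalar loss probes every output element
    out = op(t)
    w = rng.standard_normal(out.shape)
    (out * Tensor(w)).sum().backward()
    num = numerical_grad(lambda a: float((op(Tensor(a)).data * w).sum()), x.copy())
    np.testing.assert_allclose(t.grad, num, rtol=tol, atol=tol)


@pytest.mark.usefixtures("f64")
@pytest.mark.parametrize(
    "name,op,positive",
    [
        ("exp", lambda t: t.exp(), False),
        ("log", lambda t: t.log(), True),
        ("sqrt", lambda t: t.sqrt(), True),
        ("abs", lambda t: t.abs(), True),
        ("sigmoid", lambda t: t.sigmoid(), False),
        ("gelu", lambda t: t.gelu(), False),
        ("tanh", lambda t: t.tanh(), False),
        ("relu_shifted", lambda t: (t + 0.3).relu(), True),
        ("square", lambda t: t**2.0, False),
        ("recip", lambda t: 1.0 / t, True),
        ("mean_axis", lambda t: t.mean(axis=1, keepdims=True), False),
        ("sum_all", lambda t: t.sum() * t, False),
        ("slice", lambda t: t[:, 1:3], False),
        ("transpose", lambda t: t.transpose(1, 0, 2), False),
        ("reshape", lambda t: t.reshape(4, -1), False),
        ("softmax", lambda t: softmax(t, axis=-1), False),
    ],
)
def test_elementwise_and_shape_gradients(name, op, positive, rng):
    check_op(op, (2, 4, 3), rng, positive=positive)


@pytest.mark.usefixtures("f64")
def test_broadcast_binary_gradients(rng):
    a = rng.standard_normal((3, 1, 4))
    b = rng.standard_normal((1, 5, 4))
    ta, tb = Tensor(a.copy(), requires_grad=True), Tensor(b.copy(), requires_grad=True)
    out = ta * tb + ta / (Tensor(np.abs(b) + 1.0)) - tb
    w = rng.standard_normal(out.shape)
    (out * Tensor(w)).sum().backward()

    def f_a(x):
        return float(((x * b + x / (np.abs(b) + 1.0) - b) * w).sum())

    np.testing.assert_allclose(ta.grad, numerical_grad(f_a, a.copy()), atol=1e-6)
    assert tb.grad.shape == b.shape


@pytest.mark.usefixtures("f64")
def test_matmul_batched_gradient(rng):
    a = rng.standard_normal((2, 3, 4))
    b = rng.standard_normal((4, 5))
    ta, tb = Tensor(a.copy(), requires_grad=True), Tensor(b.copy(), requires_grad=True)
    out = ta @ tb
    w = rng.standard_normal(out.shape)
    (out * Tensor(w)).sum().backward()
    np.testing.assert_allclose(
        ta.grad,
        numerical_grad(lambda x: float(((x @ b) * w).sum()), a.copy()),
        atol=1e-6,
    )
    np.testing.assert_allclose(
        tb.grad,
        numerical_grad(lambda x: float(((a @ x) * w).sum()), b.copy()),
        atol=1e-6,
    )


@pytest.mark.usefixtures("f64")
def test_max_and_concat_gradients(rng):
    x = rng.standard_normal((3, 4, 5))
    t = Tensor(x.copy(), requires_grad=True)
    out = concat([t.max(axis=2, keepdims=True), t[:, :, :1]], axis=2)
    w = rng.standard_normal(out.shape)
    (out * Tensor(w)).sum().backward()

    def f(a):
        o = np.concatenate([a.max(axis=2, keepdims=True), a[:, :, :1]], axis=2)
        return float((o * w).sum())

    np.testing.assert_allclose(t.grad, numerical_grad(f, x.copy()), atol=1e-6)


@pytest.mark.usefixtures("f64")
def test_stack_gradient(rng):
    a = rng.standard_normal((2, 3))
    b = rng.standard_normal((2, 3))
    ta, tb = Tensor(a.copy(), requires_grad=True), Tensor(b.copy(), requires_grad=True)
    out = stack([ta, tb], axis=1)
    out.sum().backward()
    np.testing.assert_array_equal(ta.grad, np.ones_like(a))
    np.testing.assert_array_equal(tb.grad, np.ones_like(b))


@pytest.mark.usefixtures("f64")
def test_conv2d_gradients(rng):
    x = rng.standard_normal((2, 3, 6, 5))
    w = rng.standard_normal((4, 3, 3, 3))
    b = rng.standard_normal(4)
    tx = Tensor(x.copy(), requires_grad=True)
    tw = Tensor(w.copy(), requires_grad=True)
    tb = Tensor(b.copy(), requires_grad=True)
    out = conv2d(tx, tw, tb, pad=1)
    wt = rng.standard_normal(out.shape)
    (out * Tensor(wt)).sum().backward()

    def ref(xx, ww, bb):
        o = conv2d(Tensor(xx), Tensor(ww), Tensor(bb), pad=1).data
        return float((o * wt).sum())

    np.testing.assert_allclose(
        tx.grad, numerical_grad(lambda a: ref(a, w, b), x.copy()), atol=1e-5
    )
    np.testing.assert_allclose(
        tw.grad, numerical_grad(lambda a: ref(x, a, b), w.copy()), atol=1e-5
    )
    np.testing.assert_allclose(
        tb.grad, numerical_grad(lambda a: ref(x, w, a), b.copy()), atol=1e-5
    )


@pytest.mark.usefixtures("f64")
def test_pool_and_upsample_gradients(rng):
    x = rng.standard_normal((2, 3, 4, 6))
    for op in (max_pool2x2, upsample_bilinear2x, global_max_pool):
        t = Tensor(x.copy(), requires_grad=True)
        out = op(t)
        w = rng.standard_normal(out.shape)
        (out * Tensor(w)).sum().backward()
        num = numerical_grad(
            lambda a: float((op(Tensor(a)).data * w).sum()), x.copy()
        )
        np.testing.assert_allclose(t.grad, num, atol=1e-6)


@pytest.mark.usefixtures("f64")
def test_norm_layer_gradients(rng):
    x = rng.standard_normal((4, 3, 5, 5))
    bn = BatchNorm2d(3)
    t = Tensor(x.copy(), requires_grad=True)
    out = bn(t)
    w = rng.standard_normal(out.shape)
    (out * Tensor(w)).sum().backward()
    rm, rv = bn.running_mean.copy(), bn.running_var.copy()

    def f(a):
        bn2 = BatchNorm2d(3)
        return float((bn2(Tensor(a)).data * w).sum())

    np.testing.assert_allclose(t.grad, numerical_grad(f, x.copy()), atol=1e-5)
    # running stats moved toward the batch statistics
    assert not np.allclose(rm, 0.0)

    ln = LayerNorm(6)
    y = rng.standard_normal((3, 6))
    t2 = Tensor(y.copy(), requires_grad=True)
    (ln(t2) * Tensor(w2 := rng.standard_normal((3, 6)))).sum().backward()
    np.testing.assert_allclose(
        t2.grad,
        numerical_grad(lambda a: float((LayerNorm(6)(Tensor(a)).data * w2).sum()), y.copy()),
        atol=1e-6,
    )


def test_no_grad_builds_no_tape(rng):
    t = Tensor(rng.standard_normal((3, 3)), requires_grad=True)
    with no_grad():
        out = (t * 2.0).sum()
    assert not out.requires_grad and out._prev == ()


def test_grad_accumulates_over_multiple_uses(rng):
    t = Tensor(np.array([2.0, 3.0]), requires_grad=True)
    (t * t + t).sum().backward()  # d/dt (t² + t) = 2t + 1
    np.testing.assert_allclose(t.grad, [5.0, 7.0])


def test_default_dtype_scoping():
    with set_default_dtype(np.float64):
        assert Tensor([1.0]).dtype == np.float64
    assert Tensor([1.0]).dtype == np.float32
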