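"""Minimal reverse-mode autodiff over numpy arrays.

Supports exactly the operator set the DenseNet-SK classifier needs:
grouped/dilated 2-D convolution, batch normalization, ReLU, max/average
pooling, global average pooling, channel concatenation, linear maps,
broadcast arithmetic and exp (for softmax gates), and a focal-loss head.
Gradients accumulate into ``Tensor.grad``; ``Tensor.backward()`` walks
the tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "relu",
    "exp",
    "concat",
    "reshape",
    "linear",
    "conv2d",
    "batch_norm",
    "max_pool2d",
    "avg_pool2d",
    "global_avg_pool",
    "focal_loss_logits",
    "softmax",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """A numpy array with a gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32 if np.asarray(data).dtype.kind == "f" else None)
        if self.data.dtype != np.float32:
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic (broadcasting) --------------------------
    def __add__(self, other):
        return _elementwise(self, other, lambda a, b: a + b,
                            lambda g, a, b: (g, g))

    __radd__ = __add__

    def __mul__(self, other):
        return _elementwise(self, other, lambda a, b: a * b,
                            lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __sub__(self, other):
        return _elementwise(self, other, lambda a, b: a - b,
                            lambda g, a, b: (g, -g))

    def __truediv__(self, other):
        return _elementwise(self, other, lambda a, b: a / b,
                            lambda g, a, b: (g / b, -g * a / (b * b)))

    def __neg__(self):
        return self * np.float32(-1.0)


def _as_const(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum grad down to a broadcast operand's original shape."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _elementwise(a, b, fwd, bwd):
    a_t = a if isinstance(a, Tensor) else None
    b_t = b if isinstance(b, Tensor) else None
    av, bv = _as_const(a), _as_const(b)
    out_data = fwd(av, bv)
    if not _GRAD_ENABLED:
        return Tensor(out_data)
    parents = tuple(t for t in (a_t, b_t) if t is not None and t.requires_grad_chain())
    if not parents:
        return Tensor(out_data)

    def backward(g):
        ga, gb = bwd(g, av, bv)
        if a_t is not None and a_t.requires_grad_chain():
            a_t._accumulate(_unbroadcast(ga, av.shape))
        if b_t is not None and b_t.requires_grad_chain():
            b_t._accumulate(_unbroadcast(gb, bv.shape))

    return Tensor(out_data, parents=parents, backward=backward)


def _chain(self: Tensor) -> bool:
    return self.requires_grad or bool(self._parents)


Tensor.requires_grad_chain = _chain


def _make(out_data, parents, backward):
    if not _GRAD_ENABLED:
        return Tensor(out_data)
    parents = tuple(p for p in parents if p.requires_grad_chain())
    if not parents:
        return Tensor(out_data)
    return Tensor(out_data, parents=parents, backward=backward)


# ----------------------------------------------------------------------
def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return _make(x.data * mask, (x,), lambda g: x._accumulate(g * mask))


def exp(x: Tensor) -> Tensor:
    out = np.exp(x.data)
    return _make(out, (x,), lambda g: x._accumulate(g * out))


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape
    return _make(x.data.reshape(shape), (x,), lambda g: x._accumulate(g.reshape(old)))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)  # snapshot: the caller may mutate its list afterwards
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, o, s in zip(tensors, offsets, sizes):
            if t.requires_grad_chain():
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(o, o + s)
                t._accumulate(g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (N, Cin) @ w.T with w (Cout, Cin), optional bias (Cout,)."""
    out = x.data @ w.data.T
    if b is not None:
        out = out + b.data

    def backward(g):
        if x.requires_grad_chain():
            x._accumulate(g @ w.data)
        if w.requires_grad_chain():
            w._accumulate(g.T @ x.data)
        if b is not None and b.requires_grad_chain():
            b._accumulate(g.sum(axis=0))

    parents = (x, w) + ((b,) if b is not None else ())
    return _make(out, parents, backward)


# ----------------------------------------------------------------------
# convolution / pooling
def _im2col(xp: np.ndarray, KH, KW, SH, SW, DH, DW, OH, OW) -> np.ndarray:
    N, C = xp.shape[:2]
    cols = np.empty((N, C, KH, KW, OH, OW), dtype=xp.dtype)
    for i in range(KH):
        for j in range(KW):
            cols[:, :, i, j] = xp[:, :, i * DH : i * DH + SH * OH : SH,
                                  j * DW : j * DW + SW * OW : SW]
    return cols


def _col2im(dcols: np.ndarray, xp_shape, KH, KW, SH, SW, DH, DW, OH, OW) -> np.ndarray:
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    for i in range(KH):
        for j in range(KW):
            dxp[:, :, i * DH : i * DH + SH * OH : SH,
                j * DW : j * DW + SW * OW : SW] += dcols[:, :, i, j]
    return dxp


def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0,
           dilation: int = 1, groups: int = 1) -> Tensor:
    """Grouped, dilated 2-D cross-correlation. w: (Cout, Cin//g, KH, KW)."""
    N, C, H, W = x.data.shape
    Co, Cg, KH, KW = w.data.shape
    g = groups
    assert C % g == 0 and Co % g == 0 and C // g == Cg
    s, p, d = stride, padding, dilation
    OH = (H + 2 * p - d * (KH - 1) - 1) // s + 1
    OW = (W + 2 * p - d * (KW - 1) - 1) // s + 1
    xp_shape = (N, C, H + 2 * p, W + 2 * p)

    def _cols():
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
        cols = _im2col(xp, KH, KW, s, s, d, d, OH, OW)
        return cols.reshape(N, g, Cg * KH * KW, OH * OW)

    colsg = _cols()
    wg = w.data.reshape(g, Co // g, Cg * KH * KW)
    out = np.matmul(wg[None], colsg).reshape(N, Co, OH, OW)
    # im2col buffers are KH*KW times the input size; retain small ones for
    # the weight gradient, recompute large ones to keep graph memory flat
    saved = colsg if colsg.nbytes <= 32 * 2**20 else None
    del colsg

    def backward(grad):
        dog = grad.reshape(N, g, Co // g, OH * OW)
        if w.requires_grad_chain():
            cg = saved if saved is not None else _cols()
            dwg = np.matmul(dog, cg.transpose(0, 1, 3, 2)).sum(axis=0)
            w._accumulate(dwg.reshape(Co, Cg, KH, KW))
        if x.requires_grad_chain():
            dcolsg = np.matmul(wg[None].transpose(0, 1, 3, 2), dog)
            dcols = dcolsg.reshape(N, C, KH, KW, OH, OW)
            dxp = _col2im(dcols, xp_shape, KH, KW, s, s, d, d, OH, OW)
            x._accumulate(dxp[:, :, p : p + H, p : p + W] if p else dxp)

    return _make(out, (x, w), backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    N, C, H, W = x.data.shape
    k, s, p = kernel, stride, padding
    OH = (H + 2 * p - k) // s + 1
    OW = (W + 2 * p - k) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x.data
    xp_shape = xp.shape
    cols = _im2col(xp, k, k, s, s, 1, 1, OH, OW).reshape(N, C, k * k, OH, OW)
    idx = cols.argmax(axis=2).astype(np.uint8)  # window positions fit a byte
    out = np.take_along_axis(cols, idx[:, :, None].astype(np.intp), axis=2)[:, :, 0]
    del cols, xp

    def backward(grad):
        if not x.requires_grad_chain():
            return
        dcols = np.zeros((N, C, k * k, OH, OW), dtype=grad.dtype)
        np.put_along_axis(dcols, idx[:, :, None].astype(np.intp), grad[:, :, None], axis=2)
        dxp = _col2im(dcols.reshape(N, C, k, k, OH, OW), xp_shape, k, k, s, s, 1, 1, OH, OW)
        x._accumulate(dxp[:, :, p : p + H, p : p + W] if p else dxp)

    return _make(out, (x,), backward)


def avg_pool2d(x: Tensor, kernel: int = 2, stride: int = 2) -> Tensor:
    N, C, H, W = x.data.shape
    k, s = kernel, stride
    OH = (H - k) // s + 1
    OW = (W - k) // s + 1
    cols = _im2col(x.data, k, k, s, s, 1, 1, OH, OW)
    out = cols.mean(axis=(2, 3))

    def backward(grad):
        if not x.requires_grad_chain():
            return
        dcols = np.broadcast_to(grad[:, :, None, None] / (k * k), (N, C, k, k, OH, OW))
        x._accumulate(_col2im(np.ascontiguousarray(dcols), x.data.shape, k, k, s, s, 1, 1, OH, OW))

    return _make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean (the channel statistic s)."""
    N, C, H, W = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def backward(grad):
        x._accumulate(np.broadcast_to(grad[:, :, None, None] / (H * W), x.data.shape).copy())

    return _make(out, (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """BN over all axes except channel axis 1; updates running stats in place."""
    axes = (0,) if x.ndim == 2 else (0, 2, 3)
    shape = (1, -1) if x.ndim == 2 else (1, -1, 1, 1)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.size / x.data.shape[1]
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(shape)) * invstd.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def backward(grad):
        if gamma.requires_grad_chain():
            gamma._accumulate((grad * xhat).sum(axis=axes))
        if beta.requires_grad_chain():
            beta._accumulate(grad.sum(axis=axes))
        if x.requires_grad_chain():
            gs = gamma.data.reshape(shape) * invstd.reshape(shape)
            if training:
                m = x.data.size / x.data.shape[1]
                gsum = grad.sum(axis=axes).reshape(shape)
                gx = (grad * xhat).sum(axis=axes).reshape(shape)
                x._accumulate(gs * (grad - gsum / m - xhat * gx / m))
            else:
                x._accumulate(gs * grad)

    return _make(out, (x, gamma, beta), backward)


# ----------------------------------------------------------------------
def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain numpy softmax along the last axis (inference utility)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def focal_loss_logits(logits: Tensor, labels: np.ndarray, gamma: float = 2.0,
                      alpha: float = 0.25) -> Tensor:
    """Mean focal loss -alpha (1 - p_t)^gamma log p_t from raw logits.

    gamma=0, alpha=1 reduces to cross-entropy. The analytic gradient
    w.r.t. the logits is supplied directly.
    """
    labels = np.asarray(labels, dtype=int)
    p = softmax(logits.data.astype(np.float64))
    n = len(labels)
    pt = np.clip(p[np.arange(n), labels], 1e-12, 1.0)
    loss = float(np.mean(-alpha * (1 - pt) ** gamma * np.log(pt)))

    def backward(grad):
        if not logits.requires_grad_chain():
            return
        # dL/dp_t, then chain through softmax
        g_pt = alpha * (gamma * (1 - pt) ** np.maximum(gamma - 1, 0) * np.log(pt)
                        - (1 - pt) ** gamma / pt)
        dlogits = p * (g_pt * pt)[:, None]
        dlogits[np.arange(n), labels] -= g_pt * pt
        dlogits *= -1.0 / n
        logits._accumulate((dlogits * float(grad)).astype(np.float32))

    return _make(np.float32(loss), (logits,), backward)
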