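"""Minimal reverse-mode autodiff on numpy arrays.

Only the operations the package's three vision models need are implemented:
broadcast add/mul, matmul, 2-D convolution, average pooling, nearest
upsampling, channel concatenation, ReLU/sigmoid, a per-channel spectral
gate (learnable frequency-domain attention) and fused classification /
segmentation losses.  Gradients are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "conv2d",
    "avg_pool2d",
    "upsample_nearest",
    "concat",
    "reshape",
    "global_avg_pool",
    "spectral_gate",
]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64)
        self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # convenience operators
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None for t in tensors)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _node(data, parents, backward) -> Tensor:
    if any(_needs(p) for p in parents):
        return Tensor(data, parents=tuple(parents), backward=backward)
    return Tensor(data)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        a.accumulate(g @ b.data.T)
        b.accumulate(a.data.T @ g)

    return _node(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        x.accumulate(g * mask)

    return _node(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(g):
        x.accumulate(g * s * (1.0 - s))

    return _node(s, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape
    out_data = x.data.reshape(shape)

    def backward(g):
        x.accumulate(g.reshape(old))

    return _node(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(start, stop)
            t.accumulate(g[tuple(idx)])

    return _node(out_data, tuple(tensors), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) mean over the spatial axes."""
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        x.accumulate(np.broadcast_to(g[:, :, None, None], x.data.shape) / (h * w))

    return _node(out_data, (x,), backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError("avg_pool2d requires spatial size divisible by the window")
    oh, ow = h // k, w // k
    out_data = x.data.reshape(n, c, oh, k, ow, k).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x.accumulate(gx)

    return _node(out_data, (x,), backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    out_data = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)
    n, c, h, w = x.data.shape

    def backward(g):
        x.accumulate(g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)))

    return _node(out_data, (x,), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation over an (N, C, H, W) batch.

    Implemented as a sum over kernel offsets of strided slices, which keeps
    memory flat (no im2col buffer) and routes every contraction through
    BLAS via einsum.
    """
    n, c, h, wd = x.data.shape
    o, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {ci}")
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (wd + 2 * pad - kw) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data

    out_data = np.zeros((n, o, oh, ow), dtype=np.result_type(x.data, w.data))
    for ki in range(kh):
        for kj in range(kw):
            xs = xp[:, :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride]
            out_data += np.einsum("ncij,oc->noij", xs, w.data[:, :, ki, kj], optimize=True)
    if b is not None:
        out_data += b.data[None, :, None, None]

    def backward(g):
        gxp = np.zeros_like(xp, dtype=np.float64)
        gw = np.zeros_like(w.data, dtype=np.float64)
        for ki in range(kh):
            for kj in range(kw):
                sl = np.s_[:, :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride]
                xs = xp[sl]
                gw[:, :, ki, kj] = np.einsum("noij,ncij->oc", g, xs, optimize=True)
                gxp[sl] += np.einsum("noij,oc->ncij", g, w.data[:, :, ki, kj], optimize=True)
        if pad:
            gxp = gxp[:, :, pad:-pad, pad:-pad]
        x.accumulate(gxp)
        w.accumulate(gw)
        if b is not None:
            b.accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def _mirror_spectrum(w: np.ndarray) -> np.ndarray:
    """Map w[.., ky, kx] -> w[.., (-ky) % H, (-kx) % W]."""
    return np.roll(w[..., ::-1, ::-1], shift=(1, 1), axis=(-2, -1))


def spectral_gate(x: Tensor, weight: Tensor) -> Tensor:
    """Learnable frequency-domain attention with a residual connection.

    Each channel's 2-D spectrum is multiplied by a real, even-symmetrised
    weight map, transformed back, and added to the input:

        y = Re(ifft2(S . fft2(x))) + x,   S = (w + mirror(w)) / 2

    The symmetrisation makes the spectral symbol conjugate-symmetric, so the
    output is exactly real; with all-ones weights the gate reduces to the
    identity (y = 2x with the residual, y - x = x).
    """
    if weight.data.shape != x.data.shape[1:]:
        raise ValueError(
            f"spectral weights {weight.data.shape} must match feature shape {x.data.shape[1:]}"
        )
    h, wd = x.data.shape[-2:]
    sym = 0.5 * (weight.data + _mirror_spectrum(weight.data))
    xf = np.fft.fft2(x.data)
    out_data = np.real(np.fft.ifft2(sym[None] * xf)) + x.data
    out_data = out_data.astype(x.data.dtype)

    def backward(g):
        gf = np.fft.fft2(g)
        # operator is self-adjoint: real even spectral symbol
        gx = np.real(np.fft.ifft2(sym[None] * gf)) + g
        x.accumulate(gx)
        d_sym = np.real(np.conj(gf) * xf).sum(axis=0) / (h * wd)
        weight.accumulate(0.5 * (d_sym + _mirror_spectrum(d_sym)))

    return _node(out_data, (x, weight), backward)
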