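"""Reverse-mode autodiff and 3D convolution primitives in numpy.

Supplies exactly what the one-two-one segmentation network needs: SAME-padded
3D convolution (stride 1 or 2), its transpose (stride-2 upsampling), ReLU,
sigmoid, residual addition, channel concatenation, dropout, and Adam.
Feature arrays are channels-first ``(N, C, D, H, W)`` float32.

Convolutions are evaluated as k^3 offset-shifted matrix products (one BLAS
contraction per kernel tap) rather than a materialised im2col buffer, which
keeps peak memory at a small multiple of the activation size even for
64x128x128 blocks.  Gradients are exact adjoints of the same contractions;
the test suite checks them against finite differences.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = [
    "Tensor",
    "Conv3d",
    "ConvTranspose3d",
    "relu",
    "sigmoid",
    "add",
    "concat",
    "dropout",
    "Adam",
]


class Tensor:
    """A node in the computation graph: value, gradient, and backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self, grad: np.ndarray) -> None:
        """Backpropagate ``grad`` (dLoss/dself) through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for big models
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# ---------------------------------------------------------------------------
# convolution primitives (pad = (k-1)//2, "SAME")
# ---------------------------------------------------------------------------


def _out_spatial(spatial, k, s):
    p = (k - 1) // 2
    return tuple((d + 2 * p - k) // s + 1 for d in spatial)


def _tap_slices(i, j, l, s, out_sp):
    return (
        slice(i, i + s * (out_sp[0] - 1) + 1, s),
        slice(j, j + s * (out_sp[1] - 1) + 1, s),
        slice(l, l + s * (out_sp[2] - 1) + 1, s),
    )


def conv3d_fwd(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    """x (N,Ci,D,H,W) * w (Co,Ci,k,k,k) -> (N,Co,D',H',W'), no bias."""
    k = w.shape[2]
    p = (k - 1) // 2
    out_sp = _out_spatial(x.shape[2:], k, stride)
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    y = np.zeros((x.shape[0], *out_sp, w.shape[0]), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                sl = _tap_slices(i, j, l, stride, out_sp)
                y += np.tensordot(xp[:, :, sl[0], sl[1], sl[2]], w[:, :, i, j, l], axes=([1], [1]))
    return np.ascontiguousarray(np.moveaxis(y, -1, 1))


def conv3d_gx(gy: np.ndarray, w: np.ndarray, x_spatial, stride: int) -> np.ndarray:
    """Gradient of conv3d_fwd w.r.t. its input (also the transposed-conv map)."""
    k = w.shape[2]
    p = (k - 1) // 2
    out_sp = gy.shape[2:]
    gxp = np.zeros(
        (gy.shape[0], w.shape[1], *(d + 2 * p for d in x_spatial)), dtype=np.float32
    )
    for i in range(k):
        for j in range(k):
            for l in range(k):
                t = np.tensordot(gy, w[:, :, i, j, l], axes=([1], [0]))  # (N,sp...,Ci)
                sl = _tap_slices(i, j, l, stride, out_sp)
                gxp[:, :, sl[0], sl[1], sl[2]] += np.moveaxis(t, -1, 1)
    return np.ascontiguousarray(gxp[:, :, p : p + x_spatial[0], p : p + x_spatial[1], p : p + x_spatial[2]])


def conv3d_gw(x: np.ndarray, gy: np.ndarray, stride: int, k: int) -> np.ndarray:
    """Gradient of conv3d_fwd w.r.t. the kernel."""
    p = (k - 1) // 2
    out_sp = gy.shape[2:]
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    gw = np.empty((gy.shape[1], x.shape[1], k, k, k), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                sl = _tap_slices(i, j, l, stride, out_sp)
                gw[:, :, i, j, l] = np.tensordot(
                    gy, xp[:, :, sl[0], sl[1], sl[2]], axes=([0, 2, 3, 4], [0, 2, 3, 4])
                )
    return gw


# ---------------------------------------------------------------------------
# graph ops
# ---------------------------------------------------------------------------


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    y = conv3d_fwd(x.data, w.data, stride) + b.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(y, parents=(x, w, b))

    def _bw(g):
        if x.requires_grad:
            x._accumulate(conv3d_gx(g, w.data, x.data.shape[2:], stride))
        if w.requires_grad:
            w._accumulate(conv3d_gw(x.data, g, stride, w.data.shape[2]))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    out._backward = _bw
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2) -> Tensor:
    """Transposed conv: exact adjoint of the stride-``stride`` SAME conv, so a
    d-voxel axis maps to stride*d.  Kernel is stored (C_in, C_out, k, k, k)."""
    out_spatial = tuple(stride * d for d in x.data.shape[2:])
    y = conv3d_gx(x.data, w.data, out_spatial, stride) + b.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(y, parents=(x, w, b))

    def _bw(g):
        if x.requires_grad:
            x._accumulate(conv3d_fwd(g, w.data, stride))
        if w.requires_grad:
            w._accumulate(conv3d_gw(g, x.data, stride, w.data.shape[2]))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), parents=(x,))
    out._backward = lambda g: x._accumulate(np.where(mask, g, 0.0))
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data.astype(np.float64), -60.0, 60.0)))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x._accumulate((g * (s * (1.0 - s))).astype(np.float32))
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    out._backward = _bw
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Channel-axis concatenation (the "stack" skip connection)."""
    ca = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), parents=(a, b))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g[:, :ca])
        if b.requires_grad:
            b._accumulate(g[:, ca:])

    out._backward = _bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate).astype(np.float32) / (1.0 - rate)
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out


# ---------------------------------------------------------------------------
# layers and optimiser
# ---------------------------------------------------------------------------


class Conv3d:
    """SAME conv layer; He-normal kernel init, zero bias."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, bias_init: float = 0.0):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for SAME padding")
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (in_ch * k**3))
        self.w = Tensor(rng.normal(0.0, std, (out_ch, in_ch, k, k, k)), requires_grad=True)
        self.b = Tensor(np.full(out_ch, bias_init, dtype=np.float32), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, self.stride)

    @property
    def parameters(self):
        return [self.w, self.b]


class ConvTranspose3d:
    """Stride-2 transposed conv doubling each spatial axis."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (in_ch * k**3))
        self.w = Tensor(rng.normal(0.0, std, (in_ch, out_ch, k, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.w, self.b, self.stride)

    @property
    def parameters(self):
        return [self.w, self.b]


class Adam:
    """Adam with bias correction; the reference learning rate is 0.001."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            mhat = m / (1.0 - self.b1**self.t)
            vhat = v / (1.0 - self.b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
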