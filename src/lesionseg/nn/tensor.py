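"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Feature maps use the NHWC layout (batch, height, width, channels) throughout.
All convolutions are stride-1 cross-correlations with "same" zero padding;
spatial downsampling happens only through 2x2 max pooling and upsampling only
through bilinear interpolation, so every backward pass has a closed form.
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
    "max_pool2",
    "resize_bilinear",
    "concat",
    "mean",
    "amax",
    "broadcast_hw",
    "dropout",
    "bce_mean",
    "masked_mean",
]


class Tensor:
    """An n-d array node in the computation graph.

    ``requires_grad`` marks trainable parameters; gradients are accumulated on
    every node reached by :meth:`backward`, which lets callers inspect
    intermediate gradients (needed for Grad-CAM).
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad=None):
        """Backpropagate from this node through the whole graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, grad):
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad = self.grad + grad


def _unbroadcast(grad, shape):
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def bw(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def bw(g):
        a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(g):
        a.accumulate(g @ b.data.T)
        b.accumulate(a.data.T @ g)

    out._backward = bw
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), parents=(x,))

    def bw(g):
        x.accumulate(g * mask)

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out = Tensor(s, parents=(x,))

    def bw(g):
        x.accumulate(g * s * (1.0 - s))

    out._backward = bw
    return out


def _im2col(xp, k, dilation, H, W):
    """Strided view (N, H, W, k, k, C) of the padded input ``xp``."""
    N = xp.shape[0]
    C = xp.shape[3]
    s = xp.strides
    shape = (N, H, W, k, k, C)
    strides = (s[0], s[1], s[2], s[1] * dilation, s[2] * dilation, s[3])
    return np.lib.stride_tricks.as_strided(xp, shape=shape, strides=strides)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Stride-1 "same" cross-correlation; ``w`` has shape (k, k, C_in, C_out)."""
    k = w.data.shape[0]
    if k % 2 == 0:
        raise ValueError("conv2d requires an odd kernel size")
    if x.data.shape[3] != w.data.shape[2]:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[3]} channels, "
            f"kernel expects {w.data.shape[2]}"
        )
    N, H, W, C = x.data.shape
    Cout = w.data.shape[3]
    pad = dilation * (k - 1) // 2
    span = dilation * (k - 1) + 1
    if span > H + 2 * pad or span > W + 2 * pad:
        raise ValueError(
            f"dilated kernel span {span} exceeds padded input {(H + 2 * pad, W + 2 * pad)}"
        )
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    cols = _im2col(xp, k, dilation, H, W).reshape(N * H * W, k * k * C)
    wm = w.data.reshape(k * k * C, Cout)
    y = cols @ wm
    if b is not None:
        y = y + b.data
    out = Tensor(y.reshape(N, H, W, Cout), parents=(x, w) if b is None else (x, w, b))

    def bw(g):
        gflat = g.reshape(N * H * W, Cout)
        w.accumulate((cols.T @ gflat).reshape(w.data.shape))
        if b is not None:
            b.accumulate(gflat.sum(axis=0))
        dcols = (gflat @ wm.T).reshape(N, H, W, k, k, C)
        gxp = np.zeros_like(xp)
        for u in range(k):
            for v in range(k):
                gxp[:, u * dilation:u * dilation + H, v * dilation:v * dilation + W, :] += \
                    dcols[:, :, :, u, v, :]
        x.accumulate(gxp[:, pad:pad + H, pad:pad + W, :])

    out._backward = bw
    return out


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (per-channel)."""
    N, H, W, C = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2 requires even spatial size, got {(H, W)}")
    Ho, Wo = H // 2, W // 2
    win = x.data.reshape(N, Ho, 2, Wo, 2, C).transpose(0, 1, 3, 5, 2, 4).reshape(N, Ho, Wo, C, 4)
    idx = win.argmax(axis=-1)
    y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, parents=(x,))

    def bw(g):
        gwin = np.zeros((N, Ho, Wo, C, 4))
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(N, Ho, Wo, C, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(N, H, W, C)
        x.accumulate(gx)

    out._backward = bw
    return out


def _lin_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Bilinear interpolation matrix (half-pixel-center convention)."""
    A = np.zeros((n_out, n_in))
    src = np.clip((np.arange(n_out) + 0.5) * n_in / n_out - 0.5, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = src - i0
    np.add.at(A, (np.arange(n_out), i0), 1 - t)
    np.add.at(A, (np.arange(n_out), i1), t)
    return A


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    N, H, W, C = x.data.shape
    Ah = _lin_matrix(H, out_h)
    Aw = _lin_matrix(W, out_w)
    y = np.einsum("ha,nawc->nhwc", Ah, x.data, optimize=True)
    y = np.einsum("wb,nhbc->nhwc", Aw, y, optimize=True)
    out = Tensor(y, parents=(x,))

    def bw(g):
        gx = np.einsum("ha,nhwc->nawc", Ah, g, optimize=True)
        gx = np.einsum("wb,nawc->nabc", Aw, gx, optimize=True)
        x.accumulate(gx)

    out._backward = bw
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t.accumulate(piece)

    out._backward = bw
    return out


def mean(x: Tensor, axis, keepdims: bool = False) -> Tensor:
    axes = (axis,) if isinstance(axis, int) else tuple(axis)
    out = Tensor(x.data.mean(axis=axes, keepdims=keepdims), parents=(x,))
    count = np.prod([x.data.shape[a] for a in axes])

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axis=axes)
        x.accumulate(np.broadcast_to(g / count, x.data.shape).copy())

    out._backward = bw
    return out


def amax(x: Tensor, axis, keepdims: bool = False) -> Tensor:
    axes = (axis,) if isinstance(axis, int) else tuple(axis)
    m = x.data.max(axis=axes, keepdims=True)
    mask = x.data == m
    nmax = mask.sum(axis=axes, keepdims=True)
    out = Tensor(m if keepdims else np.squeeze(m, axis=axes), parents=(x,))

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axis=axes)
        x.accumulate(mask * (g / nmax))  # ties share the subgradient equally

    out._backward = bw
    return out


def broadcast_hw(x: Tensor, H: int, W: int) -> Tensor:
    """Broadcast an (N, 1, 1, C) map to (N, H, W, C); backward sums spatially."""
    N, h, w, C = x.data.shape
    if (h, w) != (1, 1):
        raise ValueError("broadcast_hw expects spatial size (1, 1)")
    out = Tensor(np.broadcast_to(x.data, (N, H, W, C)).copy(), parents=(x,))

    def bw(g):
        x.accumulate(g.sum(axis=(1, 2), keepdims=True))

    out._backward = bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0:
        return x
    keep = rng.random(x.data.shape) >= rate
    scale = 1.0 / (1.0 - rate)
    out = Tensor(x.data * keep * scale, parents=(x,))

    def bw(g):
        x.accumulate(g * keep * scale)

    out._backward = bw
    return out


def bce_mean(prob: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy with probabilities clamped to [eps, 1-eps]."""
    y = np.asarray(target, dtype=np.float64)
    if y.shape != prob.data.shape:
        raise ValueError(f"shape mismatch: target {y.shape} vs prediction {prob.data.shape}")
    p = np.clip(prob.data, eps, 1.0 - eps)
    val = -(y * np.log(p) + (1.0 - y) * np.log1p(-p)).mean()
    out = Tensor(val, parents=(prob,))
    inside = (prob.data > eps) & (prob.data < 1.0 - eps)

    def bw(g):
        gp = (p - y) / (p * (1.0 - p)) / p.size
        prob.accumulate(g * gp * inside)

    out._backward = bw
    return out


def masked_mean(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean of ``x`` over True entries of a boolean mask (scalar output)."""
    m = np.asarray(mask, dtype=bool)
    n = m.sum()
    if n == 0:
        raise ValueError("masked_mean over an empty mask")
    out = Tensor((x.data * m).sum() / n, parents=(x,))

    def bw(g):
        x.accumulate(g * m / n)

    out._backward = bw
    return out
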