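"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine providing exactly the operations the
enhancer network needs: padded 2-D convolution, ceil-mode average pooling,
adaptive average pooling, global/channel-wise pooling reductions, batch
normalization, dense (linear) layers, ReLU/sigmoid, concatenation, dropout,
and softmax cross-entropy.  Gradients are validated against finite
differences in the test suite.

Tensors wrap ``numpy`` arrays; operations build a DAG of parents and a
closure that accumulates gradients into them.  ``no_grad`` disables graph
construction for inference.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def param(data) -> Tensor:
    """A trainable tensor (leaf with gradient accumulation)."""
    return Tensor(np.asarray(data), requires_grad=True)


def _make(data, parents, backward_fn) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes introduced or expanded by broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def backward(root: Tensor) -> None:
    """Backpropagate from a scalar (or any) tensor through the tape."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
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
    root.grad = np.ones_like(root.data)
    for node in reversed(topo):
        if node._backward is not None:
            node._backward(node.grad)
            # free the closure (and cached forward buffers) eagerly
            node._backward = None
            node._parents = ()


# ---------------------------------------------------------------------------
# elementwise / linear algebra


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out, (a, b), bw)


def scale(a: Tensor, c: float) -> Tensor:
    def bw(g):
        _accum(a, g * c)

    return _make(a.data * c, (a,), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        _accum(x, g * mask)

    return _make(x.data * mask, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        _accum(x, g * s * (1.0 - s))

    return _make(s, (x,), bw)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w (+ b)`` for 2-D ``x`` of shape (N, D) and ``w`` (D, O)."""
    out = x.data @ w.data
    if b is not None:
        out = out + b.data

    def bw(g):
        _accum(w, x.data.T @ g)
        if b is not None:
            _accum(b, g.sum(axis=0))
        _accum(x, g @ w.data.T)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(out, tuple(tensors), bw)


def reshape(x: Tensor, shape: tuple) -> Tensor:
    orig = x.data.shape

    def bw(g):
        _accum(x, g.reshape(orig))

    return _make(x.data.reshape(shape), (x,), bw)


def mean_axis(x: Tensor, axis, keepdims: bool = True) -> Tensor:
    axes = axis if isinstance(axis, tuple) else (axis,)
    count = int(np.prod([x.data.shape[a] for a in axes]))
    out = x.data.mean(axis=axis, keepdims=keepdims)

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axis=axes)
        _accum(x, np.broadcast_to(g / count, x.data.shape).copy())

    return _make(out, (x,), bw)


def max_axis(x: Tensor, axis: int, keepdims: bool = True) -> Tensor:
    """Maximum along one axis; gradient routes to the first argmax (ties)."""
    idx = x.data.argmax(axis=axis)
    out = np.take_along_axis(x.data, np.expand_dims(idx, axis), axis=axis)
    if not keepdims:
        out = np.squeeze(out, axis=axis)

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        dx = np.zeros_like(x.data)
        np.put_along_axis(dx, np.expand_dims(idx, axis), g, axis=axis)
        _accum(x, dx)

    return _make(out, (x,), bw)


def global_avgpool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) mean over spatial positions."""
    return mean_axis(x, axis=(2, 3), keepdims=False)


def global_maxpool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) max over spatial positions."""
    N, C, H, W = x.data.shape
    flat = x.data.reshape(N, C, H * W)
    idx = flat.argmax(axis=2)
    out = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]

    def bw(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[:, :, None], g[:, :, None], axis=2)
        _accum(x, dflat.reshape(N, C, H, W))

    return _make(out, (x,), bw)


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)

    def bw(g):
        _accum(x, g * keep)

    return _make(x.data * keep, (x,), bw)


# ---------------------------------------------------------------------------
# convolution and pooling


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 convolution; ``w`` has shape (O, C, kh, kw).

    Lowered to batched GEMM: columns are gathered per kernel offset into a
    (N, C*kh*kw, H*W) buffer (no copy at all for 1x1 kernels) and
    contracted against the flattened kernel.
    """
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O, C2, kh, kw = wd.shape
    if C != C2:
        raise ValueError(f"conv2d channel mismatch: input {C}, kernel {C2}")
    ph, pw = kh // 2, kw // 2
    HW = H * W
    wmat = wd.reshape(O, C * kh * kw)
    if kh == 1 and kw == 1:
        xp = xd
        colmat = xd.reshape(N, C, HW)
    else:
        xp = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=xd.dtype)
        xp[:, :, ph : ph + H, pw : pw + W] = xd
        cols = np.empty((N, C, kh, kw, H, W), dtype=xd.dtype)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = xp[:, :, i : i + H, j : j + W]
        colmat = cols.reshape(N, C * kh * kw, HW)
    out = np.matmul(wmat, colmat)  # (N, O, HW)
    if b is not None:
        out += b.data[:, None]
    outd = out.reshape(N, O, H, W)

    def bw(g):
        gmat = g.reshape(N, O, HW)
        dw = np.matmul(gmat, colmat.transpose(0, 2, 1)).sum(axis=0)
        _accum(w, dw.reshape(wd.shape))
        if b is not None:
            _accum(b, gmat.sum(axis=(0, 2)))
        if x.requires_grad:
            dcol = np.matmul(wmat.T, gmat)  # (N, C*kh*kw, HW)
            if kh == 1 and kw == 1:
                _accum(x, dcol.reshape(N, C, H, W))
            else:
                dcol6 = dcol.reshape(N, C, kh, kw, H, W)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i : i + H, j : j + W] += dcol6[:, :, i, j]
                _accum(x, np.ascontiguousarray(dxp[:, :, ph : ph + H, pw : pw + W]))

    parents = (x, w) if b is None else (x, w, b)
    return _make(outd, parents, bw)


def avgpool2x2_ceil(x: Tensor) -> Tensor:
    """2x2 stride-2 average pooling with ceiling division.

    Edge windows that fall partly outside the input average only the cells
    that exist, so a constant input pools to the same constant everywhere
    and odd dimensions shrink as ceil(n/2) (never to zero).
    """
    xd = x.data
    N, C, H, W = xd.shape
    Ho, Wo = -(-H // 2), -(-W // 2)
    pad_h, pad_w = 2 * Ho - H, 2 * Wo - W
    xp = np.pad(xd, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)))
    win = xp.reshape(N, C, Ho, 2, Wo, 2)
    sums = win.sum(axis=(3, 5))
    rows = np.full(Ho, 2.0, dtype=xd.dtype)
    cols = np.full(Wo, 2.0, dtype=xd.dtype)
    if pad_h:
        rows[-1] = 1.0
    if pad_w:
        cols[-1] = 1.0
    counts = rows[:, None] * cols[None, :]
    out = sums / counts

    def bw(g):
        gd = (g / counts)[:, :, :, None, :, None]
        dxp = np.broadcast_to(gd, (N, C, Ho, 2, Wo, 2)).reshape(
            N, C, 2 * Ho, 2 * Wo
        )
        _accum(x, dxp[:, :, :H, :W].copy())

    return _make(out, (x,), bw)


def adaptive_avgpool2d(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Average pooling onto a fixed (out_h, out_w) grid (PyTorch binning)."""
    xd = x.data
    N, C, H, W = xd.shape
    hb = [(i * H // out_h, -(-(i + 1) * H // out_h)) for i in range(out_h)]
    wb = [(j * W // out_w, -(-(j + 1) * W // out_w)) for j in range(out_w)]
    out = np.empty((N, C, out_h, out_w), dtype=xd.dtype)
    for i, (hs, he) in enumerate(hb):
        for j, (ws, we) in enumerate(wb):
            out[:, :, i, j] = xd[:, :, hs:he, ws:we].mean(axis=(2, 3))

    def bw(g):
        dx = np.zeros_like(xd)
        for i, (hs, he) in enumerate(hb):
            for j, (ws, we) in enumerate(wb):
                n = (he - hs) * (we - ws)
                dx[:, :, hs:he, ws:we] += g[:, :, i : i + 1, j : j + 1] / n
        _accum(x, dx)

    return _make(out, (x,), bw)


# ---------------------------------------------------------------------------
# batch normalization and losses


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    eps: float,
    momentum: float,
    train: bool,
) -> Tensor:
    """Per-channel standardization (x - mu)/sqrt(var + eps), then gamma/beta.

    In train mode batch statistics are used and the running statistics are
    updated in place; in eval mode the running statistics are used.
    """
    xd = x.data
    N, C, H, W = xd.shape
    gsh = (1, C, 1, 1)
    if train:
        if N < 2 and H * W < 2:
            raise ValueError("batch normalization needs >1 value per channel in train mode")
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu = running_mean.astype(xd.dtype)
        var = running_var.astype(xd.dtype)
    inv = (1.0 / np.sqrt(var + eps)).astype(xd.dtype)
    xhat = (xd - mu.reshape(gsh)) * inv.reshape(gsh)
    out = gamma.data.reshape(gsh) * xhat + beta.data.reshape(gsh)

    if train:

        def bw(g):
            m = N * H * W
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
            _accum(beta, g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxhat = g * gamma.data.reshape(gsh)
                t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (inv.reshape(gsh) / m) * (m * dxhat - t1 - xhat * t2)
                _accum(x, dx)

    else:

        def bw(g):
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
            _accum(beta, g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                _accum(x, g * (gamma.data * inv).reshape(gsh))

    return _make(out, (x, gamma, beta), bw)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain softmax on the last axis (inference helper, not differentiable)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns the scalar loss tensor and the probability matrix.
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    logp = z - np.log(e.sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), labels].mean()

    def bw(g):
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        _accum(logits, g * d / n)

    return _make(np.asarray(loss), (logits,), bw), probs
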