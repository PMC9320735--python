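"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine sufficient for convolutional segmentation networks:
grouped/dilated/strided convolution, batch normalization, bilinear resampling,
adaptive average pooling, elementwise activations, concatenation and the fused
softmax cross-entropy loss.  All arithmetic is float32; gradients accumulate
into ``Tensor.grad``.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "conv2d", "conv_transpose2d", "batch_norm", "relu", "relu6",
    "add", "concat", "dropout", "resize_bilinear", "adaptive_avg_pool",
    "softmax_cross_entropy", "softmax",
]


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _node(data, parents, backward, requires_grad=None):
    out = Tensor(data)
    if requires_grad is None:
        requires_grad = any(p.requires_grad for p in parents)
    out.requires_grad = requires_grad
    if requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution

def _im2col(xp, k, stride, dilation, Hp, Wp):
    """(N,C,Hpad,Wpad) -> (N, C, k, k, Hp, Wp) patch tensor (copies).

    For stride 2 the input is first split into its four polyphase grids so
    every patch copy is a contiguous slice rather than a strided gather.
    """
    N, C = xp.shape[:2]
    col = np.empty((N, C, k, k, Hp, Wp), dtype=xp.dtype)
    if stride == 2 and dilation == 1:
        phases = [[np.ascontiguousarray(xp[:, :, a::2, b::2])
                   for b in range(2)] for a in range(2)]
        for ki in range(k):
            for kj in range(k):
                ph = phases[ki % 2][kj % 2]
                col[:, :, ki, kj] = ph[:, :, ki // 2:ki // 2 + Hp,
                                       kj // 2:kj // 2 + Wp]
        return col
    for ki in range(k):
        for kj in range(k):
            i0, j0 = ki * dilation, kj * dilation
            col[:, :, ki, kj] = xp[:, :, i0:i0 + Hp * stride:stride,
                                   j0:j0 + Wp * stride:stride]
    return col


def _conv2d_1x1(x: Tensor, weight: Tensor, bias: Tensor | None,
                stride: int, groups: int) -> Tensor:
    """Pointwise convolution: a channel matmul, no patch extraction."""
    N, C, H, W = x.data.shape
    Cout = weight.data.shape[0]
    G = groups
    xs = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
    Hp, Wp = xs.shape[2:]
    xg = xs.reshape(N, G, C // G, Hp * Wp)
    wg = weight.data.reshape(G, Cout // G, C // G)
    y = np.matmul(wg[None], xg).reshape(N, Cout, Hp, Wp)
    if bias is not None:
        y += bias.data.reshape(1, Cout, 1, 1)
    parents = [x, weight] + ([bias] if bias is not None else [])

    def backward(dy):
        dyg = dy.reshape(N, G, Cout // G, Hp * Wp)
        if weight.requires_grad:
            dW = np.matmul(dyg, xg.transpose(0, 1, 3, 2)).sum(axis=0)
            weight._accumulate(dW.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(dy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxs = np.matmul(wg.transpose(0, 2, 1)[None], dyg)
            dxs = dxs.reshape(N, C, Hp, Wp)
            if stride > 1:
                dx = np.zeros_like(x.data)
                dx[:, :, ::stride, ::stride] = dxs
            else:
                dx = dxs
            x._accumulate(dx)

    return _node(y, parents, backward)


def _conv2d_depthwise(x: Tensor, weight: Tensor, bias: Tensor | None,
                      stride: int, dilation: int, padding: int) -> Tensor:
    """Depthwise convolution (groups == C): k^2 shifted fused multiply-adds."""
    N, C, H, W = x.data.shape
    k = weight.data.shape[2]
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp = (H + 2 * padding - dilation * (k - 1) - 1) // stride + 1
    Wp = (W + 2 * padding - dilation * (k - 1) - 1) // stride + 1
    views = {}
    y = np.zeros((N, C, Hp, Wp), dtype=xp.dtype)
    for ki in range(k):
        for kj in range(k):
            i0, j0 = ki * dilation, kj * dilation
            v = xp[:, :, i0:i0 + Hp * stride:stride, j0:j0 + Wp * stride:stride]
            views[ki, kj] = v
            y += weight.data[:, 0, ki, kj].reshape(1, C, 1, 1) * v
    if bias is not None:
        y += bias.data.reshape(1, C, 1, 1)
    parents = [x, weight] + ([bias] if bias is not None else [])

    def backward(dy):
        if weight.requires_grad:
            dW = np.empty_like(weight.data)
            for (ki, kj), v in views.items():
                dW[:, 0, ki, kj] = np.einsum("nchw,nchw->c", dy, v)
            weight._accumulate(dW)
        if bias is not None and bias.requires_grad:
            bias._accumulate(dy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for ki in range(k):
                for kj in range(k):
                    i0, j0 = ki * dilation, kj * dilation
                    dxp[:, :, i0:i0 + Hp * stride:stride,
                        j0:j0 + Wp * stride:stride] += \
                        weight.data[:, 0, ki, kj].reshape(1, C, 1, 1) * dy
            if padding:
                dxp = dxp[:, :, padding:padding + H, padding:padding + W]
            x._accumulate(dxp)

    return _node(y, parents, backward)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, dilation: int = 1, groups: int = 1,
           padding: int | None = None) -> Tensor:
    """2-D convolution; weight (C_out, C_in/groups, k, k), NCHW activations.

    ``padding=None`` selects the "same" padding ``dilation * (k // 2)`` so that
    stride 1 preserves spatial dims and stride 2 produces ``ceil(size / 2)``.
    Pointwise and depthwise cases take dedicated fast paths; the general
    grouped case goes through im2col + batched matmul.
    """
    N, C, H, W = x.data.shape
    Cout, Cg, k, _ = weight.data.shape
    if padding is None:
        padding = dilation * (k // 2)
    G = groups
    assert C % G == 0 and Cout % G == 0 and Cg == C // G
    if k == 1 and padding == 0:
        return _conv2d_1x1(x, weight, bias, stride, groups)
    if G == C and Cout == C:
        return _conv2d_depthwise(x, weight, bias, stride, dilation, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp = (H + 2 * padding - dilation * (k - 1) - 1) // stride + 1
    Wp = (W + 2 * padding - dilation * (k - 1) - 1) // stride + 1
    col = _im2col(xp, k, stride, dilation, Hp, Wp)
    colg = col.reshape(N, G, (C // G) * k * k, Hp * Wp)
    wg = weight.data.reshape(G, Cout // G, (C // G) * k * k)
    y = np.matmul(wg[None], colg)                       # (N,G,Cout/G,P)
    y = y.reshape(N, Cout, Hp, Wp)
    if bias is not None:
        y += bias.data.reshape(1, Cout, 1, 1)

    parents = [x, weight] + ([bias] if bias is not None else [])

    def backward(dy):
        dyg = dy.reshape(N, G, Cout // G, Hp * Wp)
        if weight.requires_grad:
            dW = np.matmul(dyg, colg.transpose(0, 1, 3, 2)).sum(axis=0)
            weight._accumulate(dW.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(dy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcol = np.matmul(wg.transpose(0, 2, 1)[None], dyg)   # (N,G,ik,P)
            dcol = dcol.reshape(N, C, k, k, Hp, Wp)
            dxp = np.zeros_like(xp)
            for ki in range(k):
                for kj in range(k):
                    i0, j0 = ki * dilation, kj * dilation
                    dxp[:, :, i0:i0 + Hp * stride:stride,
                        j0:j0 + Wp * stride:stride] += dcol[:, :, ki, kj]
            if padding:
                dxp = dxp[:, :, padding:padding + H, padding:padding + W]
            x._accumulate(dxp)

    return _node(y, parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
                     factor: int = 2) -> Tensor:
    """Transposed convolution with kernel == stride == factor (no overlap).

    weight shape (C_in, C_out, factor, factor).
    """
    N, C, H, W = x.data.shape
    Cin, Cout, f, _ = weight.data.shape
    assert Cin == C and f == factor
    y = np.einsum("nchw,cdab->ndhawb", x.data, weight.data, optimize=True)
    y = y.reshape(N, Cout, H * f, W * f)
    if bias is not None:
        y += bias.data.reshape(1, Cout, 1, 1)
    parents = [x, weight] + ([bias] if bias is not None else [])

    def backward(dy):
        dyr = dy.reshape(N, Cout, H, f, W, f)
        if weight.requires_grad:
            dW = np.einsum("nchw,ndhawb->cdab", x.data, dyr, optimize=True)
            weight._accumulate(dW)
        if bias is not None and bias.requires_grad:
            bias._accumulate(dy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dx = np.einsum("ndhawb,cdab->nchw", dyr, weight.data, optimize=True)
            x._accumulate(dx)

    return _node(y, parents, backward)


# ---------------------------------------------------------------------------
# normalization and activations

def batch_norm(x: Tensor, gamma: Tensor | None, beta: Tensor | None,
               running_mean: np.ndarray, running_var: np.ndarray, *,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain arrays mutated in place during
    training; they are state, not trainable parameters.
    """
    N, C, H, W = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, C, 1, 1)) * ivar.reshape(1, C, 1, 1)
    y = xhat
    if gamma is not None:
        y = y * gamma.data.reshape(1, C, 1, 1) + beta.data.reshape(1, C, 1, 1)
    parents = [x] + ([gamma, beta] if gamma is not None else [])
    M = N * H * W

    def backward(dy):
        if gamma is not None:
            if gamma.requires_grad:
                gamma._accumulate(np.einsum("nchw,nchw->c", dy, xhat))
            if beta.requires_grad:
                beta._accumulate(dy.sum(axis=(0, 2, 3)))
            dxhat = dy * gamma.data.reshape(1, C, 1, 1)
        else:
            dxhat = dy
        if x.requires_grad:
            iv = ivar.reshape(1, C, 1, 1)
            if training:
                s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = iv * (dxhat - s1 / M - xhat * s2 / M)
            else:
                dx = dxhat * iv
            x._accumulate(dx)

    return _node(y, parents, backward)


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0)

    def backward(dy):
        if x.requires_grad:
            x._accumulate(dy * (y > 0))

    return _node(y, [x], backward)


def relu6(x: Tensor) -> Tensor:
    mask = (x.data > 0) & (x.data < 6)
    y = np.clip(x.data, 0, 6)

    def backward(dy):
        if x.requires_grad:
            x._accumulate(dy * mask)

    return _node(y, [x], backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    y = a.data + b.data

    def backward(dy):
        if a.requires_grad:
            a._accumulate(dy)
        if b.requires_grad:
            b._accumulate(dy)

    return _node(y, [a, b], backward)


def concat(tensors, axis: int = 1) -> Tensor:
    y = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(dy):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * dy.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(dy[tuple(sl)])

    return _node(y, list(tensors), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0:
        return x
    keep = (rng.random(x.data.shape, dtype=np.float32) >= p) \
        .astype(np.float32) / (1.0 - p)
    y = x.data * keep

    def backward(dy):
        if x.requires_grad:
            x._accumulate(dy * keep)

    return _node(y, [x], backward)


# ---------------------------------------------------------------------------
# resampling (matrix-based separable interpolation)

_interp_cache: dict = {}


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) matrix for half-pixel-aligned linear interp."""
    key = ("lin", n_out, n_in)
    if key not in _interp_cache:
        M = np.zeros((n_out, n_in), dtype=np.float32)
        scale = n_in / n_out
        for i in range(n_out):
            src = (i + 0.5) * scale - 0.5
            src = min(max(src, 0.0), n_in - 1.0)
            lo = int(np.floor(src))
            hi = min(lo + 1, n_in - 1)
            w = src - lo
            M[i, lo] += 1.0 - w
            M[i, hi] += w
        _interp_cache[key] = M
    return _interp_cache[key]


def _avgpool_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Adaptive average pooling matrix: bin i covers [i*n/b, ceil((i+1)*n/b))."""
    key = ("avg", n_out, n_in)
    if key not in _interp_cache:
        M = np.zeros((n_out, n_in), dtype=np.float32)
        for i in range(n_out):
            lo = (i * n_in) // n_out
            hi = -(-((i + 1) * n_in) // n_out)  # ceil division
            M[i, lo:hi] = 1.0 / (hi - lo)
        _interp_cache[key] = M
    return _interp_cache[key]


def _separable_resample(x: Tensor, Mh: np.ndarray, Mw: np.ndarray) -> Tensor:
    y = np.einsum("oh,nchw,pw->ncop", Mh, x.data, Mw, optimize=True)

    def backward(dy):
        if x.requires_grad:
            dx = np.einsum("oh,ncop,pw->nchw", Mh, dy, Mw, optimize=True)
            x._accumulate(dx)

    return _node(y, [x], backward)


def resize_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize to (H_out, W_out), half-pixel centers (no corner align)."""
    H, W = x.data.shape[2:]
    Ho, Wo = size
    if (Ho, Wo) == (H, W):
        return x
    return _separable_resample(x, _bilinear_matrix(Ho, H), _bilinear_matrix(Wo, W))


def adaptive_avg_pool(x: Tensor, bins: tuple[int, int]) -> Tensor:
    H, W = x.data.shape[2:]
    return _separable_resample(x, _avgpool_matrix(bins[0], H), _avgpool_matrix(bins[1], W))


# ---------------------------------------------------------------------------
# loss / output decoding

def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Plain numpy softmax (inference path; no gradient)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, target: np.ndarray,
                          n_classes: int | None = None) -> Tensor:
    """Mean per-pixel negative log-likelihood; logits (N,C,H,W), target (N,H,W)."""
    N, C, H, W = logits.data.shape
    if target.min() < 0 or target.max() >= C:
        raise ValueError("target class index outside [0, %d)" % C)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    idx = (np.arange(N)[:, None, None], target,
           np.arange(H)[None, :, None], np.arange(W)[None, None, :])
    loss = -logp[idx].mean()
    M = N * H * W

    def backward(dy):
        if logits.requires_grad:
            p = np.exp(logp)
            p[idx] -= 1.0
            logits._accumulate(dy * p / M)

    return _node(np.float32(loss), [logits], backward)
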