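"""Reverse-mode automatic differentiation on NumPy arrays.

This is the compute core of the package: a small dynamic tape of
:class:`Tensor` nodes, each holding a float64 ndarray and a closure that
propagates the upstream gradient to its parents.  Only the operations the
segmentation network needs are implemented (3-D convolution with groups,
stride and dilation; separable linear resizing; channel/batch
normalisation; the usual pointwise nonlinearities; reductions), but each
one computes exact gradients, verified against central finite differences
in the test suite.

Gradient flow is opt-in: an operation records a backward closure only when
at least one input has ``requires_grad`` set, so inference runs tape-free.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "div",
    "narrow",
    "concat",
    "conv3d",
    "gelu",
    "relu",
    "sigmoid",
    "softmax",
    "log_softmax",
    "layer_norm_channels",
    "batch_norm",
    "channel_mean",
    "channel_max",
    "global_avg_pool",
    "linear",
    "interpolate",
]

_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def accumulate_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape),
                                 dtype=self.data.dtype)
        else:
            self.grad += g

    def accumulate_grad_owned(self, g: np.ndarray) -> None:
        """Accumulate a gradient buffer the caller guarantees is freshly
        allocated, exactly shaped and never reused — stored without copy."""
        if self.grad is None:
            self.grad = g
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node through the recorded tape."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without an explicit gradient "
                                   "requires a scalar tensor")
            grad = np.ones_like(self.data)
        # iterative topological order (post-order DFS)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.accumulate_grad(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, as_tensor(-1.0))

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def sum(self, axis=None, keepdims=False):
        return _reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else _axis_size(self.data.shape, axis)
        return _reduce_sum(self, axis, keepdims) * (1.0 / n)

    def reshape(self, *shape):
        return _reshape(self, shape)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _axis_size(shape, axis) -> int:
    if isinstance(axis, int):
        axis = (axis,)
    n = 1
    for a in axis:
        n *= shape[a]
    return n


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise arithmetic


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad_owned(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad_owned(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad_owned(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate_grad_owned(_unbroadcast(-g * a.data / (b.data * b.data),
                                                 b.data.shape))

    return _make(data, (a, b), backward)


def _reduce_sum(x: Tensor, axis, keepdims) -> Tensor:
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not x.requires_grad:
            return
        if axis is None:
            x.accumulate_grad_owned(np.broadcast_to(g, x.data.shape).copy())
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        x.accumulate_grad_owned(np.broadcast_to(gg, x.data.shape).copy())

    return _make(data, (x,), backward)


def _reshape(x: Tensor, shape) -> Tensor:
    data = x.data.reshape(shape)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g.reshape(x.data.shape))

    return _make(data, (x,), backward)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice ``[start, start+length)`` along one axis."""
    idx = [slice(None)] * x.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    data = x.data[idx]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[idx] = g
            x.accumulate_grad(gx)

    return _make(data, (x,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = list(tensors)
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate_grad(g[tuple(idx)])

    return _make(data, ts, backward)


# ---------------------------------------------------------------------------
# nonlinearities


def sigmoid(x: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad_owned(g * data * (1.0 - data))

    return _make(data, (x,), backward)


def relu(x: Tensor) -> Tensor:
    data = np.maximum(x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad_owned(g * (x.data > 0.0))

    return _make(data, (x,), backward)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    cdf = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    data = x.data * cdf

    def backward(g):
        if x.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data * x.data)
            x.accumulate_grad_owned(g * (cdf + x.data * pdf))

    return _make(data, (x,), backward)


def exp(x: Tensor) -> Tensor:
    data = np.exp(x.data)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad_owned(g * data)

    return _make(data, (x,), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * data).sum(axis=axis, keepdims=True)
            x.accumulate_grad_owned(data * (g - dot))

    return _make(data, (x,), backward)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    data = z - lse

    def backward(g):
        if x.requires_grad:
            s = np.exp(data)
            x.accumulate_grad_owned(g - s * g.sum(axis=axis, keepdims=True))

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------------
# reductions over the channel axis of (N, C, D, H, W) volumes


def channel_mean(x: Tensor) -> Tensor:
    """Per-voxel mean over channels, keeping a singleton channel axis."""
    C = x.data.shape[1]
    data = x.data.mean(axis=1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad_owned(np.broadcast_to(g / C, x.data.shape).copy())

    return _make(data, (x,), backward)


def channel_max(x: Tensor) -> Tensor:
    """Per-voxel max over channels; gradient routes to the first argmax."""
    idx = x.data.argmax(axis=1, keepdims=True)
    data = np.take_along_axis(x.data, idx, axis=1)

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.put_along_axis(gx, idx, g, axis=1)
            x.accumulate_grad_owned(gx)

    return _make(data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial axes of (N, C, D, H, W), returning (N, C)."""
    n = np.prod(x.data.shape[2:])
    data = x.data.mean(axis=(2, 3, 4))

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad_owned(
                np.broadcast_to(g[:, :, None, None, None] / n, x.data.shape).copy())

    return _make(data, (x,), backward)


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Affine map ``x @ weight.T + bias`` for 2-D ``x`` of shape (N, in)."""
    data = x.data @ weight.data.T
    if bias is not None:
        data = data + bias.data

    def backward(g):
        if x.requires_grad:
            x.accumulate_grad_owned(g @ weight.data)
        if weight.requires_grad:
            weight.accumulate_grad_owned(g.T @ x.data)
        if bias is not None and bias.requires_grad:
            bias.accumulate_grad(g.sum(axis=0))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(data, parents, backward)


# ---------------------------------------------------------------------------
# 3-D convolution


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError(f"expected a scalar or 3-tuple, got {v!r}")
        return tuple(int(x) for x in v)
    return (int(v),) * 3


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride=1, padding=0, dilation=1, groups: int = 1) -> Tensor:
    """Grouped 3-D cross-correlation over (N, C, D, H, W) volumes.

    ``weight`` has shape (C_out, C_in // groups, kd, kh, kw).  The kernel is
    applied as a loop over its taps, each tap a strided slice of the padded
    input contracted against one weight slice — no im2col buffer, so memory
    stays proportional to the input, and depthwise kernels (groups == C_in)
    reduce to broadcast multiplies.
    """
    xd = x.data
    wd = weight.data
    N, Cin, D, H, W = xd.shape
    Cout, Cing, kd, kh, kw = wd.shape
    if Cing * groups != Cin:
        raise ValueError(
            f"conv3d: weight expects {Cing * groups} input channels, got {Cin}")
    if Cout % groups:
        raise ValueError("conv3d: C_out must be divisible by groups")
    s = _triple(stride)
    p = _triple(padding)
    dl = _triple(dilation)
    out_sp = []
    for size, ss, pp, dd, kk in zip((D, H, W), s, p, dl, (kd, kh, kw)):
        o = (size + 2 * pp - dd * (kk - 1) - 1) // ss + 1
        if o < 1:
            raise ValueError(f"conv3d: spatial dim {size} too small for "
                             f"kernel {kk} (dilation {dd}, padding {pp})")
        out_sp.append(o)
    Do, Ho, Wo = out_sp

    xp = np.pad(xd, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
    og = Cout // groups
    depthwise = (Cing == 1 and og == 1)

    def tap_slice(a, b, c):
        return (Ellipsis,
                slice(a * dl[0], a * dl[0] + Do * s[0], s[0]),
                slice(b * dl[1], b * dl[1] + Ho * s[1], s[1]),
                slice(c * dl[2], c * dl[2] + Wo * s[2], s[2]))

    taps = [(a, b, c) for a in range(kd) for b in range(kh) for c in range(kw)]

    if depthwise:
        wview = wd.reshape(Cout, kd, kh, kw)
        xv = xp
        y = np.zeros((N, Cout, Do, Ho, Wo))
        for a, b, c in taps:
            y += xv[tap_slice(a, b, c)] * wview[:, a, b, c].reshape(1, Cout, 1, 1, 1)
    else:
        wview = wd.reshape(groups, og, Cing, kd, kh, kw)
        xv = xp.reshape(N, groups, Cing, *xp.shape[2:])
        y = np.zeros((N, groups, og, Do, Ho, Wo))
        for a, b, c in taps:
            y += np.einsum("ngixyz,goi->ngoxyz", xv[tap_slice(a, b, c)],
                           wview[..., a, b, c])
        y = y.reshape(N, Cout, Do, Ho, Wo)
    if bias is not None:
        y += bias.data.reshape(1, Cout, 1, 1, 1)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias.accumulate_grad(g.sum(axis=(0, 2, 3, 4)))
        need_x = x.requires_grad
        need_w = weight.requires_grad
        gg = g if depthwise else g.reshape(N, groups, og, Do, Ho, Wo)
        gxp = np.zeros_like(xv) if need_x else None
        gw = np.zeros_like(wview) if need_w else None
        for a, b, c in taps:
            sl = tap_slice(a, b, c)
            if need_w:
                xs = xv[sl]
                if depthwise:
                    gw[:, a, b, c] = (xs * gg).sum(axis=(0, 2, 3, 4))
                else:
                    gw[..., a, b, c] = np.einsum("ngixyz,ngoxyz->goi", xs, gg)
            if need_x:
                if depthwise:
                    gxp[sl] += gg * wview[:, a, b, c].reshape(1, Cout, 1, 1, 1)
                else:
                    gxp[sl] += np.einsum("ngoxyz,goi->ngixyz", gg,
                                         wview[..., a, b, c])
        if need_w:
            weight.accumulate_grad(gw.reshape(wd.shape))
        if need_x:
            gx = gxp.reshape(xp.shape)[:, :, p[0]:p[0] + D,
                                       p[1]:p[1] + H, p[2]:p[2] + W]
            x.accumulate_grad(np.ascontiguousarray(gx))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(y, parents, backward)


# ---------------------------------------------------------------------------
# normalisation


def layer_norm_channels(x: Tensor, gamma: Tensor, beta: Tensor,
                        eps: float = 1e-6) -> Tensor:
    """Layer normalisation over the channel axis at every voxel.

    The channels-last convention of ConvNeXt-style convolutional blocks:
    each spatial position is normalised independently across its C features,
    then scaled and shifted by per-channel affine parameters.
    """
    C = x.data.shape[1]
    mu = x.data.mean(axis=1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    gsh = gamma.data.reshape(1, C, 1, 1, 1)
    data = gsh * xhat + beta.data.reshape(1, C, 1, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate_grad((g * xhat).sum(axis=(0, 2, 3, 4)))
        if beta.requires_grad:
            beta.accumulate_grad(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gh = g * gsh
            m1 = gh.mean(axis=1, keepdims=True)
            m2 = (gh * xhat).mean(axis=1, keepdims=True)
            x.accumulate_grad_owned(inv * (gh - m1 - xhat * m2))

    return _make(data, (x, gamma, beta), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray, *,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, D, H, W) per channel, with running stats.

    ``running_mean``/``running_var`` are plain arrays updated in place during
    training (exponential moving average, unbiased variance) and used verbatim
    in evaluation mode.
    """
    C = x.data.shape[1]
    axes = (0, 2, 3, 4)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.size // C
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu = running_mean
        var = running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None, None]) * inv[None, :, None, None, None]
    gsh = gamma.data.reshape(1, C, 1, 1, 1)
    data = gsh * xhat + beta.data.reshape(1, C, 1, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate_grad((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta.accumulate_grad(g.sum(axis=axes))
        if x.requires_grad:
            gh = g * gsh
            if training:
                m1 = gh.mean(axis=axes, keepdims=True)
                m2 = (gh * xhat).mean(axis=axes, keepdims=True)
                gx = inv[None, :, None, None, None] * (gh - m1 - xhat * m2)
            else:
                gx = gh * inv[None, :, None, None, None]
            x.accumulate_grad_owned(gx)

    return _make(data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# separable linear resizing (trilinear interpolation, align_corners=False)


def _axis_resize_indices(in_len: int, out_len: int):
    dst = np.arange(out_len, dtype=np.float64)
    src = (dst + 0.5) * (in_len / out_len) - 0.5
    i0 = np.floor(src).astype(np.int64)
    frac = src - i0
    lo = np.clip(i0, 0, in_len - 1)
    hi = np.clip(i0 + 1, 0, in_len - 1)
    return lo, hi, frac


def _resize_axis(x: Tensor, axis: int, out_len: int) -> Tensor:
    in_len = x.data.shape[axis]
    if out_len == in_len:
        return x
    lo, hi, frac = _axis_resize_indices(in_len, out_len)
    shape = [1] * x.data.ndim
    shape[axis] = out_len
    w = frac.reshape(shape)
    data = (np.take(x.data, lo, axis=axis) * (1.0 - w)
            + np.take(x.data, hi, axis=axis) * w)
    out_len = int(out_len)

    def backward(g):
        if not x.requires_grad:
            return
        # scatter-add via bincount on the flattened (leading, index) plane
        gm = np.moveaxis(g, axis, -1)
        lead = gm.size // out_len
        g2 = gm.reshape(lead, out_len)
        base = np.arange(lead)[:, None] * in_len
        total = np.bincount((base + lo).ravel(),
                            weights=(g2 * (1.0 - frac)).ravel(),
                            minlength=lead * in_len)
        total += np.bincount((base + hi).ravel(),
                             weights=(g2 * frac).ravel(),
                             minlength=lead * in_len)
        shape = list(gm.shape)
        shape[-1] = in_len
        gx = np.moveaxis(total.reshape(shape), -1, axis)
        x.accumulate_grad(np.ascontiguousarray(gx))

    return _make(data, (x,), backward)


def interpolate(x: Tensor, size: tuple[int, int, int]) -> Tensor:
    """Trilinear resize of (N, C, D, H, W) to the given spatial ``size``.

    Half-pixel-centre coordinate mapping (the align_corners=False
    convention); the three axes are resized separably, which is exact for
    trilinear interpolation under this mapping.
    """
    out = x
    for axis, target in zip((2, 3, 4), size):
        out = _resize_axis(out, axis, int(target))
    return out
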