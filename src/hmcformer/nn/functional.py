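"""Neural-network operations on :class:`~hmcformer.nn.tensor.Tensor`.

Convolution is implemented by im2col (slice-gathered patches reshaped into a
matrix product) so both the forward and backward passes run as BLAS calls.
Softmax, layer norm and cross entropy are fused primitives with analytic
backward rules rather than compositions, which keeps the graphs small.

A lightweight multiply-accumulate profiler can be enabled with
:class:`MacCounter`; conv/linear/batched-matmul primitives report their MAC
counts to it, matching the convention of standard model profilers.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

from .tensor import Tensor, as_tensor

_PROFILER = None


class MacCounter:
    """Context manager accumulating multiply-accumulate counts by category."""

    def __init__(self):
        self.total = 0
        self.by_category: dict[str, int] = {}

    def add(self, category: str, macs: int):
        self.total += int(macs)
        self.by_category[category] = self.by_category.get(category, 0) + int(macs)

    def __enter__(self):
        global _PROFILER
        self._prev = _PROFILER
        _PROFILER = self
        return self

    def __exit__(self, *exc):
        global _PROFILER
        _PROFILER = self._prev
        return False


def _record(category: str, macs: int):
    if _PROFILER is not None:
        _PROFILER.add(category, macs)


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    xd = x.data
    phi = 0.5 * (1.0 + erf(xd / _SQRT2))
    out_data = (xd * phi).astype(np.float32)

    def bw(g):
        d = phi + xd * _INV_SQRT2PI * np.exp(-0.5 * xd * xd)
        x._accum(g * d.astype(np.float32))

    return Tensor._make(out_data, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x._accum(g * (s * (1.0 - s)).astype(np.float32))

    return Tensor._make(s.astype(np.float32), (x,), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    y = (e / e.sum(axis=axis, keepdims=True)).astype(np.float32)

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))

    return Tensor._make(y, (x,), bw)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer norm over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xc * inv).astype(np.float32)
    out_data = xhat * weight.data + bias.data

    def bw(g):
        n = x.data.shape[-1]
        if weight.requires_grad:
            red = tuple(range(g.ndim - 1))
            weight._accum((g * xhat).sum(axis=red))
            bias._accum(g.sum(axis=red))
        if x.requires_grad:
            gx = g * weight.data
            gsum = gx.sum(axis=-1, keepdims=True)
            gdot = (gx * xhat).sum(axis=-1, keepdims=True)
            x._accum((inv * (gx - gsum / n - xhat * gdot / n)).astype(np.float32))

    return Tensor._make(out_data.astype(np.float32), (x, weight, bias), bw)


# ---------------------------------------------------------------------------
# linear / matmul / conv
# ---------------------------------------------------------------------------


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """``x @ weight.T + bias`` with ``weight`` of shape (out, in)."""
    _record("linear", x.data.size // x.data.shape[-1] * weight.data.size)
    out = x @ weight.transpose(1, 0)
    if bias is not None:
        out = out + bias
    return out


def bmm(a: Tensor, b: Tensor) -> Tensor:
    """Batched matmul, counted by the MAC profiler (attention score/value)."""
    batch = int(np.prod(a.data.shape[:-2])) if a.data.ndim > 2 else 1
    _record("matmul", batch * a.data.shape[-2] * a.data.shape[-1] * b.data.shape[-1])
    return a @ b


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int,
            dh: int, dw: int, Ho: int, Wo: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C, kh, kw, Ho, Wo) patch tensor (copies)."""
    N, C = xp.shape[:2]
    cols = np.empty((N, C, kh, kw, Ho, Wo), dtype=xp.dtype)
    for a in range(kh):
        ia = a * dh
        for b in range(kw):
            jb = b * dw
            cols[:, :, a, b] = xp[:, :, ia:ia + Ho * sh:sh, jb:jb + Wo * sw:sw]
    return cols


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution, NCHW layout, weight (Co, Ci, kh, kw)."""
    N, C, H, W = x.data.shape
    Co, Ci, kh, kw = weight.data.shape
    assert Ci == C, f"channel mismatch: input {C}, weight {Ci}"
    sh = sw = stride
    dh = dw = dilation
    ekh, ekw = (kh - 1) * dh + 1, (kw - 1) * dw + 1
    ph = pw = padding
    Ho = (H + 2 * ph - ekh) // sh + 1
    Wo = (W + 2 * pw - ekw) // sw + 1
    if ph or pw:
        xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    else:
        xp = x.data
    cols = _im2col(xp, kh, kw, sh, sw, dh, dw, Ho, Wo)
    K = C * kh * kw
    cols2 = cols.reshape(N, K, Ho * Wo)
    W2 = weight.data.reshape(Co, K)
    out = np.matmul(W2, cols2)  # (N, Co, Ho*Wo)
    _record("conv", N * Co * K * Ho * Wo)
    out = out.reshape(N, Co, Ho, Wo)
    if bias is not None:
        out = out + bias.data.reshape(1, Co, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        g2 = g.reshape(N, Co, Ho * Wo)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gW = np.einsum("nop,nkp->ok", g2, cols2, optimize=True)
            weight._accum(gW.reshape(Co, C, kh, kw))
        if x.requires_grad:
            gcols = np.matmul(W2.T[None], g2)  # (N, K, Ho*Wo)
            gcols = gcols.reshape(N, C, kh, kw, Ho, Wo)
            gxp = np.zeros_like(xp)
            for a in range(kh):
                ia = a * dh
                for b in range(kw):
                    jb = b * dw
                    gxp[:, :, ia:ia + Ho * sh:sh, jb:jb + Wo * sw:sw] += gcols[:, :, a, b]
            if ph or pw:
                gxp = gxp[:, :, ph:ph + H, pw:pw + W]
            x._accum(gxp)

    return Tensor._make(out.astype(np.float32), parents, bw)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), bw)


def split(x: Tensor, parts: int, axis: int = -1) -> list[Tensor]:
    size = x.data.shape[axis]
    assert size % parts == 0
    step = size // parts
    outs = []
    for i in range(parts):
        idx = [slice(None)] * x.data.ndim
        idx[axis] = slice(i * step, (i + 1) * step)
        idx = tuple(idx)

        def bw(g, idx=idx):
            full = np.zeros_like(x.data)
            full[idx] = g
            x._accum(full)

        outs.append(Tensor._make(x.data[idx].copy(), (x,), bw))
    return outs


def pad2d_nhwc(x: Tensor, pb: int, pr: int) -> Tensor:
    """Zero-pad bottom/right of an (N, H, W, C) token map."""
    if pb == 0 and pr == 0:
        return x
    out_data = np.pad(x.data, ((0, 0), (0, pb), (0, pr), (0, 0)))
    H, W = x.data.shape[1:3]

    def bw(g):
        x._accum(g[:, :H, :W, :])

    return Tensor._make(out_data, (x,), bw)


def pad2d_nchw(x: Tensor, pb: int, pr: int) -> Tensor:
    """Zero-pad bottom/right of an (N, C, H, W) map."""
    if pb == 0 and pr == 0:
        return x
    out_data = np.pad(x.data, ((0, 0), (0, 0), (0, pb), (0, pr)))
    H, W = x.data.shape[2:]

    def bw(g):
        x._accum(g[:, :, :H, :W])

    return Tensor._make(out_data, (x,), bw)


def roll2d(x: Tensor, shift_h: int, shift_w: int) -> Tensor:
    """Cyclic shift of an (N, H, W, C) map (Swin shifted windows)."""
    out_data = np.roll(x.data, (shift_h, shift_w), axis=(1, 2))

    def bw(g):
        x._accum(np.roll(g, (-shift_h, -shift_w), axis=(1, 2)))

    return Tensor._make(out_data, (x,), bw)


def take(table: Tensor, index: np.ndarray) -> Tensor:
    """Gather rows of a parameter table (relative position bias lookup)."""
    out_data = table.data[index]

    def bw(g):
        full = np.zeros_like(table.data)
        np.add.at(full, index, g)
        table._accum(full)

    return Tensor._make(out_data, (table,), bw)


def add_const(x: Tensor, const: np.ndarray) -> Tensor:
    """Add a constant (no-grad) array, e.g. an attention mask."""
    def bw(g):
        x._accum(g)

    return Tensor._make(x.data + const, (x,), bw)


def scale_by(x: Tensor, const: np.ndarray | float) -> Tensor:
    """Multiply by a constant (no-grad) array, e.g. a dropout mask."""
    const = np.asarray(const, dtype=np.float32)

    def bw(g):
        x._accum(_np_unbroadcast(g * const, x.data.shape))

    return Tensor._make(x.data * const, (x,), bw)


def _np_unbroadcast(grad, shape):
    from .tensor import _unbroadcast

    return _unbroadcast(grad, shape)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy from raw logits; labels are integer class ids."""
    n = logits.data.shape[0]
    m = logits.data.max(axis=1, keepdims=True)
    z = logits.data - m
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    loss = -logp[np.arange(n), labels].mean()

    def bw(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accum((g * p / n).astype(np.float32))

    return Tensor._make(np.float32(loss), (logits,), bw)
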