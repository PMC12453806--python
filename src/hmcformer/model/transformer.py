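"""Transformer branch: windowed attention blocks in a Swin-style pyramid.

Token maps are (N, H, W, C).  Each stage halves the spatial size and doubles
the channel dim via patch merging.  The branch exposes three block types:

* ``W-MSA`` / ``SW-MSA`` — plain and shifted window multi-head attention with
  relative position bias.
* ``W-MSA-m`` — the fusion attention: CNN-branch features, after an adaptive
  MLP + LayerNorm preprocessing, contribute a second query/key/value triple
  *through the same projection weights*; logits become
  ``(Q K^T + q k^T) / sqrt(d_k)`` and values ``V + v``.  With a zero CNN
  input it reduces exactly to W-MSA.
"""

from __future__ import annotations

import numpy as np

from ..nn import functional as F
from ..nn.modules import (Conv2d, DropPath, Identity, LayerNorm, Linear, Mlp,
                          Module, Parameter, trunc_normal)
from ..nn.tensor import Tensor

# ---------------------------------------------------------------------------
# window bookkeeping
# ---------------------------------------------------------------------------


def window_partition(x: Tensor, w: int) -> Tensor:
    """(N, H, W, C) -> (N*nW, w*w, C); H and W must be multiples of w."""
    N, H, W, C = x.shape
    x = x.reshape(N, H // w, w, W // w, w, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(N * (H // w) * (W // w), w * w, C)


def window_departition(xw: Tensor, w: int, H: int, W: int) -> Tensor:
    """Inverse of :func:`window_partition`."""
    nW = (H // w) * (W // w)
    N = xw.shape[0] // nW
    x = xw.reshape(N, H // w, W // w, w, w, xw.shape[-1])
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(N, H, W, xw.shape[-1])


def relative_position_index(w: int, table_window: int | None = None
                            ) -> np.ndarray:
    """Swin's (w*w, w*w) index into the (2W-1)^2 relative bias table.

    ``table_window`` is the window the table was sized for; ``w <= W``
    allows reusing the table when a small feature map clamps the window.
    """
    W = table_window or w
    coords = np.stack(np.meshgrid(np.arange(w), np.arange(w), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]
    rel = rel.transpose(1, 2, 0) + (W - 1)
    return (rel[:, :, 0] * (2 * W - 1) + rel[:, :, 1]).astype(np.int64)


_MASK_CACHE: dict = {}


def attention_mask(Hp: int, Wp: int, H: int, W: int, w: int,
                   shift: int) -> np.ndarray | None:
    """(nW, w*w, w*w) additive mask for shifted windows and padded tokens."""
    key = (Hp, Wp, H, W, w, shift)
    if key in _MASK_CACHE:
        return _MASK_CACHE[key]
    if shift == 0 and Hp == H and Wp == W:
        _MASK_CACHE[key] = None
        return None
    img = np.zeros((Hp, Wp), dtype=np.float64)
    if shift > 0:
        cnt = 0
        for hs in (slice(0, Hp - w), slice(Hp - w, Hp - shift),
                   slice(Hp - shift, Hp)):
            for ws in (slice(0, Wp - w), slice(Wp - w, Wp - shift),
                       slice(Wp - shift, Wp)):
                img[hs, ws] = cnt
                cnt += 1
    # padded rows/cols get ids distinct from every real region
    img[H:, :] = -1.0
    img[:, W:] = -2.0
    win = img.reshape(Hp // w, w, Wp // w, w).transpose(0, 2, 1, 3)
    win = win.reshape(-1, w * w)
    mask = np.where(win[:, None, :] != win[:, :, None], -100.0, 0.0)
    mask = mask.astype(np.float32)
    _MASK_CACHE[key] = mask
    return mask


# ---------------------------------------------------------------------------
# attention modules
# ---------------------------------------------------------------------------


class WindowAttention(Module):
    """Multi-head attention inside one window, with relative position bias.

    When ``yw`` (preprocessed CNN-branch windows) is given, its q/k/v are
    produced by the *same* projection weights and enter the fusion form
    ``softmax((QK^T + qk^T)/sqrt(d) + B)(V + v)``.
    """

    def __init__(self, dim: int, heads: int, window: int,
                 rng: np.random.Generator, qkv_bias: bool = True):
        super().__init__()
        assert dim % heads == 0
        self.dim, self.heads, self.window = dim, heads, window
        self.head_dim = dim // heads
        self.scale = self.head_dim ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng, bias=qkv_bias)
        self.proj = Linear(dim, dim, rng)
        self.bias_table = Parameter(
            trunc_normal(rng, ((2 * window - 1) ** 2, heads)))
        self._bias_index = {window: relative_position_index(window)}

    def _heads_of(self, t: Tensor, with_bias: bool = True):
        B, T, _ = t.shape
        bias = self.qkv.bias if with_bias else None
        qkv = F.linear(t, self.qkv.weight, bias)
        qkv = qkv.reshape(B, T, 3, self.heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, h, T, hd)
        return qkv[0], qkv[1], qkv[2]

    def forward(self, xw: Tensor, yw: Tensor | None = None,
                mask: np.ndarray | None = None) -> Tensor:
        B, T, C = xw.shape
        q, k, v = self._heads_of(xw)
        logits = F.bmm(q, k.transpose(0, 1, 3, 2))
        if yw is not None:
            # CNN-side projections are pure weight products (shared weights,
            # no bias), so a zero CNN input contributes nothing
            q2, k2, v2 = self._heads_of(yw, with_bias=False)
            logits = logits + F.bmm(q2, k2.transpose(0, 1, 3, 2))
            v = v + v2
        logits = logits * self.scale
        w_eff = int(round(T ** 0.5))
        if w_eff not in self._bias_index:
            self._bias_index[w_eff] = relative_position_index(
                w_eff, self.window)
        bias = F.take(self.bias_table, self._bias_index[w_eff].reshape(-1))
        bias = bias.reshape(1, T, T, self.heads).transpose(0, 3, 1, 2)
        logits = logits + bias
        if mask is not None:
            nW = mask.shape[0]
            logits = logits.reshape(B // nW, nW, self.heads, T, T)
            logits = F.add_const(logits, mask[None, :, None])
            logits = logits.reshape(B, self.heads, T, T)
        attn = F.softmax(logits, axis=-1)
        out = F.bmm(attn, v)  # (B, h, T, hd)
        out = out.transpose(0, 2, 1, 3).reshape(B, T, C)
        return self.proj(out)


class AttentionBlock(Module):
    """One pre-norm attention module + MLP (two residual sub-layers).

    ``kind`` selects plain (``"w"``), shifted (``"sw"``) or fusion
    (``"wm"``) window attention.  Fusion blocks own the adaptive
    preprocessing ``LN(MLP(y))`` that maps CNN features into the token dim.
    """

    def __init__(self, dim: int, heads: int, window: int, kind: str,
                 rng: np.random.Generator, mlp_ratio: float = 4.0,
                 drop_path: float = 0.0, cnn_dim: int | None = None,
                 adaptive_mlp_ratio: float = 2.0):
        super().__init__()
        assert kind in ("w", "sw", "wm")
        self.kind = kind
        self.window = window
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, window, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)
        self.drop_path = DropPath(drop_path, rng) if drop_path else Identity()
        if kind == "wm":
            cnn_dim = cnn_dim or dim
            hidden = int(cnn_dim * adaptive_mlp_ratio)
            self.pre_mlp = Mlp(cnn_dim, hidden, rng, out_dim=dim)
            self.pre_norm = LayerNorm(dim)

    def _windows(self, t: Tensor, w: int, shift: int, Hp: int, Wp: int):
        if shift:
            t = F.roll2d(t, -shift, -shift)
        return window_partition(t, w)

    def forward(self, x: Tensor, y: Tensor | None = None) -> Tensor:
        N, H, W, C = x.shape
        w = min(self.window, H, W)
        shift = w // 2 if self.kind == "sw" else 0
        Hp = -(-H // w) * w
        Wp = -(-W // w) * w
        mask = attention_mask(Hp, Wp, H, W, w, shift)

        shortcut = x
        x = self.norm1(x)
        x = F.pad2d_nhwc(x, Hp - H, Wp - W)
        xw = self._windows(x, w, shift, Hp, Wp)

        yw = None
        if self.kind == "wm":
            if y is None:
                raise ValueError("fusion attention requires CNN features")
            yt = self.pre_norm(self.pre_mlp(y))     # adaptive preprocessing
            yt = F.pad2d_nhwc(yt, Hp - H, Wp - W)
            yw = self._windows(yt, w, shift, Hp, Wp)

        aw = self.attn(xw, yw=yw, mask=mask)
        a = window_departition(aw, w, Hp, Wp)
        if shift:
            a = F.roll2d(a, shift, shift)
        if Hp != H or Wp != W:
            a = a[:, :H, :W, :]
        x = shortcut + self.drop_path(a)
        x = x + self.drop_path(self.mlp(self.norm2(x)))
        return x


# ---------------------------------------------------------------------------
# stems and downsampling
# ---------------------------------------------------------------------------


class PatchEmbed(Module):
    """4x4 stride-4 patch embedding of the RGB input, LN on tokens."""

    def __init__(self, in_ch: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.proj = Conv2d(in_ch, dim, 4, rng, stride=4)
        self.norm = LayerNorm(dim)

    def forward(self, img: Tensor) -> Tensor:
        x = self.proj(img)                 # (N, C, H/4, W/4)
        x = x.transpose(0, 2, 3, 1)        # tokens (N, H, W, C)
        return self.norm(x)


class PatchMerging(Module):
    """Concatenate 2x2 neighbourhoods, LN, project 4C -> 2C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm = LayerNorm(4 * dim)
        self.reduction = Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        N, H, W, C = x.shape
        x = F.pad2d_nhwc(x, H % 2, W % 2)
        x0 = x[:, 0::2, 0::2, :]
        x1 = x[:, 1::2, 0::2, :]
        x2 = x[:, 0::2, 1::2, :]
        x3 = x[:, 1::2, 1::2, :]
        x = F.concat([x0, x1, x2, x3], axis=-1)
        return self.reduction(self.norm(x))
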