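"""CNN branch: hierarchical multi-scale pixel-excitation (HMSPE) blocks.

Feature maps are (N, C, H, W).  An HMSPE block 1x1-projects its input,
splits it into four equal channel groups and routes them through residual
conv blocks at three scales (5x5, 3x3, dilated 3x3), with Res2Net-style
progressive cross-feeding between the paths.  Each of the four outputs is
gated per pixel by a PEM; the block output is
``Concat(y1 + y2, y3 + y4) + x``.

The branch also hosts the fusion of transformer features into the CNN
stream (3x3 + 1x1 adaptive preprocessing, concat, inverted-bottleneck
1x1 expand -> SE -> 1x1 compress -> channel shuffle) and the widening
HMSPE blocks used in the last two stages.
"""

from __future__ import annotations

import numpy as np

from ..nn import functional as F
from ..nn.modules import (ChannelLayerNorm, Conv2d, Linear, Module)
from ..nn.tensor import Tensor


class ConvBlock(Module):
    """Residual expand/compress conv block at one scale.

    ``k x k`` conv expands 0.25C -> 0.5C, GELU, 1x1 compresses back to
    0.25C, plus the identity shortcut.  ``dilation=1`` on a 3x3 kernel
    with padding 2 realises the d=1 dilated variant (5x5 receptive field
    when stacked twice).
    """

    def __init__(self, ch: int, kernel: int, rng, dilated: bool = False):
        super().__init__()
        d = 2 if dilated else 1          # numpy/"rate" convention: rate 2
        pad = (kernel - 1) * d // 2
        self.expand = Conv2d(ch, 2 * ch, kernel, rng, padding=pad, dilation=d)
        self.compress = Conv2d(2 * ch, ch, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.compress(F.gelu(self.expand(x))) + x


class PEM(Module):
    """Pixel-wise excitation: a 1x1 bottleneck producing a sigmoid gate
    that multiplies the input element-wise, followed by LayerNorm."""

    def __init__(self, ch: int, rng):
        super().__init__()
        self.fc1 = Conv2d(ch, ch, 1, rng)
        self.fc2 = Conv2d(ch, ch, 1, rng)
        self.norm = ChannelLayerNorm(ch)

    def forward(self, x: Tensor) -> Tensor:
        gate = F.sigmoid(self.fc2(F.gelu(self.fc1(x))))
        return self.norm(x * gate)


class SqueezeExcite(Module):
    """Channel attention: global pool -> bottleneck MLP -> sigmoid scale."""

    def __init__(self, ch: int, rng, reduction: int = 16):
        super().__init__()
        hidden = max(1, ch // reduction)
        self.fc1 = Linear(ch, hidden, rng)
        self.fc2 = Linear(hidden, ch, rng)

    def forward(self, x: Tensor) -> Tensor:
        s = F.global_avg_pool(x)                       # (N, C)
        s = F.sigmoid(self.fc2(F.relu(self.fc1(s))))
        return x * s.reshape(s.shape[0], s.shape[1], 1, 1)


def channel_shuffle(x: Tensor, groups: int = 2) -> Tensor:
    """Interleave channel groups (a pure permutation of channels)."""
    N, C, H, W = x.shape
    x = x.reshape(N, groups, C // groups, H, W)
    x = x.transpose(0, 2, 1, 3, 4)
    return x.reshape(N, C, H, W)


class HMSPE(Module):
    """Hierarchical multi-scale pixel excitation block (C -> C)."""

    def __init__(self, ch: int, rng):
        super().__init__()
        assert ch % 4 == 0, "HMSPE needs channels divisible by 4"
        q = ch // 4
        self.in_conv = Conv2d(ch, ch, 1, rng)
        self.f5 = ConvBlock(q, 5, rng)                     # x2 path
        self.f3_a = ConvBlock(q, 3, rng)                   # x3 path
        self.f3_b = ConvBlock(q, 3, rng)                   # x4 path, 1st
        self.f3_c = ConvBlock(q, 3, rng)                   # x4 path, 2nd
        self.fd_a = ConvBlock(q, 3, rng, dilated=True)     # on shared s
        self.fd_b = ConvBlock(q, 3, rng, dilated=True)     # on fd_a(s)
        self.fd_c = ConvBlock(q, 3, rng, dilated=True)     # y4 merge path
        self.pem1 = PEM(2 * q, rng)
        self.pem2 = PEM(2 * q, rng)
        self.pem3 = PEM(2 * q, rng)
        self.pem4 = PEM(2 * q, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.in_conv(x)
        x1, x2, x3, x4 = F.split(h, 4, axis=1)
        a = self.f5(x2)                 # f5x5(x2)
        b = self.f3_a(x3)               # f3x3(x3)
        s = a + b                       # shared cross-feed
        t = self.fd_a(s)
        u = self.f3_b(x4)               # f3x3(x4)
        w = self.f3_c(u)                # f3x3(f3x3(x4))
        y1 = self.pem1(F.concat([x1, a], axis=1))
        y2 = self.pem2(F.concat([b, t], axis=1))
        y3 = self.pem3(F.concat([w, self.fd_b(t)], axis=1))
        y4 = self.pem4(F.concat([u, self.fd_c(w + t)], axis=1))
        return F.concat([y1 + y2, y3 + y4], axis=1) + x


class HMSPEUp(Module):
    """Channel-widening HMSPE (MobileNetV3-style inverted bottleneck):
    1x1 doubles channels, HMSPE at the widened dim, SE, then a 1x1 conv
    aligning the output to the transformer stage dim."""

    def __init__(self, ch: int, out_ch: int, rng, se_reduction: int = 16):
        super().__init__()
        self.expand = Conv2d(ch, 2 * ch, 1, rng)
        self.hmspe = HMSPE(2 * ch, rng)
        self.se = SqueezeExcite(2 * ch, rng, se_reduction)
        self.align = Conv2d(2 * ch, out_ch, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.align(self.se(self.hmspe(F.gelu(self.expand(x)))))


class CnnFusion(Module):
    """Inject transformer features (adaptively preprocessed) mid-stage.

    ``F(X) = 1x1_{1.5C->C}(GELU(3x3_{C->1.5C}(X)))``; the concat of the
    HMSPE output with F(X) passes through an inverted bottleneck
    (1x1 2C->4C, GELU, SE, 1x1 4C->C) and a channel shuffle.
    """

    def __init__(self, ch: int, rng, se_reduction: int = 16):
        super().__init__()
        mid = ch * 3 // 2
        self.pre3 = Conv2d(ch, mid, 3, rng, padding=1)
        self.pre1 = Conv2d(mid, ch, 1, rng)
        self.expand = Conv2d(2 * ch, 4 * ch, 1, rng)
        self.se = SqueezeExcite(4 * ch, rng, se_reduction)
        self.compress = Conv2d(4 * ch, ch, 1, rng)

    def forward(self, y_h: Tensor, x_tok: Tensor) -> Tensor:
        """``y_h``: CNN features (N,C,H,W); ``x_tok``: transformer tokens
        (N,H,W,C) at the same resolution."""
        X = x_tok.transpose(0, 3, 1, 2)
        fX = self.pre1(F.gelu(self.pre3(X)))
        f1 = F.concat([y_h, fX], axis=1)
        out = self.compress(self.se(F.gelu(self.expand(f1))))
        return channel_shuffle(out, groups=2)


class CnnStem(Module):
    """Stride-4 stem on the enhanced grayscale input (ConvNeXt style)."""

    def __init__(self, in_ch: int, dim: int, rng):
        super().__init__()
        self.proj = Conv2d(in_ch, dim, 4, rng, stride=4)
        self.norm = ChannelLayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.proj(x))


class CnnDownsample(Module):
    """LN then 2x2 stride-2 conv doubling the channels.

    Odd spatial sizes are zero-padded to even first, keeping the branch
    aligned with the transformer's patch merging.
    """

    def __init__(self, dim: int, rng):
        super().__init__()
        self.norm = ChannelLayerNorm(dim)
        self.proj = Conv2d(dim, 2 * dim, 2, rng, stride=2)

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[2:]
        x = F.pad2d_nchw(x, H % 2, W % 2)
        return self.proj(self.norm(x))
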