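"""Assembly of the dual-branch screening network.

Stage layout (stage dims ``C * 2^s`` in both branches, spatial sizes
``img/4 / 2^s``):

* transformer side — every stage hosts one core block pair: an SW-MSA
  module followed by the fusion W-MSA-m module.  The depth-6 stage wraps
  that pair with a plain Swin block (W-MSA + SW-MSA) before and after.
* CNN side — one or two HMSPE blocks per stage.  The transformer->CNN
  fusion sits after the first HMSPE (between the two where the depth is
  2).  The last two stages end with a channel-widening HMSPE block.
* the two branches cross mid-stage: the W-MSA-m consumes the first
  HMSPE's output, the CNN fusion consumes the tokens leaving the SW-MSA
  module, so each branch receives the other's features at a stage-internal
  ("moderately disadvantaged") point.

The classifier head pools both final feature maps, concatenates them and
applies LN + a linear layer.
"""

from __future__ import annotations

import numpy as np

from ..config import ModelConfig
from ..nn import functional as F
from ..nn.functional import MacCounter
from ..nn.modules import LayerNorm, Linear, Module
from ..nn.tensor import Tensor, no_grad
from .cnn import CnnDownsample, CnnFusion, CnnStem, HMSPE, HMSPEUp
from .transformer import AttentionBlock, PatchEmbed, PatchMerging


class Stage(Module):
    def __init__(self, cfg: ModelConfig, s: int, rng, drop_rates):
        super().__init__()
        dim = cfg.embed_dim << s
        heads = cfg.resolve_heads()[s]
        w = cfg.window_size
        mk = lambda kind, dp: AttentionBlock(
            dim, heads, w, kind, rng, cfg.mlp_ratio, dp, cnn_dim=dim,
            adaptive_mlp_ratio=cfg.adaptive_mlp_ratio)
        extra = cfg.transformer_depths[s] - 2
        assert extra >= 0 and extra % 4 == 0, \
            "extra depth must come in whole Swin blocks (W-MSA + SW-MSA x2)"
        n_pre = extra // 4
        it = iter(drop_rates)
        self.pre_blocks = [b for _ in range(n_pre)
                           for b in (mk("w", next(it)), mk("sw", next(it)))]
        self.sw_block = mk("sw", next(it))
        self.wm_block = mk("wm", next(it))
        self.post_blocks = [b for _ in range(n_pre)
                            for b in (mk("w", next(it)), mk("sw", next(it)))]

        self.hmspe1 = HMSPE(dim, rng)
        self.fusion = CnnFusion(dim, rng, cfg.se_reduction)
        self.hmspe2 = HMSPE(dim, rng) if cfg.cnn_depths[s] == 2 else None
        self.hmspe_up = (HMSPEUp(dim, dim, rng, cfg.se_reduction)
                         if s >= 2 else None)

    def forward(self, x: Tensor, y: Tensor):
        for b in self.pre_blocks:
            x = b(x)
        x_mid = self.sw_block(x)
        y_h = self.hmspe1(y)
        # cross-injection at the stage-internal point of both branches
        y_tok = y_h.transpose(0, 2, 3, 1)
        x = self.wm_block(x_mid, y=y_tok)
        y = self.fusion(y_h, x_mid)
        if self.hmspe2 is not None:
            y = self.hmspe2(y)
        for b in self.post_blocks:
            x = b(x)
        if self.hmspe_up is not None:
            y = self.hmspe_up(y)
        return x, y


class HMCFormer(Module):
    """Dual-input classifier: raw RGB (transformer) + enhanced gray (CNN)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.patch_embed = PatchEmbed(3, cfg.embed_dim, rng)
        self.stem = CnnStem(1, cfg.embed_dim, rng)
        total_attn = sum(cfg.transformer_depths)
        rates = iter(np.linspace(0.0, cfg.drop_path, total_attn))
        self.stages = []
        self.mergers = []
        self.downsamples = []
        for s in range(4):
            if s > 0:
                self.mergers.append(PatchMerging(cfg.embed_dim << (s - 1), rng))
                self.downsamples.append(
                    CnnDownsample(cfg.embed_dim << (s - 1), rng))
            self.stages.append(Stage(cfg, s, rng, rates))
        final = cfg.embed_dim << 3
        self.head_norm = LayerNorm(2 * final)
        self.head = Linear(2 * final, cfg.num_classes, rng)

    def forward(self, img_rgb: Tensor, img_eg: Tensor,
                return_features: bool = False):
        x = self.patch_embed(img_rgb)
        y = self.stem(img_eg)
        for s, stage in enumerate(self.stages):
            if s > 0:
                x = self.mergers[s - 1](x)
                y = self.downsamples[s - 1](y)
            x, y = stage(x, y)
        x_vec = x.mean(axis=(1, 2))          # (N, 8C) pooled tokens
        y_vec = F.global_avg_pool(y)         # (N, 8C) pooled CNN map
        feats = F.concat([x_vec, y_vec], axis=-1)
        logits = self.head(self.head_norm(feats))
        if return_features:
            return logits, x_vec, y_vec
        return logits


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> HMCFormer:
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(seed)
    return HMCFormer(cfg, rng)


def count_parameters(model: Module) -> float:
    """Trainable parameter count in millions."""
    return model.num_parameters() / 1e6


def count_flops(model: HMCFormer, img_size: int | None = None) -> float:
    """Forward-pass cost in GFLOPs (multiply-accumulate convention).

    Counts conv, linear and attention matmul MACs for a single input of
    ``img_size`` (default: the model's configured resolution), the same
    convention as mainstream profilers.
    """
    size = img_size or model.cfg.img_size
    was_training = model.training
    model.eval()
    rgb = Tensor(np.zeros((1, 3, size, size), dtype=np.float32))
    eg = Tensor(np.zeros((1, 1, size, size), dtype=np.float32))
    with no_grad(), MacCounter() as counter:
        model(rgb, eg)
    model.train(was_training)
    return counter.total / 1e9
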