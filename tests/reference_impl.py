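"""Independent reference implementations used as test oracles.

These deliberately avoid the package's code paths: plain loops and dense
matrices, written from the textbook definitions, so agreement with the
library is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# histogram redistribution / CLAHE
# ---------------------------------------------------------------------------


def ref_redistribute(h: np.ndarray, clip_limit: float, D: int) -> np.ndarray:
    """Unit-at-a-time round-robin allocator over the receiving bins.

    Clips every bin to floor(clip_limit); sweeps bins 0..D-1 adding one
    unit to each bin below the cap until the excess is gone.  If all
    receiving bins saturate, the remainder is spread evenly over them.
    """
    cap = int(np.floor(clip_limit))
    out = [min(int(v), cap) for v in h]
    excess = int(sum(int(v) for v in h) - sum(out))
    while excess > 0:
        progressed = False
        for x in range(D):
            if excess == 0:
                break
            if out[x] < cap:
                out[x] += 1
                excess -= 1
                progressed = True
        if not progressed and excess > 0:
            q, r = divmod(excess, D)
            for x in range(D):
                out[x] += q + (1 if x < r else 0)
            excess = 0
    return np.asarray(out, dtype=np.int64)


def ref_equalization_map(h: np.ndarray, L: int) -> np.ndarray:
    M = float(np.sum(h))
    lut = []
    c = 0.0
    for x in range(L):
        c += float(h[x])
        lut.append(min(L - 1, max(0, int(round((L - 1) * c / M)))))
    return np.asarray(lut, dtype=np.int64)


def ref_clahe(channel: np.ndarray, grid, norm_clip: float, L: int = 256,
              D: int | None = None) -> np.ndarray:
    """Textbook tiled CLAHE with bilinear blending, pixel loops.

    Uses the same published conventions as the library (clip limit
    formula, tile-centre anchors, round-half-up equalisation) but an
    entirely separate implementation.  ``D=None`` means uniform
    redistribution over all bins (standard CLAHE).
    """
    gr, gc = grid
    H, W = channel.shape
    assert H % gr == 0 and W % gc == 0, "reference expects exact tiling"
    th, tw = H // gr, W // gc
    M = th * tw
    clip_limit = M / L + (M - M / L) / norm_clip
    D_eff = L if D is None else D

    luts = np.zeros((gr, gc, L), dtype=np.int64)
    for i in range(gr):
        for j in range(gc):
            tile = channel[i * th:(i + 1) * th, j * tw:(j + 1) * tw]
            hist = np.zeros(L, dtype=np.int64)
            for v in tile.ravel():
                hist[int(v)] += 1
            hist = ref_redistribute(hist, clip_limit, D_eff)
            luts[i, j] = ref_equalization_map(hist, L)

    out = np.zeros((H, W), dtype=np.float64)
    for y in range(H):
        fy = (y - (th / 2.0 - 0.5)) / th
        i0 = int(np.floor(fy))
        wy = fy - i0
        if i0 < 0:
            i0, wy = 0, 0.0
        if i0 + 1 > gr - 1:
            i0, wy = gr - 1, 0.0
        i1 = min(i0 + 1, gr - 1)
        for x in range(W):
            fx = (x - (tw / 2.0 - 0.5)) / tw
            j0 = int(np.floor(fx))
            wx = fx - j0
            if j0 < 0:
                j0, wx = 0, 0.0
            if j0 + 1 > gc - 1:
                j0, wx = gc - 1, 0.0
            j1 = min(j0 + 1, gc - 1)
            v = int(channel[y, x])
            top = (1 - wx) * luts[i0, j0, v] + wx * luts[i0, j1, v]
            bot = (1 - wx) * luts[i1, j0, v] + wx * luts[i1, j1, v]
            out[y, x] = (1 - wy) * top + wy * bot
    return np.clip(np.rint(out), 0, L - 1).astype(channel.dtype)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------


def ref_window_attention(x: np.ndarray, wqkv: np.ndarray, bqkv,
                         wproj: np.ndarray, bproj: np.ndarray,
                         heads: int, bias_table: np.ndarray,
                         bias_index: np.ndarray,
                         y: np.ndarray | None = None) -> np.ndarray:
    """Dense single-window attention oracle (explicit score matrix).

    ``x``: (T, C) tokens of one window.  When ``y`` is given, its q/k/v
    come from the same weights (bias-free) and enter the fused form
    softmax((QK^T + qk^T)/sqrt(d) + B)(V + v).
    """
    T, C = x.shape
    hd = C // heads
    scale = 1.0 / np.sqrt(hd)

    def proj_qkv(t, with_bias):
        out = t @ wqkv.T
        if with_bias and bqkv is not None:
            out = out + bqkv
        q, k, v = out[:, :C], out[:, C:2 * C], out[:, 2 * C:]
        return q, k, v

    q, k, v = proj_qkv(x, True)
    out = np.zeros((T, C))
    for h in range(heads):
        sl = slice(h * hd, (h + 1) * hd)
        scores = q[:, sl] @ k[:, sl].T
        vv = v[:, sl].copy()
        if y is not None:
            q2, k2, v2 = proj_qkv(y, False)
            scores = scores + q2[:, sl] @ k2[:, sl].T
            vv = vv + v2[:, sl]
        scores = scores * scale + bias_table[bias_index, h]
        scores = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(axis=1, keepdims=True)
        out[:, sl] = attn @ vv
    return out @ wproj.T + bproj


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def ref_binary_metrics(preds: np.ndarray, labels: np.ndarray) -> dict:
    """Brute-force metric recomputation from raw prediction arrays."""
    tp = int(np.sum((preds == 1) & (labels == 1)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * sens * prec / (sens + prec) if sens + prec else 0.0
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n ** 2
    kappa = (acc - pe) / (1 - pe) if pe < 1 else 1.0
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "error_rate": 1 - acc, "precision": prec, "recall": sens,
            "f1": f1, "kappa": kappa}


def ref_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
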