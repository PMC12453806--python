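"""Training and evaluation of the dual-branch network on labelled images.

The data model is a list of (raw RGB, enhanced grayscale, label) triples:
enhancement runs once per image (it is deterministic), augmentation runs
per epoch with per-epoch derived seeds, so a run is reproducible from its
seed and resuming from a checkpoint continues the exact schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..config import EnhanceConfig, TrainConfig
from ..enhancement import enhance_image, to_grayscale
from ..model.network import HMCFormer
from ..nn import AdamW, CosineSchedule, Tensor, no_grad
from ..nn.functional import cross_entropy, softmax
from .augment import transform_pair, draw_params
from .metrics import MetricsReport, metrics_from_predictions


@dataclass
class PreparedData:
    """Raw images plus their enhanced-grayscale counterparts."""

    rgb: list                      # uint8 (H, W, 3) arrays
    gray: list                     # uint8 (H, W) enhanced grayscale
    labels: np.ndarray

    def __len__(self):
        return len(self.rgb)


def prepare_data(images, labels, enhance_cfg: EnhanceConfig | None = None,
                 ) -> PreparedData:
    """Run the dual color-space enhancement on every image and keep the
    grayscale result as the CNN-branch input."""
    cfg = enhance_cfg or EnhanceConfig()
    grays = [to_grayscale(enhance_image(img, tuple(cfg.grid),
                                        cfg.norm_clip_luma,
                                        cfg.norm_clip_chroma))
             for img in images]
    return PreparedData(list(images), grays,
                        np.asarray(labels, dtype=np.int64))


def _resize_for(crop: int) -> int:
    # keep the 260:224 resize-to-crop ratio of the full-size protocol
    return int(round(crop * 260 / 224))


def _batch_arrays(data: PreparedData, idx, crop: int,
                  rng: np.random.Generator | None):
    resize = _resize_for(crop)
    rgbs, grays = [], []
    for i in idx:
        params = draw_params(rng, resize, crop) if rng is not None else None
        r, g = transform_pair(data.rgb[i], data.gray[i], params, resize, crop)
        rgbs.append(r)
        grays.append(g)
    return (Tensor(np.stack(rgbs)), Tensor(np.stack(grays)),
            data.labels[np.asarray(idx)])


def train_model(model: HMCFormer, data: PreparedData,
                train_idx, val_idx=None, cfg: TrainConfig | None = None,
                start_epoch: int = 0, end_epoch: int | None = None,
                optimizer: AdamW | None = None, log=None) -> dict:
    """Cross-entropy training loop; returns history and the optimizer.

    Per-epoch RNGs are derived from ``cfg.seed`` and the epoch number, so
    two runs with the same seed produce identical histories, and a run
    stopped at ``end_epoch`` then resumed at ``start_epoch`` (with the
    saved optimizer) continues the original schedule exactly.
    """
    cfg = cfg or TrainConfig()
    train_idx = np.asarray(train_idx)
    crop = model.cfg.img_size
    opt = optimizer or AdamW(model.parameters(), lr=cfg.lr,
                             weight_decay=cfg.weight_decay)
    steps_per_epoch = max(1, -(-train_idx.size // cfg.batch_size))
    sched = CosineSchedule(opt, cfg.epochs * steps_per_epoch, cfg.min_lr)
    sched.step_num = start_epoch * steps_per_epoch
    history = []
    for epoch in range(start_epoch, end_epoch or cfg.epochs):
        rng = np.random.default_rng((cfg.seed * 100003 + epoch) % (2 ** 31))
        order = rng.permutation(train_idx)
        model.train()
        losses = []
        for b in range(0, order.size, cfg.batch_size):
            idx = order[b:b + cfg.batch_size]
            rgb, gray, labels = _batch_arrays(data, idx, crop, rng)
            logits = model(rgb, gray)
            loss = cross_entropy(logits, labels)
            model.zero_grad()
            loss.backward()
            opt.step()
            sched.step()
            losses.append(loss.item())
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "lr": opt.lr}
        if val_idx is not None and len(val_idx):
            preds, _ = predict(model, data, val_idx,
                               batch_size=cfg.batch_size)
            entry["val_accuracy"] = float(
                (preds == data.labels[np.asarray(val_idx)]).mean())
        history.append(entry)
        if log is not None:
            log(entry)
    return {"history": history, "optimizer": opt}


def predict(model: HMCFormer, data: PreparedData, idx,
            batch_size: int = 16):
    """Deterministic (eval-transform) inference: class ids and softmax
    probabilities."""
    idx = np.asarray(idx)
    crop = model.cfg.img_size
    model.eval()
    probs = []
    with no_grad():
        for b in range(0, idx.size, batch_size):
            rgb, gray, _ = _batch_arrays(data, idx[b:b + batch_size],
                                         crop, None)
            logits = model(rgb, gray)
            probs.append(softmax(logits, axis=-1).numpy())
    probs = np.concatenate(probs, axis=0)
    return probs.argmax(axis=1), probs


def evaluate_model(model: HMCFormer, data: PreparedData, idx,
                   n_classes: int | None = None) -> MetricsReport:
    """Inference on ``idx`` followed by the confusion-matrix report
    (binary report with AUC for 2 classes, macro report otherwise)."""
    n_classes = n_classes or model.cfg.num_classes
    preds, probs = predict(model, data, idx)
    labels = data.labels[np.asarray(idx)]
    scores = probs[:, 1] if n_classes == 2 else None
    return metrics_from_predictions(preds, labels, scores, n_classes)


def extract_stage3_features(model: HMCFormer, data: PreparedData, idx,
                            batch_size: int = 16):
    """Pooled end-of-stage-3 feature vectors from both branches
    (inputs to the mutual-information diagnostics)."""
    idx = np.asarray(idx)
    crop = model.cfg.img_size
    model.eval()
    xs, ys = [], []
    with no_grad():
        for b in range(0, idx.size, batch_size):
            rgb, gray, _ = _batch_arrays(data, idx[b:b + batch_size],
                                         crop, None)
            _, x_vec, y_vec = model(rgb, gray, return_features=True)
            xs.append(x_vec.numpy())
            ys.append(y_vec.numpy())
    return np.concatenate(xs), np.concatenate(ys)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: HMCFormer, path: str | Path, epoch: int = 0,
                    optimizer: AdamW | None = None, extra: dict | None = None):
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    if optimizer is not None:
        for i, (m, v) in enumerate(zip(optimizer._m, optimizer._v)):
            payload[f"opt_m/{i}"] = m
            payload[f"opt_v/{i}"] = v
        payload["opt_t"] = np.asarray(optimizer.t)
    meta = {"epoch": epoch, "num_classes": model.cfg.num_classes,
            "img_size": model.cfg.img_size, **(extra or {})}
    payload["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(model: HMCFormer, path: str | Path,
                    optimizer: AdamW | None = None) -> dict:
    with np.load(path) as z:
        state = {k[len("param/"):]: z[k] for k in z.files
                 if k.startswith("param/")}
        model.load_state_dict(state)
        if optimizer is not None and "opt_t" in z.files:
            for i in range(len(optimizer.params)):
                optimizer._m[i] = z[f"opt_m/{i}"].copy()
                optimizer._v[i] = z[f"opt_v/{i}"].copy()
            optimizer.t = int(z["opt_t"])
        meta = json.loads(bytes(z["meta_json"]).decode())
    return meta
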