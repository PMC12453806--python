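"""Paired augmentation of the (raw RGB, enhanced grayscale) inputs.

Training path: resize to 260x260, random 224x224 crop, random rotation in
[-15, 15] degrees, horizontal flip with p=0.5, normalise.  Evaluation
path: resize + centre crop + normalise.  The *same* geometric transform is
drawn once per sample and applied to both inputs, preserving the spatial
correspondence the dual-branch fusion relies on.  Normalisation uses the
ImageNet mean/std for RGB and (0.5, 0.5) for the gray channel.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


def _resize(img: Image.Image, size: int) -> Image.Image:
    return img.resize((size, size), Image.BILINEAR)


def draw_params(rng: np.random.Generator, resize: int, crop: int) -> dict:
    """Sample one geometric transform (shared by the paired inputs)."""
    span = resize - crop
    return {
        "top": int(rng.integers(0, span + 1)),
        "left": int(rng.integers(0, span + 1)),
        "angle": float(rng.uniform(-15.0, 15.0)),
        "flip": bool(rng.random() < 0.5),
    }


def center_params(resize: int, crop: int) -> dict:
    span = resize - crop
    return {"top": span // 2, "left": span // 2, "angle": 0.0, "flip": False}


def _apply_geometric(img: Image.Image, p: dict, resize: int,
                     crop: int) -> Image.Image:
    img = _resize(img, resize)
    img = img.crop((p["left"], p["top"], p["left"] + crop, p["top"] + crop))
    if p["angle"] != 0.0:
        img = img.rotate(p["angle"], resample=Image.BILINEAR)
    if p["flip"]:
        img = img.transpose(Image.FLIP_LEFT_RIGHT)
    return img


def normalize_rgb(arr_u8: np.ndarray) -> np.ndarray:
    """(H, W, 3) uint8 -> (3, H, W) float32, ImageNet statistics."""
    x = arr_u8.astype(np.float32) / 255.0
    x = (x - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def normalize_gray(arr_u8: np.ndarray) -> np.ndarray:
    """(H, W) uint8 -> (1, H, W) float32, mean/std 0.5."""
    x = arr_u8.astype(np.float32) / 255.0
    return ((x - 0.5) / 0.5)[None]


def transform_pair(rgb_u8: np.ndarray, gray_u8: np.ndarray,
                   params: dict | None, resize: int = 260,
                   crop: int = 224) -> tuple[np.ndarray, np.ndarray]:
    """Apply one geometric transform (or the eval transform when
    ``params`` is None) to the paired inputs and normalise.

    Returns (3, crop, crop) and (1, crop, crop) float32 arrays.
    """
    if params is None:
        params = center_params(resize, crop)
    rgb = _apply_geometric(Image.fromarray(rgb_u8), params, resize, crop)
    gray = _apply_geometric(Image.fromarray(gray_u8, mode="L"), params,
                            resize, crop)
    return normalize_rgb(np.asarray(rgb)), normalize_gray(np.asarray(gray))


def augment(rgb_u8: np.ndarray, gray_u8: np.ndarray,
            rng: np.random.Generator, resize: int = 260, crop: int = 224):
    """Training-path transform with a freshly drawn random geometry."""
    return transform_pair(rgb_u8, gray_u8, draw_params(rng, resize, crop),
                          resize, crop)
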