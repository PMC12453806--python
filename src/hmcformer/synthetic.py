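"""Synthetic colposcopy-like images with controllable acetowhite lesions.

Real VIA screening images show a pink cervix with a central os; after
acetic acid, neoplastic epithelium turns white — faintly and focally for
CIN1, more prominently for CIN2, and as extensive coarse yellow-white
plaques for CIN3.  The generator renders that ordering with three knobs
per class: ``whiteness`` (opacity of the acetowhite overlay), ``extent``
(fraction of the cervix covered) and ``roughness`` (texture-noise
amplitude, giving irregular coarse plaques at high grade).  Lesion
contours come from thresholded smoothed noise, so they are irregular but
deterministic under the seed.

These images are separable by simple statistics by design; they exercise
the code paths (enhancement, dual-input training, metrics), not clinical
difficulty.  See docs/methods.md for what passing on them does and does
not show.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

CLASS_NAMES = ("normal", "CIN1", "CIN2", "CIN3")


@dataclass(frozen=True)
class LesionSpec:
    """Acetowhite-lesion parameters for one class."""

    class_label: str
    whiteness: float        # overlay opacity in [0, 1]
    extent: float           # target fraction of the cervix area
    roughness: float        # texture-noise amplitude in [0, 1]
    boundary_sharpness: float = 4.0   # alpha ramp steepness at the contour


# class-conditional defaults: whiteness/extent/roughness strictly increase
# normal -> CIN3, mirroring the clinical grading ladder
CLASS_SPECS: dict[str, LesionSpec] = {
    "normal": LesionSpec("normal", 0.0, 0.0, 0.0),
    "CIN1": LesionSpec("CIN1", 0.35, 0.12, 0.10, boundary_sharpness=2.0),
    "CIN2": LesionSpec("CIN2", 0.60, 0.30, 0.25, boundary_sharpness=4.0),
    "CIN3": LesionSpec("CIN3", 0.85, 0.50, 0.45, boundary_sharpness=8.0),
}


def _smooth_noise(rng, shape, sigma):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    f -= f.mean()
    s = f.std()
    return f / s if s > 0 else f


def generate_image(spec: LesionSpec, seed: int, size: int = 256):
    """Render one image; returns (uint8 RGB array, lesion mask).

    Deterministic: the same (spec, seed, size) yields a bit-identical
    image.  A ``normal`` spec produces an empty lesion mask.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)

    # geometry jitter
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    ry = size * rng.uniform(0.33, 0.40)
    rx = size * rng.uniform(0.30, 0.37)
    d2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    cervix = d2 <= 1.0

    # background: dark vaginal wall with mild illumination gradient
    img = np.zeros((size, size, 3))
    base_bg = np.array([72.0, 34.0, 40.0]) + rng.uniform(-6, 6, 3)
    grad = 1.0 + 0.12 * ((yy - cy) / size)
    img[:] = base_bg
    img *= grad[..., None]

    # cervix disc: pink, slightly darker toward the rim, speckled
    base_pink = np.array([208.0, 142.0, 150.0]) + rng.uniform(-8, 8, 3)
    shade = 1.0 - 0.25 * np.clip(d2, 0, 1)
    speck = 1.0 + 0.04 * _smooth_noise(rng, (size, size), 2.5)
    cerv_col = base_pink[None, None, :] * (shade * speck)[..., None]
    img = np.where(cervix[..., None], cerv_col, img)

    # os: small dark opening at the centre
    od2 = ((yy - cy) / (0.085 * size)) ** 2 + ((xx - cx) / (0.055 * size)) ** 2
    os_mask = od2 <= 1.0
    os_col = np.array([124.0, 62.0, 72.0]) + rng.uniform(-6, 6, 3)
    img = np.where(os_mask[..., None], os_col, img)

    # acetowhite lesion
    mask = np.zeros((size, size), dtype=bool)
    if spec.extent > 0 and spec.whiteness > 0:
        field = _smooth_noise(rng, (size, size), sigma=10.0)
        # bias the field toward a random point near the os so lesions grow
        # outward from the transformation zone
        fy = cy + rng.uniform(-0.08, 0.08) * size
        fx = cx + rng.uniform(-0.08, 0.08) * size
        r2 = (((yy - fy) / ry) ** 2 + ((xx - fx) / rx) ** 2)
        field = field - 1.2 * r2
        inside = field[cervix & ~os_mask]
        thr = np.quantile(inside, 1.0 - spec.extent)
        alpha = 1.0 / (1.0 + np.exp(-spec.boundary_sharpness
                                    * (field - thr)))
        alpha = np.where(cervix & ~os_mask, alpha, 0.0)
        mask = alpha > 0.5
        texture = 1.0 + spec.roughness * _smooth_noise(rng, (size, size), 1.5)
        opacity = np.clip(spec.whiteness * alpha * texture, 0.0, 1.0)
        lesion_col = np.array([238.0, 228.0, 198.0])  # yellow-white
        img = img * (1 - opacity[..., None]) + lesion_col * opacity[..., None]

    # sensor noise
    img += rng.normal(0.0, 2.0, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


@dataclass
class SynthDataset:
    images: list
    labels: np.ndarray            # 4-class integer labels (0..3)
    masks: list
    seed: int
    size: int
    params: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.images)

    def label_names(self):
        return [CLASS_NAMES[i] for i in self.labels]

    def labels_grouped(self, scheme: str) -> np.ndarray:
        """Map the 4-class labels onto the clinical groupings.

        ``binary``: normal vs any CIN; ``three``: normal / CIN1 (low grade)
        / CIN2+3 (high grade); ``four``: unchanged.
        """
        lab = self.labels
        if scheme == "four":
            return lab.copy()
        if scheme == "three":
            return np.minimum(lab, 2)
        if scheme == "binary":
            return (lab > 0).astype(lab.dtype)
        raise ValueError(f"unknown grouping {scheme!r}")


def generate_dataset(n_per_class: int, seed: int, size: int = 256,
                     classes=CLASS_NAMES) -> SynthDataset:
    """Balanced synthetic dataset; per-image seeds derive from ``seed``."""
    rng = np.random.default_rng(seed)
    images, labels, masks = [], [], []
    for ci, cname in enumerate(classes):
        spec = CLASS_SPECS[cname]
        for _ in range(n_per_class):
            img_seed = int(rng.integers(0, 2 ** 31 - 1))
            img, mask = generate_image(spec, img_seed, size)
            images.append(img)
            labels.append(CLASS_NAMES.index(cname))
            masks.append(mask)
    return SynthDataset(images, np.asarray(labels, dtype=np.int64), masks,
                        seed, size, {"n_per_class": n_per_class,
                                     "classes": list(classes)})


def write_dataset(ds: SynthDataset, out_dir: str | Path) -> pd.DataFrame:
    """Write PNGs plus a ``labels.csv`` manifest (filename,label)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, lab) in enumerate(zip(ds.images, ds.labels)):
        name = f"img_{i:05d}.png"
        Image.fromarray(img).save(out / name)
        rows.append({"filename": name, "label": CLASS_NAMES[lab]})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "labels.csv", index=False)
    return manifest


def confusion_fixture(tp: int, fp: int, tn: int, fn: int):
    """Prediction/label arrays realising exact binary confusion counts."""
    labels = np.concatenate([np.ones(tp + fn), np.zeros(tn + fp)])
    preds = np.concatenate([np.ones(tp), np.zeros(fn),
                            np.zeros(tn), np.ones(fp)])
    return preds.astype(np.int64), labels.astype(np.int64)
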