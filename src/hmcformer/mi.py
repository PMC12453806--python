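"""Entropy / mutual-information diagnostics for branch-feature fusion.

A parallel CNN+Transformer network works well when both branches carry
diverse information (high marginal entropies H(X), H(Y)) that is coupled
but not redundant.  With I(X;Y) = H(X) + H(Y) - H(X,Y), the synergy
criterion used here is

    I(X;Y) <= H(X) + H(Y) - max(H(X), H(Y))   (= min(H(X), H(Y)))

I near the bound indicates strong, low-redundancy coupling; I far below it
indicates the branches barely interact; an estimate above it (possible
only through estimator error for a true distribution) flags redundancy.

Estimation is plug-in over a discretisation of the feature vectors: each
sample is reduced to a scalar (top principal direction by default, or the
per-sample mean) and binned on an equal-width grid; joint entropy uses the
product grid, so I(X;X) = H(X) holds exactly and I is symmetric by
construction.  Entropies are in bits.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["FeatureSample", "discretize", "estimate_entropy",
           "mutual_information", "SynergyReport", "synergy_report"]


@dataclass(frozen=True)
class FeatureSample:
    """N samples of flattened branch features (N x d), with a branch tag."""

    values: np.ndarray
    branch: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2 or v.shape[0] < 2:
            raise ValueError("need an (N >= 2) x d feature matrix")
        if not np.isfinite(v).all():
            raise ValueError("features must be finite")
        object.__setattr__(self, "values", v)


def _as_sample(x) -> FeatureSample:
    return x if isinstance(x, FeatureSample) else FeatureSample(np.asarray(x))


def discretize(sample, bins: int = 64, mode: str = "pca") -> np.ndarray:
    """Reduce each sample to a scalar and bin it; returns integer codes.

    ``mode='pca'`` projects onto the top principal direction (global
    covariance over all dims); ``mode='mean'`` uses the per-sample mean
    activation.  A constant sample maps to a single code.
    """
    s = _as_sample(sample)
    v = s.values
    if v.shape[1] == 1:
        z = v[:, 0]
    elif mode == "pca":
        vc = v - v.mean(axis=0, keepdims=True)
        # top right singular vector of the centred matrix
        _, _, vt = np.linalg.svd(vc, full_matrices=False)
        z = vc @ vt[0]
    elif mode == "mean":
        z = v.mean(axis=1)
    else:
        raise ValueError(f"unknown discretisation mode {mode!r}")
    lo, hi = z.min(), z.max()
    if hi == lo:
        return np.zeros(z.shape[0], dtype=np.int64)
    edges = np.linspace(lo, hi, bins + 1)
    codes = np.searchsorted(edges, z, side="right") - 1
    return np.clip(codes, 0, bins - 1).astype(np.int64)


def _entropy_of_codes(codes: np.ndarray) -> float:
    counts = np.bincount(codes)
    p = counts[counts > 0] / codes.size
    # summing in sorted order makes the estimate independent of code
    # labelling, so I(X;Y) == I(Y;X) holds exactly in float arithmetic
    return float(-(np.sort(p * np.log2(p))).sum())


def estimate_entropy(sample, bins: int = 64, mode: str = "pca") -> float:
    """Plug-in entropy (bits) of the discretised feature distribution."""
    s = _as_sample(sample)
    if s.values.shape[0] < bins:
        raise ValueError(f"need N >= bins ({s.values.shape[0]} < {bins})")
    return _entropy_of_codes(discretize(s, bins, mode))


def mutual_information(x, y, bins: int = 64, mode: str = "pca") -> float:
    """I(X;Y) = H(X) + H(Y) - H(X,Y) in bits, shared discretisation."""
    xs, ys = _as_sample(x), _as_sample(y)
    if xs.values.shape[0] != ys.values.shape[0]:
        raise ValueError("X and Y must pair the same N samples")
    cx = discretize(xs, bins, mode)
    cy = discretize(ys, bins, mode)
    hx = _entropy_of_codes(cx)
    hy = _entropy_of_codes(cy)
    hxy = _entropy_of_codes(cx * bins + cy)
    return hx + hy - hxy


@dataclass
class SynergyReport:
    H_X: float
    H_Y: float
    H_XY: float
    I_XY: float
    bound: float                  # H(X)+H(Y)-max(H(X),H(Y))
    criterion_satisfied: bool
    redundancy_flag: bool
    independence_flag: bool
    bins: int
    mode: str

    def to_dict(self) -> dict:
        return asdict(self)


def synergy_report(x, y, bins: int = 64, mode: str = "pca",
                   independence_fraction: float = 0.1,
                   eps: float = 1e-9) -> SynergyReport:
    """Evaluate the fusion-synergy criterion on paired branch features.

    ``redundancy_flag`` is set when I exceeds the bound (beyond estimator
    slack); ``independence_flag`` when I falls below
    ``independence_fraction`` of the bound, i.e. the branches are barely
    coupled.
    """
    xs, ys = _as_sample(x), _as_sample(y)
    cx = discretize(xs, bins, mode)
    cy = discretize(ys, bins, mode)
    hx = _entropy_of_codes(cx)
    hy = _entropy_of_codes(cy)
    hxy = _entropy_of_codes(cx * bins + cy)
    i_xy = hx + hy - hxy
    bound = hx + hy - max(hx, hy)
    return SynergyReport(
        H_X=hx, H_Y=hy, H_XY=hxy, I_XY=i_xy, bound=bound,
        criterion_satisfied=bool(i_xy <= bound + eps),
        redundancy_flag=bool(i_xy > bound + eps),
        independence_flag=bool(i_xy < independence_fraction * bound),
        bins=bins, mode=mode)
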