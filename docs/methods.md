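# Methods

This note records the model, the choices made where the design was
genuinely open, the numerical conventions, and what the tests do and do
not establish.

## Image enhancement

**Model.** Acetowhite change is primarily a *chroma* signal: low-grade
lesions are faint pink-white patches on pink epithelium. Global or
luminance contrast enhancement deepens texture everywhere and confounds
grading, so the pipeline equalises chroma instead. The image is decomposed
into Lab and YCrCb; L and Y get standard CLAHE; A, B, Cr and Cb get the
locally truncated variant (LT-CLAHE). Both equalised images are converted
back to RGB before the 50/50 blend — averaging raw values across two
different color spaces would be meaningless.

**LT-CLAHE.** Per tile of `M` pixels over `L` gray levels, the clip limit
is `M/L + (M − M/L)/normClipLimit`. Clipped mass is re-allocated only to
the receiving range `x < D`, `D = ⌊2L/3⌋` (the bound is a bin *count*,
matching the `totalE/D` average-increment definition). The integer
redistribution contract: clip every bin to `⌊clipLimit⌋`, then sweep the
receiving bins in ascending order adding `max(1, ⌊excess/D⌋)` per bin,
never beyond the cap, until the excess is exhausted; if every receiving
bin saturates (possible only under extreme clip settings) the remainder is
spread evenly over the receiving bins with the cap waived, so pixel-count
conservation and truncation locality always hold exactly. Equalisation
uses `f(x) = round((L−1)·cdf(x)/M)`; output pixels blend the four
neighbouring tile transfer functions bilinearly with tile-centre anchors
and clamped edge weights. Standard CLAHE is the same procedure with
`D = L`, and the two are pixel-identical in that limit (tested against an
independently coded textbook implementation).

**Parameters.** Tile grid 8×8 (standard CLAHE practice) and
`normClipLimit = 4.0` for both luminance and chroma by default; the chroma
value is configurable separately (`enhancement.norm_clip_chroma`) because
chroma histograms are much narrower than luminance ones. Preconditions
require `M ≥ L` (at least one pixel per gray level per tile). Color
conversions use 8-bit full-range conventions (Lab via D65 with L scaled to
0–255 and a/b offset by 128; YCrCb via BT.601 full-range); grayscale is
BT.601 luma (0.299, 0.587, 0.114).

## Network

Two four-stage branches at matched resolutions (stride-4 stem, then three
stride-2 downsamplings: 56/28/14/7 at 224×224) and matched dims
C·(1,2,4,8) with C=32.

*Transformer branch* — Swin-style blocks: pre-norm attention + MLP (ratio
4), relative position bias, shifted windows of size 7, patch merging
between stages. Every stage hosts one core pair: a shifted-window
attention module followed by the fusion attention module; the depth-6
stage wraps that pair with one plain Swin block (W-MSA + SW-MSA) before
and after, the only arrangement consistent with depths (2,2,6,2). Head
counts: the printed pairing (3,6,12,24) cannot divide the stage dims that
C=32 produces, so heads default to (2,4,8,16), keeping a head dim of 16;
any explicit pairing can be configured when the chosen C allows it.

*CNN branch* — HMSPE blocks: a 1×1 projection, four-way channel split,
residual expand/compress conv blocks at three scales (5×5, 3×3, and 3×3
with dilation rate 2, whose two-fold stacking covers a 9×9 field), with
Res2Net-style progressive cross-feeding (`f5×5(x2) + f3×3(x3)` feeds the
deeper dilated paths), four pixel-excitation gates, and output
`Concat(y1+y2, y3+y4) + x`. The pixel-excitation module (PEM) is a 1×1
bottleneck (equal hidden width) producing a sigmoid gate multiplied onto
its input, followed by LayerNorm — the minimal structure consistent with
per-pixel excitation. Stages 2 and 3 end with a widening HMSPE block
(1×1 doubling, HMSPE at the doubled width, squeeze-excitation with
reduction 16, 1×1 alignment back to the stage dim).

*Fusion.* Both injections happen mid-stage so the received features
undergo roughly half the stage's remaining computation ("moderate
disadvantage"): the fusion attention consumes the first HMSPE's output
after an adaptive `LN(MLP(y))` preprocessing; the CNN fusion consumes the
tokens leaving the shifted-window module, preprocessed by a 3×3 conv to
1.5C, GELU, and a 1×1 conv back to C, then concatenated and mixed by an
inverted bottleneck (1×1 to 4C, GELU, SE, 1×1 to C) and a two-group
channel shuffle. In the fusion attention the CNN-side q/k/v are pure
products with the shared projection weights (no bias term), so a zero CNN
input reduces it exactly to plain window attention.

*Adaptive MLP width.* The preprocessing MLP's hidden expansion is the one
interior width the block equations leave open. We set it to 2 (between
the gate's ratio 1 and the transformer MLP's ratio 4): with this choice
the assembled model totals 12.52 M trainable parameters, matching the
~12.5 M design budget of the architecture; ratio 1 gives 12.34 M. The
knob is exposed as `adaptive_mlp_ratio`.

*Classifier head.* Global average pool of both final-stage feature maps,
concatenation (512 dims), LayerNorm, linear to the class count.

*Measured constants.* At the default configuration the model has
12.5176 M trainable parameters and a forward cost of 1.644 G
multiply-accumulates for one 224×224 input pair, counting conv, linear
and attention matmuls (the convention of standard profilers; elementwise
ops, under 0.01 G elements total, are not counted).

*Initialisation and optimisation.* Truncated normal (std 0.02) for all
conv/linear weights, zeros for biases, unit/zero norm affines; AdamW
(lr 1e-3, decoupled weight decay 0.05 applied to matrices only) with
cosine decay to 1e-5 and drop-path up to 0.1; cross-entropy loss. These
follow the conventions of the model families the branches emulate; they
are package defaults, not published settings.

## Numerical core

The network runs on a compact reverse-mode autodiff engine over float32
numpy arrays (`hmcformer.nn`): convolution via im2col with slice-gathered
patches (both passes are BLAS matmuls), fused softmax/layernorm/
cross-entropy with analytic backward rules, window partition/roll/pad as
indexed views with exact adjoints. Gradients of every primitive are
checked against central finite differences in the test suite. Determinism:
identical seeds give bit-identical weights, forward passes and training
histories (per-epoch RNGs are derived from `seed` and the epoch index, so
a resumed run continues the exact schedule).

## Mutual-information diagnostics

Branch features (pooled end-of-stage-3 vectors) are reduced to scalars —
top principal direction by default, per-sample mean as the simpler
variant — and binned on an equal-width grid (default 64 bins; joint
entropy uses the product grid, making `I(X;X) = H(X)` exact and I
symmetric by construction; entropy sums run in sorted order so symmetry
holds exactly in float arithmetic). Entropies are in bits. The synergy
criterion `I ≤ H(X) + H(Y) − max(H(X), H(Y))` is evaluated with slack
1e-9; an estimate far below the bound (default: under 10% of it) sets the
independence flag, above it the redundancy flag. Plug-in MI is biased
upward by roughly `(k_x−1)(k_y−1)/(2N ln 2)`; at N = 10⁴ use ≤16 bins per
axis if near-zero MI must be resolved below 0.05 bits. kNN/KSG estimators
are out of scope.

## Synthetic data

Each image (256×256 RGB, 8-bit) renders a pink elliptical cervix with
radial shading and speckle, a darker central os, an illumination gradient,
and sensor noise; CIN classes add acetowhite patches controlled by
`whiteness` (overlay opacity), `extent` (fraction of cervix area, realised
by thresholding a smoothed noise field at the matching quantile, accurate
to ±0.03), `roughness` (texture-noise amplitude) and boundary sharpness.
Class defaults rise monotonically from CIN1 (0.35/0.12/0.10) to CIN3
(0.85/0.50/0.45), mirroring the clinical ladder from faint focal change to
extensive coarse yellow-white plaques. Generation is bit-deterministic
under the seed. Binary, 3-class (normal / CIN1 / CIN2+3) and 4-class
labelings all derive from the 4-class label.

What this does *not* emulate: real colposcopy optics (specular glare,
mucus, speculum), anatomical variability, inter-observer label noise, or
the subtlety of real CIN1-vs-normal boundaries. Passing the training
smoke tests shows the architecture, enhancement and pipeline are wired
correctly and can fit a cleanly separable signal — it says nothing about
clinical accuracy.

## Pipeline

Five-fold cross-validation: folds from a seeded (optionally stratified)
permutation; in rotation i, fold i tests, fold i+1 validates, the rest
train; fold reports are averaged unweighted. Augmentation: resize to
260×260, random 224×224 crop, rotation U(−15°, 15°), horizontal flip
p=0.5, normalisation (ImageNet statistics for RGB, 0.5/0.5 for gray); the
*same* geometric draw is applied to the raw-RGB and enhanced-gray inputs
of a sample — anything else would destroy the spatial correspondence the
fusion relies on. The evaluation path is resize + centre crop.

Metrics are computed twice in the test suite — once by the library's
closed-form expressions, once by brute force from raw prediction arrays
(plus scikit-learn cross-checks) — and must agree exactly. AUC counts
tied pairs as 1/2 (Mann–Whitney convention). One F1 is reported, with
recall exposed separately (recall = sensitivity). Degenerate denominators
(empty classes) yield 0 rather than NaN. Multi-class kappa is standard
Cohen's kappa from the full confusion matrix.

**Desk-scale problem sizes.** The compact profile (C=16, depths
(2,2,2,2)/(1,1,1,1), 112×112 inputs, batch 8, 5 epochs, 40 images per
class) is the package's chosen configuration for CPU-scale runs and the
end-to-end tests; the full-size settings (C=32, 224×224, batch 24,
300 epochs) remain available via `ModelConfig()`/`TrainConfig()`.

## Known limitations

- The NN core is single-CPU float32; no mixed precision, no
  multi-threaded data loading, no GPU path.
- The clip-limit precondition `M ≥ L` rules out tiles smaller than the
  gray-level count; choose the grid accordingly for small images.
- LT-CLAHE's cap waiver under extreme clip settings trades the clipping
  ceiling for exact conservation and locality; with the default
  `normClipLimit = 4` the ceiling always holds.
- The MI diagnostics use scalar projections of the feature vectors;
  high-dimensional structure orthogonal to the top principal direction is
  invisible to them.
- Training on real colposcopy data (and any clinical claim) requires the
  full-size profile, real datasets and external validation — all outside
  what the bundled synthetic data can support.
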