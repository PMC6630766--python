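# Methods

## Problem and model

The package segments the two paraspinal muscle groups — multifidus (MF)
and erector spinae (ES) — in 2-D axial T2-weighted lumbar MR slices and
derives the bilateral cross-sectional area (CSA) of each. Segmentation is
per-pixel binary classification by an encoder–decoder network; one
single-output model is trained per muscle (MF and ES results are reported
separately, matching how clinical tables present them). A joint two-channel
configuration exists (`out_channels=2`) but is not the default path.

**Encoder.** ResNet-18 layout with quarter widths: a full-resolution stem
convolution (no stem pooling) followed by four stages of two residual
blocks, the first block of each stage at stride 2. Four downsamplings give
a bottleneck of 1/16 the input side — for the clinical 512 px resolution,
32 px. A classical ResNet-18 downsamples 32×; dropping the stem stride and
pool is the only layout consistent with both "ResNet-18 structure" and a
1/16 bottleneck. Residual blocks are `y = ReLU(F(x) + s(x))` with `F` =
conv3×3 → ReLU → conv3×3 and `s` the identity, or a stride-matched 1×1
projection when shape changes. Batch normalisation follows every
convolution (toggleable, `norm="none"` gives the bare formulation);
convolutions carry biases only when normalisation is off.

**FPA bottleneck.** Five parts: (i) main branch, 1×1 convolution of the
bottleneck features; (ii–iv) a pyramid of 7×7 / 5×5 / 3×3 convolution
levels at 1/2, 1/4, 1/8 of the bottleneck side — two convolutions per
level (one strided entering the level, one before fusion), following the
established pyramid-attention design — fused bottom-up by bilinear
upsample-and-add, then upsampled to the bottleneck size and multiplied
elementwise into the main branch; (v) a global-average-pool → 1×1 conv
branch broadcast-added to the product. The pyramid needs three halvings,
so the FPA path requires a bottleneck of ≥ 8 px (input ≥ 128 px).

**Decoder.** Four stages of bilinear 2× upsampling, concatenation with the
same-resolution encoder map, and one block (residual or double-conv,
matching the encoder's flavour), then 1×1 convolution + sigmoid.

Variants: `(use_residual, use_fpa)` = (F, F) quarter-width U-Net baseline,
(T, F) ResU-Net, (T, T) the full model. The default full model counts
3 672 481 trainable parameters, under the 5 M budget; a published figure
of 2.53 M for the channel-reduced variant is consistent with a single
convolution per FPA level (≈2.6 M here), so the discrepancy between the
two printed figures likely reflects that choice — the ≤ 5 M bound is the
tested contract, and widths are fully configurable.

## Numerical core

No autodiff framework is part of the dependency footprint; `paraseg.nn`
implements a compact reverse-mode tape on numpy arrays with exactly the
operations the model needs. Convolution uses im2col + BLAS matmul, with
the gradient assembled by the adjoint scatter; bilinear resizing is a pair
of dense 1-D interpolation matrices (half-pixel-centre convention, edges
clamped), making its backward pass the exact adjoint; batch normalisation
uses batch statistics in training and exponential running averages
(momentum 0.1, unbiased variance) at inference. All kernels are verified
against scipy and central finite differences in the test suite. Weights
are float32; the logistic is evaluated in its numerically stable split
form.

## Training protocol

SGD with classical momentum 0.9 (`v ← μv − lr·g; w ← w + v`), initial
learning rate 0.1, closed-form per-epoch decay
`lr(e) = lr0 / (1 + (lr0/epochs)·e)` — the conventional reading of the
iterative Keras decay expression, and numerically indistinguishable from
it at `decay = 0.1/60`. Xavier-uniform initialisation, batch size 4, loss
the negative soft Dice averaged per sample over the batch with
`ε = 1e−6` in the denominator so empty masks are defined. After each epoch
the model is scored on the held-out fold by mean DSC at threshold 0.5; the
best-scoring epoch's weights are the returned checkpoint. Selection on the
held-out fold mirrors the original protocol (which itself notes the bias
this introduces); passing a separate validation set to `train_fold` gives
the unbiased variant. Best-by-DSC rather than best-by-loss is a deliberate
choice: DSC is the headline metric. Cross-validation shuffles identifiers
once (seeded), partitions them into near-equal folds (remainder to the
first folds; 1080 ids / 5 folds = 216 per test fold), and averages fold
results. No augmentation, no post-processing.

## Phantom generator

The generator emulates the three stated difficulties of paraspinal MR
segmentation, each behind a knob:

* `boundary_fuzz_sigma` (px, default 1.5) — Gaussian blur of the rendered
  intensities (never the masks); 0 gives crisp edges.
* `intensity_overlap` (default 0.35) — the target/background mean
  separation is `0.05 + 0.40·(1−overlap)` in normalised gray units and the
  per-pixel noise SD is `0.03 + 0.05·overlap`, so the Bhattacharyya
  coefficient between target and background histograms rises monotonically
  with the knob.
* `shape_variability` (default 0.25) — scales a low-order Fourier radial
  modulation of each blob boundary (clipped at ±35%) plus placement and
  size jitter.

Geometry: a bright central blob (spinous-process surrogate, mean gray
0.95), a bilateral MF-like pair adjacent to it and a more lateral ES-like
pair (background mean 0.35), on a smooth low-frequency background field.
Distinct structures keep a ≥ 2 px carved gap — the fascia-like boundary —
so apparent merging is produced only by the difficulty knobs; blob
placement guarantees `border_margin` (default 8 px) clearance from the
image edge and area fractions within (0.01, 0.4) by bounded rejection.
Default pixel spacing is 0.7 mm/px, a plausible lumbar in-plane
resolution chosen once and always carried in the manifest; physical-area
checks are property-based (conservation, identity agreement) rather than
anchored to clinical area values.

What passing tests on phantoms do **not** show: performance on real
anatomy (no fat infiltration texture, no neighbouring organs, no coil
inhomogeneity, elliptical rather than anatomical shapes). The phantoms
validate the machinery — losses, optimisation, metrics, measurement — not
clinical accuracy; published clinical figures (MF DSC ≈ 0.95, ES ≈ 0.91)
require the original hospital dataset, which is not distributable.

## Evaluation and measurement conventions

* DSC(∅, ∅) = 1; Hausdorff distance is NaN when either mask is empty; a
  rate with zero denominator is NaN and excluded from aggregation (with a
  warning).
* Sensitivity is TP/(TP+FN); the misprinted TP/(TP+TN) variant is
  available behind `printed_eq_compat=True` for audit only.
* Hausdorff distance runs over 8-connectivity boundary pixels (erosion
  difference) with an exact Euclidean distance transform, scaled to mm.
* Aggregates use the sample standard deviation (ddof = 1).
* Both sides of a muscle are evaluated and measured as one united mask
  ("bilateral total CSA").
* CSA binarisation threshold defaults to 0.5; `A = F·(w·L)²` assumes a
  square map (non-square inputs are rejected; resize first). Bland–Altman
  differences are automatic − manual with limits at mean ± 1.96 sample SD.
* Preprocessing defaults: min–max contrast normalisation (parameter-free
  and idempotent; CLAHE optional), bilinear image / nearest-neighbour mask
  interpolation (preserves binarity), spacing rescaled per axis to
  conserve the field of view. Blur exclusion (variance of Laplacian) is
  off by default — the underlying clinical criterion was manual.

## Problem sizes used in the checks

Architecture contracts are exercised at the clinical 512 px resolution
(forward only). Optimisation checks run on 48 px phantoms (ResU-Net
variant, below the FPA minimum) for seconds-scale feedback, and the
end-to-end convergence check trains the full model for 15 epochs on 40
easy phantoms at 128 px — about two minutes on one CPU core — reaching
held-out mean DSC ≥ 0.85 (typically ≈ 1.0 by epoch 10). Full 512 px /
60-epoch training is configuration, not test surface.

## Known limitations

* CPU-only numpy kernels: a 512 px forward pass takes seconds, so
  full-resolution training is slow; the architecture is
  resolution-agnostic and desk-scale runs use 128 px.
* Best-model selection on the test fold inflates fold scores (documented
  deviation hook: pass an explicit validation set).
* The phantom generator's realism limits, above.
* Single-slice 2-D only; no 3-D context, no fat-infiltration
  quantification.
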