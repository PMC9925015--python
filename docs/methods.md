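# Methods

`eyespot` implements a two-stage pipeline for quantifying circular color
pattern elements on butterfly wings: (1) an anchor-based single-stage
detector localizes spots and eyespots in a wing image and assigns a class;
(2) each detected eyespot is cropped, resized, segmented by a U-Net into
*center* and *surrounding rings*, and the two region areas are counted in
pixels and converted to mm².  A synthetic scene generator with exact
ground truth makes every stage trainable and testable end to end on one
CPU.

## Synthetic data model

The generator emulates two kinds of inputs.

**Scenes** are H×W RGB images (default 256×256) of a wing-like background
with `n_elements` pattern elements placed without overlap (rejection
sampling with a bounded retry count; exceeding it raises an explicit
error).  The background is a brownish base color plus low-frequency
Gaussian-smoothed noise (`texture_amplitude`, default 0.15) and a few
dark vein-like curves, emulating the low-contrast wing surface that makes
real detection hard.  Elements are:

* *spots* — a single elliptical patch of one color;
* *eyespots* — three concentric regions: white center (radius `r_c`),
  black disc (`r_b`), orange outer ring (`r_o`), with `r_c < r_b < r_o`.
  A fraction `p_marginal` (default 0.88, the relative abundance typical
  of real collections) is labelled *marginal*, the rest *discal*.

Ellipses have eccentricity up to 0.25 (minor axis = r·(1−ecc)) and a
random orientation.  `contrast` ∈ [0, 1] linearly blends element colors
with the local background (default 0.7); per-element color jitter and
per-pixel Gaussian noise (σ = 0.01) complete the scene.

**Rasterization rule.** A pixel belongs to a region iff its integer
center lies inside the ellipse.  True areas are therefore exact pixel
counts of the rendered masks, the recorded box is the tight hull of the
nonzero mask, and mask/area/box consistency holds by construction, not
within a tolerance.  Overlap (when explicitly allowed) is resolved by an
ownership map — the later element wins the pixel — so per-element masks
stay disjoint.

**Crops** hold exactly one centered eyespot.  The crop side is
`2·round(margin·r_o) + 1`, so `margin = 1` makes the outer ring tangent
to the border; the default margin 1.25 leaves room as a detector-box crop
would.  The three-class mask uses labels 0 = background, 1 = rings
(black + orange combined), 2 = center — the same encoding everywhere in
the package.

What the generator does *not* model: wing shape and venation geometry,
scale texture, specular lighting, focus blur, inter-species pattern
diversity, and eyespot asymmetries beyond eccentric ellipses.  Passing
synthetic tests therefore demonstrates that the pipeline's machinery
(training, matching, morphology, calibration, bookkeeping) is correct
and recovers known areas under realistic contrast and size ranges — not
that the trained weights transfer to photographs.

## Detection stage

A reference mini-detector stands in for production single-stage
detectors: a strided convolution trunk (one stride-2 block per factor of
two in the configured feature stride; at the default stride 16 that is
four blocks of widths 16/32/64/96, BatchNorm + ReLU) with one 3×3
classification head and one 3×3 box-regression head on a single feature
level.  Anchors are laid on the feature grid (default square scales
12/17/24/34/48 px, matched to the generator's element size range).
Matching follows the usual single-stage convention: positive at IoU ≥ 0.5,
negative below 0.4, ignored in between, and every ground-truth box
force-matches its best anchor.  Classification uses the focal loss
(α = 0.25, γ = 2; per-class sigmoid) normalized by the number of positive
anchors; box offsets (normalized center shift, log size ratio) use
smooth-L1.  Class-head biases start at −2.2 so the initial foreground
probability is ≈ 0.1, the standard focal-loss prior.

Training follows the shared protocol: Adam (lr 1e-4, β₁ 0.9, β₂ 0.9999),
batch 8, at most 100 epochs with early stopping after 10 epochs without
validation improvement, inputs scaled to [0, 1].  Online augmentation
applies HSV jitter (hue ± 0.03, saturation/value × [0.8, 1.2]) and
horizontal flips with probability 0.5 (`x' = W − x` applied to both ends
of the box).  Images whose size differs from the model input are
letterboxed (aspect-preserving resize onto a gray canvas) and boxes are
mapped through the inverse transform on output.

Duplicate removal is class-wise greedy NMS: keep by descending score,
suppress at IoU > 0.3 with a kept box of the same class.  The 0.3
threshold reflects that distinct elements overlap only slightly.

Three class schemes are supported — spot vs eyespot (`two_class`), any
element (`one_class_all`), marginal eyespots only (`one_class_marginal`)
— chosen at training time; the scheme is stored in the checkpoint.

## Measurement stage

The segmenter is a reduced U-Net: encoder blocks of two 3×3
convolutions (BatchNorm/ReLU) with 2×2 max pooling; decoder stages of
1×1 channel reduction, 2× nearest-neighbor upsampling, skip
concatenation and one 3×3 convolution; 1×1 softmax head.  Default depth
4, base width 16 (~1.6 M parameters), "same" padding so the output mask
matches the input size.  Crops are resized bilinearly to 128×128
(whole-wing mode: 640×640); masks use nearest neighbor so label sets are
preserved exactly.

Loss is categorical cross-entropy over per-pixel softmax, optionally
weighted per class (WCCE) because the center is tiny compared with rings
and background.  Default weights in label order (background, rings,
center): crops (1, 1.75) two-class and (1, 2, 25) three-class; whole-wing
(1, 50) and (1, 600, 25).  Probabilities are clipped at ε = 1e-7;
prediction is per-pixel argmax with ties broken toward the lower label.
The two-class mode uses a 2-way softmax rather than a sigmoid for
uniformity with the three-class head.

**Center isolation (two-class path).** The rings mask is inverted and
every 8-connected component of the inverse touching the crop boundary is
removed; the remaining components are enclosed by rings and form the
center.  All enclosed components are kept (a warning is logged when
there is more than one); a ring broken wide enough to leak to the border
yields an empty center, logged, never an exception.

**Areas.** Segmented masks are resized back to the crop's native side
(nearest neighbor), border-replicated padding is zeroed out, pixels are
counted, and mm² = px / `px_per_mm`², with `px_per_mm` = 28.944 by
default (1 mm = 28.944 px).  Total = center + rings holds exactly in
pixels and to float precision in mm².  The whole-wing baseline segments
the full image and splits eyespots by 8-connected component labelling of
rings ∪ center; a component without center pixels is measured with
center 0 and a warning.

## Evaluation

Detection: greedy score-descending matching per image (a detection is a
true positive iff IoU with an unmatched same-class ground-truth box is ≥
the threshold, boundary inclusive; duplicates of a matched object are
false positives).  AP integrates the precision-envelope over all recall
breakpoints (all-point interpolation, no 11/101-point approximation),
averaged over IoU thresholds 0.50:0.05:0.95; mAP averages classes
unweighted.  `precision(0, 0)` is defined as 1 so an empty detector
output gives a well-defined PR start point.  Classes without ground
truth are excluded from mAP with a warning.

Segmentation: pixel accuracy, macro-F1 and mean IoU from the pixel
confusion matrix; a class absent from both masks scores 1 (so identical
masks always give exactly (1, 1, 1)).

Area agreement: per-pair absolute error |auto − manual| and relative
error 100·|auto − manual|/manual, reported as mean and population
standard deviation (a `sample_std` flag switches to n−1); the standard
deviation of *signed* relative errors is reported alongside since either
convention is defensible.

## Numerical and design choices

* **numpy NN core.** Both networks run on a small self-contained numpy
  engine: im2col convolutions backed by BLAS matmul in channel-first
  (C, N, H, W) layout (contiguous per-tap writes; reused buffers avoid
  page-fault churn), BatchNorm, ReLU, 2×2 max pool (first-maximum
  tie-break), nearest upsampling, Adam, float32 throughout.  Gradients
  are verified against finite differences in float64 in the test suite.
  Single-threaded runs are bit-deterministic given the config seeds.
* **Coordinates.** 0-based, half-open boxes everywhere; only the Pascal
  VOC layer converts to that format's 1-based inclusive indices.
* **Splits.** Deterministic shuffles; fractional splits floor every part
  except the last, which takes the remainder (so (0.8, 0.2) of 125 gives
  100/25); explicit counts (e.g. 101/24) are supported for protocol
  fidelity.
* **Early stopping** restores the best-validation weights; with no
  validation set it is disabled with a warning.
* **Problem sizes.** Test and acceptance runs use desk-scale sizes
  chosen for single-CPU turnaround: 125 crops split 101/24 with the
  128×128, base-16 U-Net, and a few hundred 256×256 scenes for the
  detector; training lengths are capped well below the 100-epoch default
  where validation loss has already plateaued at these scales.

## Known limitations

* The detector is a single-level reference implementation; it is not a
  reproduction of any production architecture and its absolute accuracy
  on photographs is untested.
* Synthetic realism limits (above) mean transfer claims require real
  annotated images.
* `one_class_marginal` trained from VOC XML (CLI path) cannot recover
  the marginal/discal distinction because the XML vocabulary does not
  carry subtypes; the Python API keeps subtypes in `ElementSpec`.
* Per-ring (black vs orange separately) measurement is out of scope; the
  rings class merges both, matching the measurement definition.
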