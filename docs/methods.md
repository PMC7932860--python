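# Methods

## Problem

Lymphocyte vacuolization — round pale clearings in the cytoplasm of
lymphocytes on a stained peripheral blood smear — is a morphological hallmark
of CLN3 (Batten) disease and correlates with disease severity. Manual
quantification (the fraction of lymphocytes showing evident vacuoles) is
labor-intensive and subjective enough that laboratories average two
independent readers. `vacuoquant` implements an automated two-stage
deep-learning pipeline for this quantification, together with the
method-comparison statistics used to validate an automated method against
manual readers, and a synthetic stained-cell image generator so the entire
pipeline can be trained, validated and exercised without patient material.

## Pipeline

Per single-cell crop (one centered leukocyte, RGB):

1. **Cytoplasm segmentation.** Two independent single-target U-Net models
   predict the whole-cell mask and the nucleus mask. The cytoplasm mask is
   their difference (cell AND NOT nucleus), and everything outside it is
   blacked out. Training minimizes 1 − soft dice with Adam; masks are
   binarized at probability 0.5 (a symmetric default). Quality is scored by
   the dice coefficient, 2·|A∩B| / (|A|+|B|).
2. **Vacuolization classification.** A reduced residual CNN
   (conv-BN-ReLU stem, three stages of identity residual blocks with pooling
   transitions, global average pooling) ends in a 2-neuron softmax giving
   P(vacuolated) vs P(healthy). A cell is called vacuolated when
   P(vacuolated) ≥ τ with τ = 0.65, inclusive; τ is a configuration
   constant, never fitted.
3. **Smear aggregation.** percent_vacuolated = 100 · n_vacuolated /
   (n_total − n_excluded). Cells whose predicted cell or cytoplasm mask is
   empty are excluded from the denominator and reported; a failed mask
   yields no cytoplasm to classify, and silent dropping would hide
   segmentation failures. Per-cell probabilities are persisted so the
   threshold can be re-applied without re-inference.

Grad-CAM provides interpretability: gradients of the target-class logit are
average-pooled over the final stage's feature maps to weight them; the
rectified weighted sum is upsampled to input resolution and normalized to
[0, 1] (an identically zero raw map is returned as zeros).

### Network engine

The networks run on a compact reverse-mode autodiff engine written on numpy
(`vacuoquant.nn`): stride-1 same-padded convolution via sliding-window
tensordot (BLAS-bound), 2×2 max pooling, nearest-neighbor upsampling,
channel concatenation, batch normalization with running statistics, soft-dice
and softmax cross-entropy losses, and Adam. Every differentiable op is
verified against central finite differences in the test suite. All
computation is CPU-only, float32, and deterministic given the seed.

Architecture scale is deliberately small for desk-scale training: U-Net
depth 3 with 16 base filters; classifier with three stages of two residual
blocks each (16/32/64 channels). Batch normalization is load-bearing in the
classifier: the vacuolization signal occupies a few bright pixels of a
mostly blacked-out image, and without normalization the signal does not
survive global average pooling (training stalls at chance). The second BN of
each residual block starts at γ = 0 so blocks begin as identities. The
classifier uses a stepped learning-rate schedule (×0.1 at 50% and 80% of the
epoch budget) and keeps the best-validation-accuracy checkpoint, so extra
epochs never degrade the reported model.

## Synthetic data

The generator emulates May-Grünwald-Giemsa-stained lymphocyte crops from a
digital morphology analyzer: a radially perturbed disc cell (low-order
harmonic boundary perturbation, amplitude 8%) on a pale background, a dark
purple nucleus occupying 45–62% of the cell area and clipped to the 1-px
eroded cell so a cytoplasm rim always exists, and — in vacuolated cells —
1–4 bright round clearings strictly inside the cytoplasm. Vacuole placement
uses the exact Euclidean distance transform: a disc fits at a center iff its
radius is below the distance to the cytoplasm boundary; a radius that
nowhere fits shrinks in 0.5-px steps, and as a last resort the deepest
cytoplasm point receives the largest disc that fits, so a vacuolated cell
always carries the most evident clearing its geometry allows. Rendering is
one mean RGB color per compartment with small per-cell jitter, Gaussian blur
(σ = 0.6 px) for soft edges, and additive Gaussian pixel noise (SD 0.02).
Defaults describe a 128-px crop (the source imaging hardware's crop size is
not standardized); `SyntheticParams.for_image_size` rescales the geometry,
and all training and validation in this package run at 64 px to keep CPU
training in minutes.

One global seed expands to per-smear and per-cell seeds through a fixed
counter scheme, so datasets are bit-identical under regeneration, including
partial regeneration.

What the generator does **not** emulate: stain texture and granularity,
illumination gradients, touching or overlapping cells, non-lymphocyte
morphologies, imaging artifacts. Passing tests therefore demonstrate that
the pipeline machinery (training, masking, thresholding, aggregation,
statistics) is correct and recovers known ground truth under realistic
geometry and contrast — not that the trained weights transfer to real
smears.

A deliberate property of the palette: vacuole interiors are nearly the same
color as the slide background, as they are under a Romanowsky stain. This
makes cytoplasm segmentation quality load-bearing: if the predicted cell
boundary leaks background pixels into the cytoplasm, they mimic vacuoles.
With the default training budget (18 epochs) the cell model reaches dice
≈ 0.99 and residual leakage (~4 bright px/cell) stays well below the
smallest vacuole signal. Training the classifier on predicted rather than
ground-truth cytoplasm masks was evaluated as an alternative and rejected:
it exposes the classifier to a boundary-arc vs vacuole-disc ambiguity that
costs more accuracy than it saves (the utility remains available as
`segmentation.mask_with_predicted_cytoplasm`).

## Augmentation

Training sets can be expanded by a fixed factor with five families of random
geometric transforms — rotation (±30°), shift (±10% of the side), shear
(±10°), zoom (0.9–1.1), horizontal/vertical flips — applied jointly to the
image (bilinear) and its masks (nearest-neighbor, so masks stay binary and
subset relations survive). The output is `factor` transformed copies per
original; originals are not separately included. The magnitudes are mild so
the whole cell stays in frame; out-of-frame regions are filled with the
image's border-median color. Splitting happens **before** augmentation in
any workflow here, so augmented copies of one original never straddle the
train/validation boundary. The full synthetic workflow leaves augmentation
off by default (the generator can produce unlimited fresh examples);
augmentation matters for fixed, hand-annotated datasets.

## Method comparison

Automated percentages are validated against a manual consensus (per-smear
mean of two readers) with:

* **Passing-Bablok regression**, computed from first principles: slope =
  shifted median of all pairwise slopes (slopes equal to −1 excluded, median
  index offset by the count of slopes < −1, even counts averaging the two
  middle order statistics after the shift); intercept = median of
  y − slope·x. The automated method is y, the reference x. CIs are seeded
  percentile bootstrap over resampled pairs, 999 resamples by default.
  Analytical CIs are intentionally not provided.
* **Bland-Altman**: mean difference (automated − manual), sample SD (n−1),
  limits of agreement at ±1.96 SD; also computed between the two manual
  readers.
* **Pearson r** from the product-moment formula.
* **Levene's test** on the three paired-difference groups (auto−manual1,
  auto−manual2, manual1−manual2), classic mean-centered absolute deviations,
  p-value from the F distribution (the only scipy dependency in this
  module). Median centering (Brown-Forsythe) is available as an option.

Degenerate inputs (constant consensus, zero within-group spread, all-equal
x) raise distinct errors, and `compare_methods` converts them to explicit
report flags so full-agreement edge cases surface instead of producing
numbers. In the end-to-end synthetic workflow the two manual readers are
simulated as ground truth plus independent Gaussian error of SD 2 percentage
points per reader.

## Study conditions and problem sizes

The package's validation study (test suite and `scripts/acceptance.py`)
runs at: 64-px crops; 200 cells (50% vacuolated) for each segmenter with an
80/20 split; 1200 balanced ground-truth-masked cells for the classifier
(80/20 split, 21 epochs); 8 smears of 30 cells spanning vacuolated fractions
0–0.7 for the pipeline comparison, τ = 0.65, Passing-Bablok with 999
bootstrap resamples. These sizes train in minutes on one CPU while leaving
the tasks non-trivial.

## Known limitations

* Residual under-calling of 1–2 cells per high-fraction smear: vacuoles at
  the 9-px minimum are borderline by construction (P(vacuolated) ≈ 0.6 even
  with perfect masks — the synthetic analogue of cells on which human
  readers would disagree), and a predicted nucleus boundary occasionally
  shaves pixels off an adjacent vacuole. The resulting Passing-Bablok slope
  is typically 0.93–1.08 depending on seed.
* The dice coefficient is undefined when both masks are empty; this raises
  an error by design rather than defining 0/0, because an empty predicted
  mask is a segmentation failure that must surface.
* Single-cell crops only; the upstream leukocyte detection/locating step of
  a digital morphology analyzer is out of scope.
* No transfer learning: all weights train from scratch on synthetic data.
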