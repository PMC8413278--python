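# Methods

## Phase–height model

A quantitative phase image assigns each pixel the phase delay Δφ (radians)
of light crossing the specimen. The optical height is the algebraic
inversion h = Δφ·λ / (2π·(η_i − η_media)). Phase maps are assumed
unwrapped; no 2π-ambiguity handling is attempted. The conversion is
undefined at zero refractive-index contrast, which `OpticalParams` rejects
at construction.

The optical constants are experiment-specific and are therefore
configuration, not code constants. Defaults (in `cytophase.config`):
λ = 0.532 µm (a common green DHM illumination line), η_media = 1.333
(aqueous medium), η_i = 1.380 (a typical mean cell refractive index). In a
real deployment η_i should be calibrated per cell line; the defaults are
ours and are flagged as such.

## Segmentation

Cells are located as connected components (8-connectivity, configurable) of
the above-threshold mask of the phase image, thresholded either by Otsu's
method (module default, parameter-free) or at a fixed phase value. From
each component's integer-rounded centroid a 66×66 box is cut; a component
survives only if its area is *strictly* between 80 px and 600 px and the
box lies entirely inside the capture. With the even box side, "centred" is
resolved as the half-open window [r − 33, r + 33) × [c − 33, c + 33).
Touching cells are not split and overlapping boxes are permitted; each
qualifying component yields exactly one crop.

The *pipeline's* default threshold is fixed at 0.15 rad rather than Otsu:
on captures mixing tall apoptotic cells with flat necroptotic domes the
global Otsu threshold drifts upward and clips the flat cells' footprints
below the area filter. 0.15 rad is ~7.5× the default background noise SD,
so noise-only captures produce no detections. Otsu remains one config key
away.

## Supervised anomaly detection (SAD)

Induced experiments are impure: a dish treated with a death inducer still
contains alive-looking cells. The SAD filter is a two-class SVM (Alive vs
Death; apoptotic and necroptotic crops pooled into Death) trained on a
small curated set — 200 alive + 100 apoptotic + 100 necroptotic crops —
over a pluggable crop embedding. A crop is kept iff its predicted class
coordinates with its experiment's condition (Alive ↔ alive dish, Death ↔
induced dish, applied symmetrically in both directions) *and* its
prediction score strictly exceeds the threshold T (default 0.01). When a
crop fails both checks the verdict records `class_mismatch`; the mismatch
is the decisive rejection and the score is not consulted.

Design choices that were genuinely open:

* **Embedding.** The default extractor (`phase-stats`) computes
  deterministic classical features: a 16-bin normalized-intensity
  histogram plus height statistics, footprint fraction, spatial spread and
  Laplacian roughness (bleb-sensitive). A seeded random-weight
  convolutional encoder (`random-cnn`) is provided through the same
  contract, and a pretrained deep feature map can be slotted in likewise.
  The filter's logic — embed, separate, discard contradictions — is the
  method; the specific embedding is not.
* **Score.** "Prediction score" is defined here as the probability gap of
  the predicted class (p_predicted − p_other, clipped at zero; equals
  2·p − 1 for two classes), giving a nonnegative [0, 1] scale on which a
  small threshold like 0.01 removes only near-undecided crops. A raw SVM
  margin is available via `score_kind="margin"`. Probabilities come from
  Platt scaling, seeded for determinism.
* **SVM.** Linear kernel, C = 1.0, behind a feature standardizer (the
  histogram and moment features live on very different scales; an
  unstandardized linear SVM separates noticeably worse).

## Dataset construction and classifier

Post-filter crops, labelled by their experiment's condition, are balanced
by subsampling every class without replacement to the smallest class count
(seeded; crops are sorted by id first so the result is independent of
input order; the operation is idempotent). The balanced set is split
stratified per class, floor(n·0.2) crops to validation.

The classifier is a convolutional backbone plus a new head — fully
connected 64 → ReLU → fully connected 3 → softmax — in the fixed class
order (alive, apoptosis, necroptosis); argmax ties resolve to the earliest
class. Two backbones:

* `vgg19_full`: the VGG-19 arrangement (16 conv layers in five blocks,
  2×2 max-pools halving 224 → 112 → 56 → 28 → 14 → 7, ending at 7×7×512 =
  25088 flattened, then FC-4096/ReLU/FC-4096/ReLU). The original final
  classification stack (FC-1000, softmax, classification output) is
  removed and the new head attaches after the penultimate FC-4096
  activation. No pretrained weights ship with the package; the
  architecture is exact, initialization is seeded He-normal.
* `small_cnn` (default): three conv(3×3)+ReLU+pool blocks (8/16/32
  channels) on the native 66×66 crop, flattened to 2048 features. This is
  the desk-scale backbone used in tests and synthetic experiments.

Crops are min-max normalized to [0, 1] per crop (a constant crop maps to
zeros), bilinearly resized to the backbone's input size and replicated
over three channels.

All layers (conv via im2col + BLAS matmul, pooling, dense, softmax
cross-entropy, Adam) are implemented in numpy in `cytophase.nn`, with full
backpropagation. Training defaults: Adam, learning rate 1e-3, 10 epochs,
batch 32, `freeze_backbone=True` — the conv stack then acts as a fixed
seeded random-projection feature extractor and only the head is fitted,
which lets features be computed once per crop and keeps a full synthetic
run in seconds on one CPU. The rate 1e-3 was chosen because the 2-layer
head converges reliably within 10 epochs at desk scale; backbone
fine-tuning (`freeze_backbone=False`) is implemented and uses the same
loop. The best-validation-accuracy checkpoint is restored after training.
Determinism: every shuffle, init and draw flows from `numpy.random.default_rng`
on explicit seeds, so a fixed config reproduces results bit-for-bit.

## Evaluation

Per-class accuracy is the number of correct predictions over the number of
cells carrying that true label; a class absent from the labels is reported
as undefined (None), never 0. Multi-class ROC is handled one-vs-rest per
class on that class's softmax probability, sweeping all distinct score
thresholds, with trapezoidal AUC. Ties receive half credit, matching the
probabilistic reading of AUC (the probability a random positive outranks a
random negative), and `auc_pair_counting` computes that probability by
explicit pair enumeration as an independent oracle; the suite requires
agreement to 1e-9 at n ≤ 200.

## Synthetic data generator

The generator emulates what the pipeline consumes — not the microscope
physics. Cells are radial height profiles (µm):

* alive — irregular outline (radius modulated by low-order harmonics,
  ±15%), flattish spread profile, radius 7–10 px, peak 1.5–2.5 µm,
  height scale 1.0;
* apoptosis — shrunken dome (radius 5.5–7.5 px) carrying 3–6 compact
  high-curvature blebs, height scale 1.6 (> alive: chromatin condensation
  raises the refractive index, hence the optical height);
* necroptosis — large smooth dome (radius 10–13 px), height scale 0.55
  (< alive: membrane pores lower the index contrast).

The scale-factor ordering apoptosis > alive > necroptosis is enforced as a
construction invariant. Radii were chosen so footprints fall strictly
inside the 80–600 px area filter. Cells are placed by rejection sampling
(pairwise centre separation ≥ 40 px; border margin keeping every crop box
inside the field), summed onto a height canvas, converted to phase, and
additive Gaussian phase noise (SD 0.02 rad) is applied. Condition captures
model experiment impurity: induced dishes contain 15% still-alive cells;
alive dishes are pure.

What the generator does **not** emulate: speckle and coherent-imaging
artifacts, phase wrapping, cell-to-cell contact and clumping, debris,
focus drift, intra-class morphological continua (cells mid-transition),
and time-lapse motion. Passing tests therefore demonstrate that the
pipeline's logic is correct and that separable morphologies are recovered;
they do not certify accuracy on real microscope data, where class overlap
is substantially larger.

## Problem sizes and defaults of the end-to-end runs

A default synthetic study uses 6 captures × 16 cells per condition
(≈ 96 cells/condition before filtering), the 200/100/100 curated SAD set,
and the `small_cnn` backbone; holdout evaluation uses 6 fresh captures per
condition from disjoint experiment ids. These sizes keep a full run in a
few seconds while leaving ≥ 80 holdout cells per class, enough for stable
per-class accuracies. Scaling up is a config change.

## Known limitations

* No watershed splitting: touching cells merge into one component and are
  usually discarded by the area filter.
* The SAD score scale depends on the Platt calibration of the SVM; with
  very confident models most scores saturate near 1 and the threshold
  behaves as a near-binary gate.
* `vgg19_full` is practical for architecture audits and inference-scale
  experiments, but numpy training of the full backbone is slow; the
  transfer-learning path intended for it is head-only training.
* Holdout isolation is enforced by capture-id disjointness; the caller is
  responsible for ids that actually map 1:1 to physical experiments.
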