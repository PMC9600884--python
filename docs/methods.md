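# Methods

## Problem and approach

Inferior vena cava filters (IVCF) are small metallic, roughly conical devices
implanted to trap venous clots. They are intended to be temporary, frequently
go untracked, and are clearly visible on routine abdominopelvic CT. `ivcfind`
implements an automated detection pipeline for such scans:

1. **Preprocessing** reduces a native CT volume to a fixed model grid and
   rescales intensities to `[0, 1]`.
2. **Segmentation** labels filter pixels on every axial slice with a UNet.
3. **Flagging** declares a whole scan positive when enough consecutive slices
   contain enough segmented filter pixels, and reports the detected run.

A synthetic phantom generator provides volumes with exact ground truth so the
whole loop — including training — is testable without clinical data.

## Preprocessing

Stages run in the order crop → craniocaudal cutoff → in-plane resample →
slice resample → normalize.

- **Spatial crop** removes a fraction `f` (default 0.2) of each in-plane edge.
  The retained extent is `floor(d·(1−2f))` with leading margin `floor(d·f)`
  and the rounding remainder trailing, so a 512×512 slice becomes 307×307.
  The crop is the same for image and mask, keeping them voxel-aligned.
- **Craniocaudal cutoff** keeps only slices whose center offset from the most
  cranial slice is strictly below 400 mm (filters sit in the abdomen, within
  40 cm of the cranial end of a chest–abdomen–pelvis acquisition), i.e. the
  first `min(n, ceil(400/thickness))` cranial slices. The half-open interval
  makes the boundary slice deterministic. Loaders normalise stacks to
  cranial-first order (DICOM slices are sorted by position along the slice
  normal, never by file name) so "cranial end" is well defined.
- **Resampling** brings each slice to 256×256 and the stack to 128 slices.
  Intensities are interpolated bilinearly/linearly; label masks always use
  nearest-neighbor so the label set can never grow. Spacing metadata is
  rescaled by the extent ratio.
- **Normalization** maps HU to `[0, 1]`. *Hard* mode clips to the window
  [1, 2500] HU and rescales linearly — metal (≥ 2500 HU) saturates at 1.0 and
  all soft tissue is compressed near 0, maximising filter contrast. *Soft*
  mode uses the volume's own min/max; a constant volume maps to all zeros
  (documented degenerate case). Values below the hard window floor clip to 0:
  the window is read as a display/contrast window, which is what makes the
  metal stand out.

## Augmentation

Training-time augmentation applies, per slice and identically to image and
mask: upscale by a margin (default 10 %) followed by a random crop back to
the original size; a left–right flip (p = 0.5); a rotation drawn uniformly
from ±10° with exposed corners filled with background. Masks are always
transformed with nearest-neighbor interpolation. Magnitudes are not dictated
by the problem, so all three are config-exposed; a stepped generator gives
every epoch a fresh draw while a fixed seed reproduces a whole run.
Augmentation never runs at prediction time.

## Segmentation network

The network is a standard UNet encoder–decoder with skip concatenation,
written directly on numpy (im2col convolutions with explicit reverse-mode
gradients, verified against central finite differences). Per encoder level:
two 3×3 convolutions, each followed by batch normalization and a leaky ReLU
(negative slope 0.2, letting negative pre-activations keep a gradient during
downsampling), then 2×2 max-pooling. The decoder mirrors this with
nearest-neighbor upsampling + convolution, concatenation of the
same-resolution encoder features, and two further convolutions with plain
ReLU. Dropout (rate 0.5) is applied only in the first upsampling stage —
dropout is of limited value inside convolutional stacks, so it is restricted
to the single widest decoder bottleneck. A final 1×1 convolution emits
per-pixel class logits.

Defaults are 4 levels and 64 base filters doubling per level (≈ 34.5 M
trainable parameters); `depth` and `base_filters` scale the network to any
budget, and every sizing is validated (input extents must be divisible by
`2^depth`).

Training minimises sparse categorical cross-entropy (mean per-pixel negative
log-probability) with Adam. Reference settings for the clinical grid are 500
epochs, batch 20, learning rate 1e-4, and a deterministic shuffled 80/20
slice split (465 slices → 372 train / 93 validation). No class weighting is
used; the imbalance between filter and background pixels is instead absorbed
downstream by the flagging thresholds. Checkpoints are self-describing
(`.npz` with the estimator config embedded) and reload bit-identically.

`UNetSegmenter` exposes this as a scikit-learn estimator: `fit(X, y)` on
`(n_slices, H, W)` arrays, `predict` / `predict_proba`, fitted attributes
`model_`, `loss_history_`, `val_loss_history_`, `n_parameters_`, and
`get_params`/`set_params` for pipeline and model-selection compatibility.

## Scan flagging

Given a predicted mask volume, each slice is cleaned by removing connected
components (8-neighborhood by default) smaller than `min_region_area` pixels
(default 10). The criteria are deliberately area-only: shape-based filters
(eccentricity, solidity) would claim more than the segmentation model
justifies, since ring-like spinal calcification is a known surviving
confuser. Per-slice foreground counts are then computed, and the scan is
flagged iff some `sequence` consecutive slices each hold at least
`sig_count` pixels (both comparisons inclusive; reference operating points
combine `sig_count` ∈ {200, 300} with `sequence` ∈ {5, 7, 9}). The report
carries the earliest qualifying run extended to its maximal extent, the
per-slice counts, and the parameters used. Counts are computed on the
processed 128-slice grid, matching the grid the segmenter saw.

The decision is monotone by construction — raising either threshold can only
un-flag scans — and is property-tested against an exhaustive all-windows
oracle. A scan shorter than `sequence` is simply not flagged, never an
error.

## Phantom generator

Each phantom is: an air background (−1000 HU); an elliptical soft-tissue body
(mean 40 HU, texture SD 20 HU, plus scanner noise SD 10 HU); a circular
spine-like column posterior of center (700 HU); optionally a filter rendered
as a cone of ring cross-sections (radius growing from half to full over the
span) with strut dots on the ring, at 3000 HU so hard normalization clips it
to exactly 1.0; optionally a ring-like calcification confuser (1300 HU) near
the spine that survives the hard window yet is labelled background —
reproducing the main false-positive mechanism qualitatively. The mask marks
exactly the filter voxels. Default geometry (48+ slices of 512×512, ring
radius 30 px, thickness 4 px) gives every span slice ≥ 300 labelled pixels,
so the clinical `sig_count = 300` operating point is satisfiable by
construction; `expected_ring_area` provides the analytic annulus area the
rendered counts are tested against.

What the phantoms do *not* emulate: beam hardening, streak artifacts, couch
and arms, vendor-specific filter shapes, organ anatomy. Passing the
closed-loop tests therefore demonstrates that the pipeline machinery is
correct and the model can learn bright ring-like structure against
distractors — not clinical-grade performance on real scans.

## Scaled study conditions

The end-to-end study (`ivcfind.experiments`) runs the full loop at desk
scale: phantoms of 32 slices × 80×80 at 5 mm thickness, preprocessed with a
10 % crop to the 64×64 model grid; a depth-2, base-4 UNet (≈ 8.4 k
parameters); 20 positive training phantoms contributing 4 filter and 2
background slices each; 15 epochs, batch 10, learning rate 1e-3; 5 positive
and 5 negative held-out phantoms; flagging thresholds `sig_count = 60`,
`sequence = 6`, `min_region_area = 8`, scaled to the ~60–130 px ring
cross-sections of this geometry exactly as the clinical thresholds relate to
real filter cross-sections. A full cycle takes well under a minute on one
CPU and typically reaches held-out foreground Dice 0.6–0.97 with all 10
flag decisions correct.

Small networks under heavily imbalanced cross-entropy occasionally converge
to the all-background solution for unlucky initialisations. The study
handles this the way k-means handles bad starts: if the fitted model's
training-set foreground Dice is below 0.3, training restarts with a
deterministically derived fresh seed (at most 3 attempts), keeping the whole
study reproducible for a given seed.

## Evaluation conventions

- Dice `2|A∩B|/(|A|+|B|)`; both masks empty → 1.0, exactly one empty → 0.0.
- Pixel sensitivity/specificity from the confusion counts; a rate whose
  truth class is empty is NaN, never silently 0.
- Precision–recall curves sweep 101 evenly spaced thresholds on the
  foreground probability; precision with no predicted positives is 1.0; the
  curve is undefined (an error) without positive truth pixels. PR curves are
  preferred over ROC because the pixel classes are extremely imbalanced.
- Scan-level metrics are the standard ratios from TP/FP/TN/FN and are
  reported to 4 decimals.

## Known limitations

- The numpy network trains on CPU only; clinical-grid training (256×256,
  millions of parameters, hundreds of epochs) is expressible but slow — the
  implementation is sized for method correctness and phantom-scale studies.
- Slice indices in flag reports refer to the processed 128-slice grid, not
  native slice numbers.
- DICOM support covers single-frame CT series only; no multi-frame/enhanced
  DICOM, no DICOM writing.
- The phantom idealisation above bounds what green tests imply about real
  scans.
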