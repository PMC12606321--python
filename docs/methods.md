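# Methods

This note documents the models, conventions and numerical choices behind
`bbtquant`, and what its phantom-based validation does and does not show.

## Problem setting

Benign bone tumours (BBTs) on plain radiographs are followed over months to
years; the clinically relevant questions are whether the lesion's physical
size or area has changed and whether its contour has become irregular.
`bbtquant` implements the full measurement chain — lesion localisation,
segmentation, contour extraction, scale-bar calibration, millimetre
quantification and centroid-aligned longitudinal comparison — and validates
every stage against synthetic phantoms with exactly known ground truth,
since clinical radiographs of this kind are IRB-restricted and cannot ship
with the package.

## Coordinate and mask conventions

Coordinates are 0-based `(row, col)` with rows increasing downward, used
repo-wide.  Bounding boxes are half-open `[row0, row1) x [col0, col1)`.
Masks are strictly binary (bool in memory, 0/255 PNG on disk).  Linear
pixel extents are inclusive (`max - min + 1`): a one-pixel lesion is one
pixel wide, the same semantics as a physical bar of n pixels.

## Contour extraction

The lesion contour is defined set-theoretically: a pixel belongs to the edge
set iff it is foreground and at least one of its 8 neighbours is background.
Out-of-bounds neighbours count as background, so lesions touching the crop
border still yield closed contours — a requirement for both the visual
overlay and the boundary-F1 metric.  This is implemented as mask minus its
3x3 erosion and verified against a brute-force double-loop oracle.

## Haar channel fusion

A single-level orthonormal 2-D Haar transform is applied to the lesion crop.
On each non-overlapping 2x2 block `[[a, b], [c, d]]`:

    LL = (a+b+c+d)/2,  LH = ((a+b)-(c+d))/2,
    HL = ((a+c)-(b+d))/2,  HH = (a-b-c+d)/2.

Subband orientation naming conflicts across libraries, so the package fixes
it algebraically by this closed form: LH is the vertical-detail band
(responds to horizontal edges), HL the horizontal-detail band.  The
convention is recorded in the channel map of every fusion image, and the
implementation is cross-checked against PyWavelets in the test suite.
Odd dimensions are edge-replicated by one row/column before the blockwise
transform.

The fusion image maps LL→red, LH→green, HL→blue; HH is treated as noise and
discarded.  Three choices are underdetermined by the approach itself and are
made explicitly here:

* signed coefficients become 8-bit intensities by per-subband min–max
  rescaling (a constant subband maps to 0); the normalisation parameters are
  stored so the mapping is invertible;
* the half-resolution colour image is upsampled by nearest neighbour before
  stacking with the grayscale crop into the 4-channel input, avoiding
  interpolation artifacts on edges;
* rounding to integer intensities is half-up.

## Detection

The detector contract is a plain callable so a learned model can be plugged
in.  The shipped reference detector is classical and deterministic:
subtract a heavily blurred background estimate (Gaussian, sigma = 1/8 of the
image side), smooth the residual (sigma 2), threshold with Otsu's method —
guarded below by 3 robust standard deviations (1.4826·MAD) of the residual,
because Otsu alone can split inside the background mode when the lesion
occupies a tiny pixel fraction — and return the largest 8-connected
component's box with its solidity as score.  The leftmost 10% strip (the
calibration region) is excluded.  Detected boxes are padded by 25 px on all
sides before segmentation to preserve contour context (config-exposed).

Evaluation is single-class average precision at IoU 0.5 with all-point
interpolation of the precision–recall curve (the modern convention; an
11-point variant would change third-decimal digits on small sets).

## Segmentation

A compact two-level U-Net (single 3x3 convolution per resolution level,
base width 8, ~33k parameters) is trained on 64 px crops under three input
configurations — grayscale (1 channel), fusion image (3), grayscale+fusion
(4) — with identical splits and seeds, which is the channel-ablation
experiment the fusion representation exists for.  The network and its
backpropagation are implemented directly in numpy (im2col convolutions,
Adam); training is deterministic given the seed.  The model is deliberately
small: the benchmark task is bright blob segmentation at desk scale on one
CPU core, and depth/width are constructor arguments where more capacity is
needed.

Training protocol (fixed defaults): Adam, initial learning rate 1e-3,
multiplied by 0.3 every 10 epochs; up to 50 epochs (30 in the benchmark) at
batch size 8; pixelwise two-class cross-entropy; one validation check per
epoch, early stopping after 4 consecutive checks without validation-loss
improvement.  The first check initialises the best loss, so a never-improving
run stops after `1 + patience` epochs.

Metrics:

* **mean accuracy** — per-class recall averaged over the classes present in
  the ground truth ("class-balanced pixel accuracy"); this interpretation is
  config-free and matches the scale of commonly reported values;
* **mean IoU** — per-class intersection-over-union averaged over background
  and lesion;
* **BF1** — boundary F1 with match tolerance θ defaulting to 0.75% of the
  image diagonal (rounded up, ≥ 1 px), the customary tolerance for this
  score; θ is an explicit argument everywhere.

All three are verified against brute-force per-pixel oracles.

## Scale-bar calibration

The leftmost 10% of the image is binarised at fixed threshold 25 (≤ 25 →
background), the 8-connected component with the greatest vertical extent is
taken as the bar (ties: leftmost, then largest), and the label is read by an
OCR backend and parsed as `<number> <cm|mm>` (cm × 10).  The spatial
resolution is `mm_per_px = bar_length_mm / bar_height_px`.

Both ratios are stored explicitly.  All physical measurements use
millimetres per pixel; the conventional two-decimal report figure
(`report_ratio`) is pixels per millimetre, because that is how worked
examples are printed in practice (423 px / 130 mm → 3.25).  Its rounding
mode is config-exposed (`round`, half-up, default; or `truncate`, which
reproduces reports that print 3.31 for 431/130 where half-up gives 3.32).

OCR backends implement `recognize(image) -> [OcrResult]`.  The shipped
fixture backend matches connected components exactly against the package's
5x7 bitmap font — deterministic and sufficient for phantoms; an adapter for
the `easyocr` engine exists for real radiographs and is an optional runtime
dependency exercised by no test.

## Measurement

Width/height are the minimum bounding box extents times `mm_per_px`; area
is the mask pixel count times `mm_per_px` squared, which avoids the
overestimation a width×height product commits on irregular lesions (a
checkerboard test asserts the strict inequality).  Deviation reports
compute percent deviations from the *unrounded* absolute deviations divided
by ground truth, then round half-up to two decimals for display; this
reproduces the bundled ten-case validation table's aggregates (0.58% width,
0.38% height, 1.06% maximum).  The plain mean of all 20 per-case percent
deviations is reported as the overall aggregate (0.48% on that table).

## Longitudinal comparison

Masks from ordered visits are aligned by translating each one — integer
pixels only, no resampling, so areas and contours are preserved exactly —
until its foreground centroid is within 0.5 px of a common canvas centre.
Area changes are computed in mm² (each visit keeps its own calibration,
since scale bars differ between acquisitions), both consecutive and against
baseline; any absolute change strictly greater than 10% (config-exposed) is
flagged, growth or shrinkage, on either comparison.  Contours are overlaid
in red/green/blue time order with additive blending; shape change is
reported visually and as XOR area but never auto-classified — that judgement
is left to experts.

## Phantom generator

Phantoms emulate exactly the features the pipeline depends on:

* background: mean level (default 90) + a vertical gradient (±12) + a
  smooth random field (sigma = image/8, amplitude 10), so wavelet subbands
  are non-trivial, plus additive Gaussian noise (default sigma 8);
* lesion: a bright (default +45) region whose contour is an ellipse with a
  truncated random Fourier radial perturbation (default relative amplitude
  0.15, 4 harmonics, always < 0.5) — smooth but irregular, the shape class
  for which pixel-count area beats width×height;
* calibration strip: the leftmost 10% is near-black (noise clipped below
  the binarisation threshold) with a solid vertical bar of known pixel
  height and a bitmap-font label (e.g. "13 cm"); the bar is always the
  tallest component, and the label drops its space when the strip is too
  narrow for the full rendering.

Everything is deterministic given the config seed.  Follow-up series scale
the lesion semi-axes by the square root of per-visit area growth factors
while sharing the wobble realisation — the same lesion at different visits.
The default image is 512x512 for desk-scale runs; full clinical resolution
(1125x1125) is a config field away.

What phantoms do **not** emulate: real bone texture and trabecular
structure, overlapping anatomy, multiple or ill-defined lesions, burned-in
annotations other than the scale bar, detector-specific noise.  Passing the
phantom benchmarks therefore demonstrates the correctness of the
measurement chain and the trainability of the segmentation arms, not
clinical-grade accuracy on hospital radiographs; the published headline
metrics of segmentation models trained on clinical data are out of this
package's reproducible scope.

## Validation problem sizes

Chosen as the package's own desk-scale protocol: 100 phantoms for detection
mAP@0.5, 50 for calibration round-trip and extent recovery (tolerance: one
pixel-equivalent), 20 seeded series for temporal flagging (15% growth must
flag, 5% control must not), and 200 train / 50 test phantoms (≤ 30 epochs,
64 px patches) for the segmentation benchmark with its mean-IoU ≥ 0.80 bar.
`scripts/acceptance.py` recomputes all of these from scratch under a single
driving seed.

## Known limitations

* The reference detector assumes a single bright lesion; it is a stand-in
  interface implementation, not a clinical detector.
* Alignment is translation-only; rotation/scale registration between visits
  is out of scope.
* The numpy U-Net trains at desk scale only; it makes no claim to the
  capacity of GPU-scale segmentation models.
* DICOM inputs are intentionally unsupported (exported 8-bit 2-D images
  only); pixel-spacing tags, where available, would bypass the scale-bar
  route entirely.
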