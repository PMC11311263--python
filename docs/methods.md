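# Methods

This note documents the models, conventions and parameter choices behind
mammocalc, what the synthetic phantoms do and do not emulate, and the known
limitations.

## Conventions

Images are 2-D float64 grids, 0-based, row-major, origin top-left.
Intensities stay floating point through every stage; quantization happens
only when a 16-bit PNG is written (round-half-to-even).  An `ImageGrid`
carries optional physical pixel spacing in mm/px and a nominal display
range.  All filter responses are **cross-correlations** (kernels are not
flipped), the common filter convention in image processing; consequently the
impulse response of a kernel is its point reflection.  'Same'-size outputs
use zero padding and the border ring of width (k−1)/2 is not meaningful.

## Phantom generator

The generator emulates the geometry of the detection task, not mammographic
physics:

* **Breast**: a half-ellipse flush with the left or right image edge
  (side chosen by seed), axes 0.47·H and 0.72·W — a rough MLO/CC silhouette.
* **Tissue**: Gaussian-low-pass white noise (σ = `tissue_texture_scale`,
  default 12 px), scaled to ±0.08 around a base level of 0.35 on the [0, 1]
  scale.  The amplitude is chosen so that texture alone never mimics a spot:
  a brute-force local-maximum scan confirms no pixel rises above its 7×7
  neighbourhood by more than half the default spot contrast.
* **Spots**: radially symmetric raised-cosine bumps,
  h(r) = (c/2)(1 + cos πr/R) for r ≤ R, which avoid the aliasing hard disks
  show at 1–14 px radii.  Diameters are drawn uniformly from
  `spot_diameter_range` (default 0.1–1.0 mm) and converted to pixels via
  `pixel_spacing` (default 0.07 mm/px, typical full-field digital
  mammography, so spots span ≈1.4–14 px).  `spot_contrast` is the exact
  intensity lift of the bump peak over the local tissue.
* **Patterns**: scattered (uniform over the eroded breast interior),
  clustered/regional (isotropic Gaussian spread with dispersion radius
  0.08·min(H, W), tripled for regional), segmental (anisotropic spread along
  a random axis), linear (evenly spaced beads on a random line with
  perpendicular jitter ≤ 2 px; the spacing shrinks toward a 4 px floor when
  the full chain does not fit the breast).  Placement is rejection sampling
  with bounded retries; an infeasible pattern raises an explicit error.
* **Artifacts**: 1–3 bright text-like blocks stamped on background corners,
  standing in for the annotation/equipment marks preprocessing must remove.

Everything is driven by one `numpy` Generator seeded from the spec, so the
same spec yields bit-identical pixels and truth.

What the phantoms do **not** model: X-ray noise and scatter, pectoral
muscle, vessel/duct structure, benign-vs-malignant calcification
morphology, and compression artifacts.  Passing the synthetic studies shows
the pipeline's machinery is correct and that conspicuous spots are
recoverable; it says nothing about performance on real, subtle clinical
cases.

## Preprocessing

Stage order is grayscale → artifact removal → window → resize; the order of
removal vs windowing is configurable (`window_before_removal`) since either
is defensible.  Grayscale uses the luma weights (0.2989, 0.5870, 0.1140),
whose sum is 0.9999 — a white 255 input maps to 254.9745, and the package
deliberately does not renormalize.  Artifact removal labels 4-connected
components of pixels strictly above `fg_threshold` (default 0: the
background is an exact 0 after windowing) and keeps only the largest by
area, ties broken toward the earliest label in raster order.  The VOI
window is the linear center/width map; with no parameters the 2nd/98th
foreground percentiles are used, and a constant image is returned unchanged.
When no window is requested the pipeline applies the identity, which makes
it idempotent on its own output.  Resizing is bilinear without
anti-aliasing, and pixel spacing is rescaled per axis.

## Augmentation and split

Right-angle rotations (counter-clockwise positive) and reflections are exact
pixel permutations.  Scaling is a centre-anchored affine resampling on a
fixed canvas: the output pixel (r, c) samples the input at the
centre-preserving preimage, so scale(s) and scale(1/s) are exact inverse
mappings and a band-limited image round-trips to within bilinear
interpolation error (~1–2% of the dynamic range; broadband pixel noise does
not round-trip, which is inherent to resampling, not a defect).  Each
transform is applied to the original independently — no compositions — and
the identity scale emits nothing, making augmented counts exactly
predictable.

The stratified split uses round-half-up for the train and validation counts
and gives the remainder to test; this is the only rounding convention
consistent with both reference class sizes (2748 → 1924/550/274 and
2942 → 2059/588/295).  Assignment is a per-class seeded shuffle.

## Feature stack

The 8 channels are 2 Prewitt + 5 Gabor + 1 GLCM — the only composition of
the three kernel families that yields eight channels.

* **Gabor**: the canonical bank is five fixed 5×5 matrices treated as
  authoritative fixtures (shipped as a JSON resource and loaded at import;
  the θ=0 kernel peaks at 0.7726).  They are not reproducible from the
  parametric Gabor form with any single (σ, γ, ψ): the θ=0 matrix is
  radially symmetric and the θ=180 matrix differs from θ=0, which a pure
  cosine-phase Gabor cannot produce.  A `parametric` mode evaluates
  G(x, y) = exp(−(x′² + γ²y′²)/2σ²)·cos(2πx′/λ + ψ) on integer offsets
  −2…2 with λ = 1/0.625 for exploration, documented as approximate.
* **GLCM**: `glcm_compute` quantizes a window uniformly over its own
  min–max into `levels` bins and counts ordered pairs at offset
  (Δx, Δy) = d·(cos θ, −sin θ) (Δx = column, Δy = row; positive angles point
  up the image).  The texture map (`glcm_texture_samples` /
  `glcm_texture_map`) uses one **global** 8-level quantization of the image
  instead of per-window ranges: neighbouring windows then share a gray
  scale (a flat window in a bright region is not artificially stretched)
  and the window counts reduce to box sums computed with integral images,
  evaluated on a stride grid (window 17, stride 8, d=1, counts pooled over
  the four angles) and bilinearly upsampled.  Default feature is Haralick
  contrast; correlation is defined as 0 when a marginal variance vanishes.
* **Normalization**: each channel is min–max scaled to [0, 1] (a constant
  channel maps to 0) and resampled to the classifier input side
  (default 508, reconciling a 1024² preprocessed image with the standard
  network input).

## Classifier

Valid (unpadded) convolutions shrink each side by k−1; max pools divide by
the pool side with floor — with two blocks of (16, 3×3, pool 2) on
508×508×8 the sides are 506/253/251/125 and the flatten length 250,000.
A third block and other widths are configurable.  The dense width (64) is a
package default.  The implementation is plain numpy: im2col convolution,
manual backpropagation (verified against central finite differences to
~1e-9 relative error), He-normal seeded initialization, Adam
(β₁=0.9, β₂=0.999), binary cross-entropy with an L2 penalty on weight
matrices (λ·½Σw², biases excluded), and inverted dropout on the dense
hidden layer during training only.  Max-pool ties share the gradient
evenly.  The best-validation-loss parameters are restored after training.
Default hyperparameters follow the tuned reference configuration
(lr 1e-6, batch 8, 80 epochs, dropout 0.2, L2 0.01); the synthetic studies
pass lr 1e-3 and ~20 epochs explicitly, appropriate to their much smaller
scale.  Decisions use a strict '>' against the 0.5 threshold, so a
probability exactly at the threshold classifies negative.

## Localization

The disk structuring element is {(dr, dc): dr² + dc² ≤ r²}; the default
radius ceil(1.0 mm / spacing / 2) + 1 guarantees the largest expected
calcification fits strictly inside the disk and is erased by the opening.
Grayscale erosion/dilation replicate edge values at the border.  The white
top-hat is the original minus its opening, non-negative by
anti-extensivity.  Candidates are 8-connected blobs above a threshold
(default: mean + 3σ of the nonzero responses), filtered by area and ranked
by peak response.  The full pipeline adds one practical rule: the opening
cannot reconstruct the breast boundary, so the response map carries a rim
along the skin line; when the image has a zero background the threshold is
computed from the full map but candidates are extracted only from the
breast interior (foreground eroded by the SE radius).  On 20 seeded
negative phantoms this leaves a median of 0 false candidates while spot
recall on positives stays ≈0.99.  The 3 px centre-match radius used in
scoring is a package convention; blob connectivity is 8-way for candidates
but 4-way for breast-island detection.

## Evaluation

Metrics with zero denominators are flagged `undefined`, never silently
zeroed.  ROC points come from a threshold sweep over the unique scores and
the AUC is the trapezoid integral, equivalent to the Mann–Whitney
probability with rank-averaged ties (verified exhaustively against the
pairwise comparison at n ≤ 50).  Localization scoring matches candidate
centroids to truth centres greedily by ascending distance, one-to-one,
within the match radius (default: mean planted spot radius + 2 px).

## Synthetic study sizes

The reference experiments use 128×128 phantoms with 64×64×8 stacks, 64
training and 40 held-out images (balanced), spot contrast 0.5 for detection
and 0.7 for localization, 20 epochs at lr 1e-3 — a single-CPU scale chosen
as the package's standard benchmark.  Typical results: held-out accuracy
1.0, AUC 1.0, pooled spot recall 0.95–0.99.  High-contrast phantoms make
this an easy task by clinical standards; the studies validate machinery,
not clinical performance.

## Known limitations

* The CNN is a minimal numpy implementation: single-threaded, no GPU, no
  convolutional padding options, suitable for small inputs and method
  validation rather than full-resolution training.
* The GLCM texture map's global quantization differs from the per-window
  quantization of standalone `glcm_compute` (intentionally, see above).
* DICOM support covers single-frame monochrome images with simple
  center/width VOI-LUT metadata.
* No pectoral-muscle removal, breast-density estimation, malignancy grading
  or BI-RADS descriptors.
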