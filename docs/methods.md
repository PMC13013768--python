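# Methods

## Specular reflections as an augmentation signal

Endoscopic frames are lit by the scope itself, so wet mucosa produces
saturated specular highlights (SR) in essentially every image.  The package
implements two complementary augmentation routes built on one primitive —
the binary SR mask — plus the preprocessing, baseline augmentations, and
evaluation harness that a polyp-classification (AD vs HP) pipeline needs
around them.  Everything is driven by explicit random streams
(`numpy.random.Generator`); there is no global randomness, and per-item
streams are derived from `(seed, index)` so outputs never depend on
processing order.

## SR mask extraction

SR pixels are defined as grayscale luma strictly above a threshold
(default 245 on the 8-bit scale).  Luma is BT.601
(`0.299R + 0.587G + 0.114B`, rounded), the default of mainstream imaging
libraries.  The strict inequality matters at the boundary: a pixel at
exactly 245 is not SR.  No morphological area or shape filtering is applied
by default — fragmented bright pixels that are not true SR will be picked
up, which is a known precision limitation of fixed-threshold extraction; an
optional connected-component `min_area` filter is available but off by
default so the default behavior stays the plain threshold.

## Mask refinement (generation route)

The binary mask is softened into two weight maps in [0, 1]:

* **Highlight**: Gaussian blur with a fixed odd kernel `k₁` (default 5).
  Sigma follows the standard size→sigma rule
  `σ = 0.3·((k−1)/2 − 1) + 0.8`, the convention used when a kernel size is
  given without a sigma.
* **Halo**: Gaussian blur parameterized directly by `σ₂` (default 3.0),
  with the kernel auto-sized to the nearest odd integer ≥ 6σ₂ + 1 — the
  common convention for a "zero" kernel size meaning "derive the size from
  sigma".

Both blurs use reflective borders and normalized sampled-Gaussian kernels,
so a single-pixel mask becomes a unit-mass stamp.  Neither sigma has a
canonical published value; both are exposed in the configs.

## SR generation

For a target image, a donor of the *same class* with a non-degenerate mask
(area fraction ≥ `min_mask_fraction`, default 10⁻³) is sampled uniformly;
if no donor exists the caller falls back to passing the image through
(dataset-level augmentation logs a warning and keeps class proportions
intact).  The donor's two soft masks are jointly transformed by a random
rotation in {0°, 90°, 180°, 270°} and independent horizontal/vertical flips
(p = 0.5 each); rotation is restricted to grid-exact multiples of 90° so
the mask geometry survives unresampled.  The halo color is the donor's mean
RGB over its SR pixels, perturbed per channel by an integer uniform in
{−δ, …, +δ} (default δ = 10) — emulating the color blotches around real
highlights.  Compositing is two-layer alpha blending, halo first, then a
pure-saturation highlight layer (default 255):

```
out = (1 − W)·target + W·c_halo
out = (1 − H)·out + H·255
```

Blending with soft masks rather than pasting the binary mask is what
produces smooth highlights with localized color spreading instead of hard
seams.  The layer order (halo under highlight) follows from the physical
picture: the color spread surrounds the saturated core.  Consequences that
the tests pin down: the edit is local (pixels where both weights are zero
are bit-identical to the target), the output is bounded by the convex hull
of the inputs, and the transplanted core re-exceeds the extraction
threshold (self-consistency).

Limitations inherited by design: the transplant ignores 3-D surface
geometry and lighting direction, so transplanted highlights can land in
anatomically arbitrary positions within the crop; this is accepted as
clinically plausible because real SR also appears on background mucosa.

## SR inpainting

The image's own mask is extracted, dilated with a rectangular all-true
10 × 10 element (the saturated core understates the corrupted area), and
the hole refilled by an inpainting **backend** — any pure function
`fill(image, mask) → image`.  The pipeline then composites so that pixels
outside the dilated mask are bit-identical to the input; this contract is
enforced post-backend because learned inpainters may perturb unmasked
pixels, and it is tested with an adversarial noise-returning backend.
Dilation anchors even-sized elements at `(⌊h/2⌋, ⌊w/2⌋)`; pixels outside
the image are background (for symmetric elements this coincides with
reflective handling).

The built-in default backend is a classical **harmonic (diffusion) fill**:
masked pixels are repeatedly replaced by the mean of their 4-neighbors
(edge-replicated at the frame border, unmasked pixels clamped) until the
largest per-sweep change is below 0.1 intensity or 500 sweeps.  The
converged solution satisfies the discrete Laplace equation, hence the
maximum principle (filled values stay within the range of the hole's
boundary values), and matches a dense linear solve to within quantization
on small holes.  Masked pixels start at the unmasked channel mean, which
accelerates convergence without changing the fixed point.  A learned
high-resolution model is the natural production backend and can be
registered by name; its weights are deliberately not bundled.

Inpainting is deterministic: one inpainted image per input.  This is also
why, as an augmentation, it contributes less diversity than generation —
generation resamples donors every draw, inpainting maps each image to a
single cleaned version.

## Preprocessing

The clinician-annotated polyp bounding box drives a crop → pad-to-square →
bilinear-resize chain (anti-aliasing on downscale).  Padding before
resizing preserves the aspect ratio of the polyp pattern; the pad value
defaults to 0 (the field outside the illuminated area is black), and odd
padding puts the extra pixel bottom/right.  "Coordination noise" shifts the
crop center by `(δx·w, δy·h)` with `δx, δy ~ Uniform(−α, α)` before
cropping at the original box size, clamped back inside the image so the
patch size is invariant.  α defaults to 0.1; the clamping choice (rather
than padding out-of-bounds crops) keeps every output pixel a real image
pixel.  Supported network input sizes are 150 and 224.

## Baseline augmentations and FDA

The conventional stack — rotation (±30° default, reflective fill), flips,
color jitter (brightness/contrast/saturation each scaled by
`Uniform(1−s, 1+s)`, s = 0.2), additive Gaussian noise (σ = 5), Gaussian
blur (σ = 1) — is applied per-op with probability 0.5 in a fixed order
(rotation → flip → jitter → noise → blur).  Magnitudes have no canonical
values; they are mild conventional defaults, and a grid-sweep utility
yields candidate configs for users to evaluate with their own trainer.
Feature-space methods (style mixing between network feature maps) are
excluded: they cannot exist without a model.

FDA swaps the centered low-frequency amplitude spectrum of a source image
(central square window of half-width `⌊β·min(H, W)⌋`) with a target's,
keeping the source phase everywhere.  A window of half-width 0 swaps only
the DC coefficient and therefore transfers the target's mean intensity
exactly (up to 8-bit rounding); off-window amplitudes are untouched up to
the final quantization.

## Synthetic phantoms

The phantom generator emulates the *structure* of an NBI polyp dataset,
not its appearance: a dark reddish background (R > G > B around a mean of
90), one bright elliptical polyp (+40 contrast) carrying a sinusoidal
surface texture whose frequency encodes the class (AD 18 cycles/image,
HP 6 — a stand-in for fine vs coarse mucosal patterns), Gaussian sensor
noise (σ = 4), and 1–6 saturated elliptical SR blobs (radius 2–10 px,
intensity 246–255) placed in and around the polyp.  Class counts follow
the floor rule `⌊n·balance⌋` AD.

Two constructions make the phantoms an exact oracle: the non-SR image is
hard-clamped at 245 per channel, and SR pixels are written at ≥ 246 in all
channels, so `extract_sr_mask(·, 245)` recovers the planted mask
pixel-for-pixel.  The class label is recoverable without a network via the
dominant radial frequency inside the box (SR pixels replaced by the median
and a Hann taper applied before the FFT, so the saturated discs and the
polyp rim do not drown the texture peak).  What passing phantom tests do
**not** show: robustness to real mucosal texture, illumination gradients,
compression artifacts, or SR that is bright but unsaturated — the phantoms
validate the machinery, not clinical performance.

## Evaluation harness

* **Splits**: stratified hold-out (n per class, uniformly at random) and
  stratified k-fold (per-class round-robin over a permutation, fold sizes
  within 1).  On a 1,369 + 1,247 cohort with 120 held out per class this
  yields the 2,376-image pool (1,249 + 1,127) used by the balance table.
* **Balance testing**: Pearson chi-square *without* Yates continuity
  correction — this convention reproduces the published cohort's
  train/test p-values (0.448 / 0.783 / 0.753 / 0.849) from the printed
  counts; with correction the 2 × 2 values drift.  Cell percentages are
  column shares at 1 decimal.
* **Metrics**: AUC via the Mann–Whitney statistic with midranks (ties ½),
  equal to trapezoidal ROC integration; ACC/SEN/SPE/PPV/NPV at a 0.5
  threshold by default (operating points are dataset-specific), AD
  positive.  Undefined ratios (empty denominator) are NaN rather than 0.
* **DeLong's test**: placement values per sample, empirical covariance of
  the paired components, normal two-sided p.  Degenerate zero variance
  (e.g. identical classifiers) returns z = 0, p = 1.
* **Stress schedule**: nested class-stratified subsets at 10 %…100 % —
  one permutation per class, prefixes taken per fraction.  Nesting is a
  variance-reduction choice; plain independent sampling would satisfy the
  same marginal sizes.
* **Soft voting**: unweighted mean of member scores per group (video
  clip), label consistency enforced.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline on phantom sets of
5–100 images at 48–96 px (CLI end-to-end at 96 → 150 px) — sizes chosen so
the whole suite completes in well under a minute while every oracle
(pixel-exact mask recovery, brute-force dilation on ≤ 32² grids, dense
Laplace solves on ≤ 15² holes, 10⁴-resample bootstrap on 40 predictions)
stays exhaustive.  The harmonic fill is compared to the dense solve at
tolerance 0.5 intensity (8-bit quantization); chi-square and AUC checks are
exact to floating point.  All randomized checks are seeded; the acceptance
script derives every stream from its `--seed` argument.

## Known limitations

* Fixed-threshold SR extraction misses bright-but-unsaturated highlights
  and admits non-SR saturated fragments (no shape constraints by default).
* The generation route is photometrically heuristic: no surface curvature,
  lighting angle, or 3-D consistency.
* The diffusion fill restores smooth tissue, not fine texture; a learned
  backend is expected for production-quality fills.
* Phantoms are structural stand-ins; no claim of NBI visual realism.
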