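# specaug

Specular-reflection-aware data augmentation for colonoscopy computer-aided
diagnosis (CADx).

## The problem

During colonoscopy the endoscope's light source illuminates the dark
intestinal lumen, so every frame contains **specular reflections (SR)**:
saturated, near-white highlights where light bounces off wet mucosa.  SR
obscures exactly the surface and vascular patterns that distinguish
adenomatous (AD) from hyperplastic (HP) polyps under narrow-band imaging,
and classifiers trained on SR-heavy data tend to latch onto the highlights
instead of the tissue.  Rather than discarding SR-heavy frames as
non-informative, `specaug` turns SR into an augmentation signal:

* **SR generation** — extract the SR mask of a donor image (grayscale
  conversion, binary threshold at luma > 245), soften it with two Gaussian
  filters (a small `k₁ = 5` kernel for the crisp highlight and a wider
  sigma-driven kernel for the surrounding color halo), randomly
  rotate/flip it, perturb the halo color, and alpha-composite it onto a
  randomly chosen **same-class** target image.  One target can yield many
  distinct augmented images because donors are resampled per draw.
* **SR inpainting** — threshold the image's own SR mask `M_S`, dilate it
  with a rectangular 10 × 10 kernel to cover the corrupted rim, isolate
  the unaffected region `Ĩ_S` by bitwise masking, and refill the hole
  through a pluggable inpainting backend.  The built-in backend is a
  classical harmonic (diffusion) fill; learned high-resolution inpainters
  can be registered without changing the pipeline, and pixels outside the
  dilated mask are guaranteed bit-identical to the input regardless of the
  backend.

Around this core the package ships the rest of a CADx data pipeline:
bounding-box-guided crop → square pad → resize preprocessing with
"coordination noise" (uniform jitter of the crop center by ±α of the box
size), the conventional baseline augmentations (rotation, flips, color
jitter, Gaussian noise/blur) plus Fourier Domain Adaptation (FDA), a
stratified split and chi-square balance-test harness, ROC/AUC and DeLong's
paired AUC test, stress-test subsampling schedules, frame-level soft
voting, and a seeded endoscopy-phantom generator whose planted SR masks
are recovered *exactly* by the extraction pipeline — the ground truth that
makes the whole toolkit testable without private clinical data.

## Core definitions

* SR mask: `M_S(x) = [Y(x) > 245]` with BT.601 luma
  `Y = 0.299R + 0.587G + 0.114B`.
* Refinement: `H = G_{k₁} * M_S` (highlight), `W = G_{σ₂} * M_S` (halo),
  kernels truncated/auto-sized by the usual size↔sigma conventions.
* Compositing: `out = (1−H)·[(1−W)·target + W·c_halo] + H·255`, where
  `c_halo` is the donor's mean RGB over `M_S` plus a uniform integer
  perturbation in `{−δ,…,δ}` per channel.
* AUC: Mann–Whitney formulation with ties counted ½; DeLong's test
  compares two correlated AUCs via the covariance of placement values.
* Balance testing: Pearson chi-square without continuity correction,
  `X² = Σ (O−E)²/E`, `df = (r−1)(c−1)`.

## Worked example

The phantom generator stands in for a real dataset; every stage is a CLI
subcommand (all are also plain library functions):

```bash
specaug make-phantoms --n 8 --size 96 --seed 7 --out phantoms
# wrote 8 phantoms to phantoms ({'AD': 4, 'HP': 4})
specaug preprocess --manifest phantoms/manifest.csv --out pp --size 150 --seed 7
# preprocessed 8 images to pp
specaug augment-gen --manifest pp/manifest.csv --out gen --seed 7
# wrote 8 SR-generated images to gen
specaug augment-inp --manifest gen/manifest.csv --out inp
# wrote 8 inpainted images to inp
specaug balance-test --train phantoms/manifest.csv --test phantoms/manifest.csv
# covariate  chi2  df   p AD (train) AD (test) HP (train) HP (test)
#     label   0.0   1 1.0   4 (50.0)  4 (50.0)   4 (50.0)  4 (50.0)
```

The first phantom contains 127 planted SR pixels
(`extract_sr_mask(img, 245).sum()`); after `augment-inp` the same check
returns 0 — every saturated highlight has been removed and refilled from
the surrounding texture.  Re-running any command with the same `--seed`
reproduces the output byte-for-byte.

In Python the same core operations look like:

```python
from specaug.io_manifest import seeded_rng
from specaug.sr_generation import SRGenConfig, generate_sr
from specaug.sr_inpainting import SRInpConfig, inpaint_sr

augmented, mask = generate_sr(target, donor, SRGenConfig(), seeded_rng(0))
cleaned, dilated = inpaint_sr(image, SRInpConfig())
```

## Scope

Model training (ResNet/ViT), learned inpainting network internals, and
generative augmentation (GAN/DDPM) are out of scope: the package prepares
data for and evaluates the outputs of external trainers through its
manifest and prediction-CSV interfaces.
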