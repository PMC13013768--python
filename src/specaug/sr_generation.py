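"""SR generation: transplant a donor image's specular highlights onto a target.

The donor's SR mask is extracted by thresholding, softened into a highlight
layer and a color halo, randomly rotated/flipped, and alpha-composited onto
a same-class target image.  The halo carries the donor's mean SR color with
a small random RGB perturbation (the color blotches seen around real
highlights); the highlight layer is pure saturation.  Because donors are
resampled per draw, one target can yield many distinct augmented images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from specaug.io_manifest import (
    AnnotatedSample,
    DatasetManifest,
    ValidationError,
    read_image,
    spawn_rng,
    validate_image,
    write_image,
    write_manifest,
)
from specaug.sr_mask import (
    DEFAULT_K1,
    DEFAULT_SIGMA2,
    DEFAULT_THRESHOLD,
    extract_sr_mask,
    mask_area_fraction,
    refine_mask,
    transform_mask,
)

logger = logging.getLogger("specaug")


class NoSRDonorError(RuntimeError):
    """No same-class source image with a usable SR mask is available.

    Callers fall back to base augmentation when this is raised.
    """


@dataclass(frozen=True)
class SRGenConfig:
    """Free parameters of the SR-generation pipeline.

    threshold
        Grayscale cutoff (strict >) defining SR pixels in the donor.
    k1
        Odd kernel size of the highlight-softening Gaussian.
    sigma2
        Sigma of the halo Gaussian (kernel auto-sized).
    perturb_amplitude
        Max absolute per-channel integer offset of the halo color.
    highlight_intensity
        Intensity composited at full highlight weight (255 = saturated).
    min_mask_fraction
        Minimum SR area fraction for a donor to count as non-degenerate.
    """

    threshold: int = DEFAULT_THRESHOLD
    k1: int = DEFAULT_K1
    sigma2: float = DEFAULT_SIGMA2
    perturb_amplitude: int = 10
    highlight_intensity: int = 255
    min_mask_fraction: float = 0.001

    def __post_init__(self) -> None:
        if self.perturb_amplitude < 0:
            raise ValidationError(
                f"perturb_amplitude must be >= 0, got {self.perturb_amplitude}"
            )
        if not 0 < self.min_mask_fraction < 1:
            raise ValidationError(
                f"min_mask_fraction must be in (0, 1), got {self.min_mask_fraction}"
            )


def sample_source(
    manifest: DatasetManifest,
    target_label: str,
    cfg: SRGenConfig,
    rng: np.random.Generator,
    exclude_path: str | None = None,
) -> AnnotatedSample:
    """Uniformly pick a same-class donor whose SR mask is non-degenerate.

    ``exclude_path`` removes the target itself from the candidate pool
    whenever at least one other candidate remains.
    """
    candidates = []
    for s in manifest:
        if s.label != target_label:
            continue
        mask = extract_sr_mask(read_image(s.image_path), cfg.threshold)
        if mask_area_fraction(mask) >= cfg.min_mask_fraction:
            candidates.append(s)
    if exclude_path is not None and len(candidates) > 1:
        remaining = [s for s in candidates if s.image_path != exclude_path]
        if remaining:
            candidates = remaining
    if not candidates:
        raise NoSRDonorError(
            f"no SR donor: no {target_label} sample has mask fraction >= "
            f"{cfg.min_mask_fraction} at threshold {cfg.threshold}"
        )
    return candidates[rng.integers(len(candidates))]


def perturb_rgb(
    stamp_color: np.ndarray, delta: int, rng: np.random.Generator
) -> np.ndarray:
    """Offset each channel by an integer ~ Uniform{-delta..+delta}, clipped."""
    if delta < 0:
        raise ValidationError(f"delta must be >= 0, got {delta}")
    color = np.asarray(stamp_color, dtype=np.int64)
    offsets = rng.integers(-delta, delta + 1, size=3)
    return np.clip(color + offsets, 0, 255).astype(np.uint8)


def _resize_soft(soft: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if soft.shape == shape:
        return soft
    out = _sk_resize(soft, shape, order=1, mode="reflect", anti_aliasing=False)
    return np.clip(out, 0.0, 1.0)


def _resize_binary(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if mask.shape == shape:
        return mask
    out = _sk_resize(
        mask.astype(np.float64), shape, order=0, mode="reflect", anti_aliasing=False
    )
    return out > 0.5


def composite_sr(
    target: np.ndarray,
    highlight: np.ndarray,
    halo: np.ndarray,
    halo_color: np.ndarray,
    highlight_intensity: int = 255,
) -> np.ndarray:
    """Two-layer alpha blend: halo color first, saturated highlight on top.

    out = (1 - halo) * target + halo * halo_color, then
    out = (1 - highlight) * out + highlight * highlight_intensity,
    per channel, rounded and clipped to [0, 255].
    """
    out = target.astype(np.float64)
    out = (1.0 - halo[..., None]) * out + halo[..., None] * halo_color.astype(
        np.float64
    )
    out = (1.0 - highlight[..., None]) * out + highlight[..., None] * float(
        highlight_intensity
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def generate_sr(
    target: np.ndarray,
    source: np.ndarray,
    cfg: SRGenConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize an SR-augmented image from a (target, donor) pair.

    Steps: extract the donor's SR mask; soften into highlight/halo weight
    maps; draw one random rotation (0/90/180/270) and independent
    horizontal/vertical flips (p = 0.5 each), applied consistently to both
    maps and the binary mask; resize to the target if needed; compute the
    halo color as the donor's mean RGB over its SR pixels, perturbed; then
    composite.  Returns the augmented image and the transformed binary
    mask for downstream QC.
    """
    target = validate_image(target)
    source = validate_image(source)
    mask = extract_sr_mask(source, cfg.threshold)
    if mask_area_fraction(mask) < cfg.min_mask_fraction:
        raise NoSRDonorError(
            f"no SR donor: source mask fraction {mask_area_fraction(mask):.5f} "
            f"< {cfg.min_mask_fraction}"
        )
    highlight, halo = refine_mask(mask, cfg.k1, cfg.sigma2)

    rotation = int(rng.integers(4)) * 90
    flip_h = bool(rng.random() < 0.5)
    flip_v = bool(rng.random() < 0.5)
    highlight = transform_mask(highlight, rotation, flip_h, flip_v)
    halo = transform_mask(halo, rotation, flip_h, flip_v)
    mask_t = transform_mask(mask, rotation, flip_h, flip_v)

    tshape = target.shape[:2]
    highlight = _resize_soft(highlight, tshape)
    halo = _resize_soft(halo, tshape)
    mask_t = _resize_binary(mask_t, tshape)

    mean_color = source[mask].mean(axis=0)
    halo_color = perturb_rgb(np.rint(mean_color), cfg.perturb_amplitude, rng)
    out = composite_sr(target, highlight, halo, halo_color, cfg.highlight_intensity)
    logger.debug(
        "generate_sr: %d SR pixels transplanted (rot=%d, fh=%s, fv=%s)",
        int(mask_t.sum()), rotation, flip_h, flip_v,
    )
    return out, mask_t


def augment_dataset_gen(
    manifest: DatasetManifest,
    cfg: SRGenConfig,
    n_per_image: int,
    rng: np.random.Generator,
    out_dir: str | Path,
    seed: int | None = None,
) -> DatasetManifest:
    """Emit ``n_per_image`` SR-generated variants of every manifest sample.

    Donors are drawn independently per variant from the same class.
    Samples with no eligible donor are passed through unchanged with a
    logged warning, so class proportions are preserved.  When ``seed`` is
    given, per-sample streams are derived from it so outputs do not depend
    on processing order.
    """
    if n_per_image < 1:
        raise ValidationError(f"n_per_image must be >= 1, got {n_per_image}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_samples = []
    for i, sample in enumerate(manifest):
        local_rng = spawn_rng(seed, i) if seed is not None else rng
        target = read_image(sample.image_path)
        stem = Path(sample.image_path).stem
        for j in range(n_per_image):
            out_path = out_dir / f"{stem}_srgen{j}.png"
            mask_path = out_dir / f"{stem}_srgen{j}_mask.png"
            try:
                donor = sample_source(
                    manifest, sample.label, cfg, local_rng,
                    exclude_path=sample.image_path,
                )
                img, mask = generate_sr(
                    target, read_image(donor.image_path), cfg, local_rng
                )
            except NoSRDonorError:
                logger.warning(
                    "no SR donor for %s; passing through unchanged",
                    sample.image_path,
                )
                img = target
                mask = np.zeros(target.shape[:2], dtype=bool)
            write_image(img, out_path)
            write_image(mask, mask_path)
            out_samples.append(
                AnnotatedSample(
                    image_path=str(out_path),
                    label=sample.label,
                    bbox=sample.bbox,
                    sr_mask_path=str(mask_path),
                    metadata=dict(sample.metadata),
                )
            )
        logger.info("SR generation done for %s", sample.image_path)
    out_manifest = DatasetManifest(out_samples)
    write_manifest(out_manifest, out_dir / "manifest.csv")
    return out_manifest
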