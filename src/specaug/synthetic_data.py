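"""Seeded endoscopy-phantom generator with exact ground-truth SR masks.

Real NBI colonoscopy datasets are private; the phantom emulates their
*structure* so every pipeline stage is testable: a dark reddish luminal
background, one bright elliptical "polyp" carrying a sinusoidal surface
texture whose spatial frequency encodes the class (AD fine-grained, HP
coarse — a stand-in for vascular/surface pattern differences), additive
sensor noise, and a handful of saturated elliptical specular blobs planted
inside and around the polyp.

Two hard guarantees make the phantoms an oracle for mask extraction:
non-SR pixels are clamped to intensity <= 245 per channel, and planted SR
pixels are set to a sampled intensity >= 246 in all channels, so
thresholding at 245 recovers the planted mask pixel-for-pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from specaug.io_manifest import (
    AnnotatedSample,
    BoundingBox,
    DatasetManifest,
    ValidationError,
    spawn_rng,
    write_image,
    write_manifest,
)
from specaug.sr_mask import to_grayscale

#: Channel offsets giving the reddish cast (R > G > B around background_mean).
_TINT = np.array([18.0, 0.0, -18.0])
_TEXTURE_AMPLITUDE = 12.0


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom-set parameters (all intensities 8-bit).

    The defaults satisfy the detectability invariants: SR blobs at
    >= 246 are above the 245 threshold, and background + polyp contrast
    + 3 sigma of noise stays below 246 so thresholding yields no false
    positives (non-SR pixels are additionally clamped at 245).
    """

    n_images: int = 100
    image_size: int = 224
    class_balance: float = 0.5  # fraction AD
    sr_blob_count_range: tuple[int, int] = (1, 6)
    sr_blob_radius_range: tuple[int, int] = (2, 10)
    sr_intensity_range: tuple[int, int] = (246, 255)
    background_mean: int = 90
    polyp_contrast: int = 40
    texture_freq_ad: float = 18.0  # cycles per image width
    texture_freq_hp: float = 6.0
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.class_balance < 1.0:
            raise ValidationError(
                f"class_balance must be in (0,1), got {self.class_balance}"
            )
        if self.sr_intensity_range[0] < 246:
            warnings.warn(
                "sr_intensity_range low end < 246: planted SR may not be "
                "detectable at threshold 245",
                stacklevel=2,
            )
        headroom = (
            self.background_mean + _TINT.max() + self.polyp_contrast
            + _TEXTURE_AMPLITUDE + 3.0 * self.noise_sigma
        )
        if headroom >= 246:
            warnings.warn(
                f"background + contrast + texture + 3*noise = {headroom:.0f} >= 246: "
                "non-SR pixels will be clamped hard at 245",
                stacklevel=2,
            )

    def label_for(self, idx: int) -> str:
        """Deterministic label assignment: first floor(n*balance) images are AD."""
        n_ad = int(np.floor(self.n_images * self.class_balance))
        return "AD" if idx < n_ad else "HP"


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2 <= 1.0


def generate_phantom(
    cfg: PhantomConfig,
    idx: int,
    rng: np.random.Generator,
    label: str | None = None,
) -> tuple[np.ndarray, AnnotatedSample, np.ndarray]:
    """Render one phantom: (image, annotated sample, planted SR mask).

    The sample's ``image_path`` is a placeholder name derived from ``idx``;
    :func:`generate_phantom_set` replaces it with the written file path.
    """
    size = cfg.image_size
    label = label if label is not None else cfg.label_for(idx)

    base = np.full((size, size, 3), float(cfg.background_mean)) + _TINT

    # one bright elliptical polyp with class-dependent sinusoidal texture
    center = (
        rng.uniform(0.35 * size, 0.65 * size),
        rng.uniform(0.35 * size, 0.65 * size),
    )
    axes = (rng.uniform(0.15 * size, 0.28 * size), rng.uniform(0.15 * size, 0.28 * size))
    angle = rng.uniform(0.0, np.pi)
    polyp = _ellipse_mask((size, size), center, axes, angle)
    base[polyp] += cfg.polyp_contrast

    freq = cfg.texture_freq_ad if label == "AD" else cfg.texture_freq_hp
    theta = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    carrier = np.sin(
        2.0 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) / size
    )
    base[polyp] += (_TEXTURE_AMPLITUDE * carrier)[polyp][:, None]

    base += rng.normal(0.0, cfg.noise_sigma, size=base.shape)
    # hard ceiling below the SR threshold keeps the planted mask exact
    img = np.clip(np.rint(base), 0, 245).astype(np.uint8)

    # saturated SR blobs inside and near the polyp
    ys, xs = np.where(polyp)
    y0, y1 = ys.min(), ys.max()
    x0, x1 = xs.min(), xs.max()
    sr_mask = np.zeros((size, size), dtype=bool)
    lo, hi = cfg.sr_blob_count_range
    n_blobs = int(rng.integers(lo, hi + 1))
    margin = 0.15 * size
    for _ in range(n_blobs):
        by = rng.uniform(max(0, y0 - margin), min(size - 1, y1 + margin))
        bx = rng.uniform(max(0, x0 - margin), min(size - 1, x1 + margin))
        r1 = rng.uniform(*cfg.sr_blob_radius_range)
        r2 = rng.uniform(*cfg.sr_blob_radius_range)
        blob = _ellipse_mask((size, size), (by, bx), (r1, r2), rng.uniform(0, np.pi))
        intensity = int(rng.integers(cfg.sr_intensity_range[0],
                                     cfg.sr_intensity_range[1] + 1))
        img[blob] = intensity
        sr_mask |= blob

    bbox = BoundingBox(
        x_min=int(x0), y_min=int(y0), width=int(x1 - x0 + 1), height=int(y1 - y0 + 1)
    )
    sample = AnnotatedSample(
        image_path=f"phantom_{idx:05d}.png", label=label, bbox=bbox
    )
    return img, sample, sr_mask


def generate_phantom_set(
    cfg: PhantomConfig, out_dir: str | Path
) -> DatasetManifest:
    """Write ``cfg.n_images`` phantoms, their SR masks, and a manifest.

    Class counts follow the floor rule: floor(n * balance) AD, remainder
    HP.  Each image's stream is derived from (cfg.seed, index) so any
    single phantom is reproducible in isolation.
    """
    if cfg.n_images < 1:
        raise ValidationError(f"n_images must be >= 1, got {cfg.n_images}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = []
    for i in range(cfg.n_images):
        rng = spawn_rng(cfg.seed, i)
        img, sample, sr_mask = generate_phantom(cfg, i, rng)
        img_path = out_dir / f"phantom_{i:05d}.png"
        mask_path = out_dir / f"phantom_{i:05d}_srmask.png"
        write_image(img, img_path)
        write_image(sr_mask, mask_path)
        sample.image_path = str(img_path)
        sample.sr_mask_path = str(mask_path)
        samples.append(sample)
    manifest = DatasetManifest(samples)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def dominant_texture_frequency(img: np.ndarray, bbox: BoundingBox) -> float:
    """Dominant radial spatial frequency inside the box, in cycles/image.

    A trivial spectral statistic that separates the two phantom classes
    (AD texture is fine, HP coarse), giving harness tests a learnable
    signal without a neural network.
    """
    crop = to_grayscale(
        img[bbox.y_min : bbox.y_max, bbox.x_min : bbox.x_max]
    ).astype(np.float64)
    # saturated SR discs would otherwise dominate the spectrum
    regular = crop <= 245
    fill = np.median(crop[regular]) if regular.any() else np.median(crop)
    crop[~regular] = fill
    h, w = crop.shape
    # Hann taper suppresses leakage from the polyp rim crossing the crop
    crop = (crop - crop.mean()) * np.outer(np.hanning(h), np.hanning(w))
    spec = np.abs(np.fft.fftshift(np.fft.fft2(crop)))
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - h // 2, xx - w // 2)
    # suppress residual DC / very-low-frequency leakage
    spec[r < 2.0] = 0.0
    peak = np.unravel_index(np.argmax(spec), spec.shape)
    cycles_per_crop = r[peak]
    scale = img.shape[0] / max(h, w)
    return float(cycles_per_crop * scale)
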