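"""Conventional photometric/geometric augmentations and Fourier Domain Adaptation.

The baseline stack mirrors what natural-image classification pipelines use:
small random rotation, flips, color jitter (brightness/contrast/saturation),
additive Gaussian noise, and Gaussian blur, each applied independently with
a per-op probability, in a fixed order.  FDA is the domain-adaptation
comparator: the low-frequency amplitude spectrum of one image is replaced
by another's while the phase is kept, transferring global illumination and
color tone without touching structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate

from specaug.io_manifest import ValidationError, validate_image
from specaug.sr_mask import _LUMA

ALL_OPS = ("rotation", "flip", "color_jitter", "gaussian_noise", "gaussian_blur")


@dataclass(frozen=True)
class BaseAugConfig:
    """Baseline augmentation settings; magnitudes are conventional mild defaults."""

    enabled_ops: tuple[str, ...] = ALL_OPS
    rotation_max_deg: float = 30.0
    jitter_strength: float = 0.2
    noise_sigma: float = 5.0
    blur_sigma: float = 1.0
    apply_prob: float = 0.5

    def __post_init__(self) -> None:
        unknown = set(self.enabled_ops) - set(ALL_OPS)
        if unknown:
            raise ValidationError(f"unknown augmentation ops: {sorted(unknown)}")
        if not 0.0 <= self.apply_prob <= 1.0:
            raise ValidationError(f"apply_prob must be in [0,1], got {self.apply_prob}")
        if not 0.0 <= self.jitter_strength <= 1.0:
            raise ValidationError(
                f"jitter_strength must be in [0,1], got {self.jitter_strength}"
            )


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def _rotate(img, cfg, rng):
    angle = rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg)
    out = _sk_rotate(
        img.astype(np.float64), angle, mode="reflect", order=1, preserve_range=True
    )
    return _to_uint8(out)


def _flip(img, cfg, rng, forced_axis=None):
    axis = forced_axis if forced_axis is not None else int(rng.integers(2))
    return img[:, ::-1] if axis == 0 else img[::-1, :]


def _color_jitter(img, cfg, rng):
    s = cfg.jitter_strength
    fb, fc, fs = rng.uniform(1.0 - s, 1.0 + s, size=3)
    out = img.astype(np.float64)
    out = out * fb  # brightness
    mean = out.mean()
    out = (out - mean) * fc + mean  # contrast
    gray = (out @ _LUMA)[..., None]
    out = gray + (out - gray) * fs  # saturation
    return _to_uint8(out)


def _gaussian_noise(img, cfg, rng):
    noise = rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    return _to_uint8(img.astype(np.float64) + noise)


def _gaussian_blur(img, cfg, rng):
    out = ndimage.gaussian_filter(
        img.astype(np.float64), sigma=(cfg.blur_sigma, cfg.blur_sigma, 0.0),
        mode="reflect",
    )
    return _to_uint8(out)


_OP_FUNCS = {
    "rotation": _rotate,
    "flip": _flip,
    "color_jitter": _color_jitter,
    "gaussian_noise": _gaussian_noise,
    "gaussian_blur": _gaussian_blur,
}


def apply_base_aug(
    img: np.ndarray, cfg: BaseAugConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply each enabled op with probability ``apply_prob``, in fixed order.

    Order: rotation -> flip -> color jitter -> Gaussian noise -> Gaussian
    blur.  Output is 8-bit with the input dimensions.
    """
    img = validate_image(img)
    out = img
    for op in ALL_OPS:
        if op not in cfg.enabled_ops:
            continue
        if rng.random() < cfg.apply_prob:
            out = _OP_FUNCS[op](out, cfg, rng)
    return out


def sweep_base_aug_configs(
    rotation_max_deg=(15.0, 30.0),
    jitter_strength=(0.1, 0.2),
    noise_sigma=(3.0, 5.0),
    blur_sigma=(0.5, 1.0),
    apply_prob=(0.5,),
):
    """Yield :class:`BaseAugConfig` objects over a hyperparameter grid.

    Utility for re-deriving the best baseline settings on a user's own
    data (the effective magnitudes are dataset-dependent): evaluate each
    yielded config with an external trainer and keep the winner.
    """
    for r, j, n, b, p in itertools.product(
        rotation_max_deg, jitter_strength, noise_sigma, blur_sigma, apply_prob
    ):
        yield BaseAugConfig(
            rotation_max_deg=r,
            jitter_strength=j,
            noise_sigma=n,
            blur_sigma=b,
            apply_prob=p,
        )


def fda_transfer(source: np.ndarray, target: np.ndarray, beta: float) -> np.ndarray:
    """Replace the source's low-frequency amplitude with the target's.

    Per channel: 2-D FFT of both images; in the centered amplitude
    spectrum, the central square window of half-width
    ``floor(beta * min(H, W))`` takes the target's amplitude; the source's
    phase is kept everywhere; inverse transform, real part, clipped to
    8-bit.  ``beta`` small enough to give half-width 0 swaps only the DC
    coefficient, transferring the target's mean intensity.
    """
    source = validate_image(source)
    target = validate_image(target)
    if source.shape != target.shape:
        raise ValidationError(
            f"source {source.shape} and target {target.shape} must match"
        )
    if not 0.0 < beta <= 0.5:
        raise ValidationError(f"beta must be in (0, 0.5], got {beta}")
    h, w = source.shape[:2]
    b = int(np.floor(beta * min(h, w)))
    cy, cx = h // 2, w // 2
    out = np.empty_like(source, dtype=np.float64)
    for c in range(3):
        fs = np.fft.fftshift(np.fft.fft2(source[..., c].astype(np.float64)))
        ft = np.fft.fftshift(np.fft.fft2(target[..., c].astype(np.float64)))
        amp, phase = np.abs(fs), np.angle(fs)
        amp[cy - b : cy + b + 1, cx - b : cx + b + 1] = np.abs(
            ft[cy - b : cy + b + 1, cx - b : cx + b + 1]
        )
        mixed = amp * np.exp(1j * phase)
        out[..., c] = np.real(np.fft.ifft2(np.fft.ifftshift(mixed)))
    return _to_uint8(out)
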