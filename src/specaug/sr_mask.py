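"""Specular-reflection mask extraction, refinement, and morphology.

The shared core of both SR augmentation routes: SR pixels are defined as
those whose BT.601 luma exceeds a fixed threshold (245 by default — SR is
near-saturated).  Generation softens the binary mask with two Gaussian
filters (a small kernel for the crisp highlight, a sigma-driven one for the
surrounding color halo); inpainting dilates it with a rectangular element
to cover the corrupted rim around each highlight.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from specaug.io_manifest import ValidationError, validate_image

#: BT.601 luma weights for RGB -> grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

DEFAULT_THRESHOLD = 245
DEFAULT_K1 = 5
DEFAULT_SIGMA2 = 3.0


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """BT.601 luma: Y = 0.299 R + 0.587 G + 0.114 B, rounded to uint8."""
    img = validate_image(img)
    y = img.astype(np.float64) @ _LUMA
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def extract_sr_mask(img: np.ndarray, threshold: int = DEFAULT_THRESHOLD) -> np.ndarray:
    """Boolean mask of pixels with grayscale value strictly above ``threshold``."""
    if not 0 <= threshold <= 255:
        raise ValidationError(f"threshold must be in [0, 255], got {threshold}")
    return to_grayscale(img) > threshold


def sigma_from_kernel(ksize: int) -> float:
    """Standard kernel-size -> sigma rule: 0.3 * ((k - 1)/2 - 1) + 0.8."""
    return 0.3 * ((ksize - 1) / 2.0 - 1.0) + 0.8


def kernel_from_sigma(sigma: float) -> int:
    """Auto kernel size for a given sigma: nearest odd integer >= 6*sigma + 1."""
    k = int(np.ceil(6.0 * sigma + 1.0))
    return k if k % 2 == 1 else k + 1


def _gaussian_soft(mask01: np.ndarray, ksize: int, sigma: float) -> np.ndarray:
    radius = (ksize - 1) // 2
    if radius == 0:
        return mask01.copy()
    out = ndimage.gaussian_filter(
        mask01, sigma=sigma, mode="reflect", truncate=radius / sigma
    )
    return np.clip(out, 0.0, 1.0)


def refine_mask(
    mask: np.ndarray,
    k1: int = DEFAULT_K1,
    sigma2: float = DEFAULT_SIGMA2,
) -> tuple[np.ndarray, np.ndarray]:
    """Soften a binary SR mask into (highlight, halo) weight maps in [0, 1].

    ``highlight`` is the 0/1 mask blurred with a ``k1 x k1`` truncated
    Gaussian (sigma from :func:`sigma_from_kernel`) — the crisp saturated
    core.  ``halo`` is a wider blur parameterized directly by ``sigma2``
    with its kernel auto-sized by :func:`kernel_from_sigma` — the diffuse
    color-spreading rim around the highlight.  Reflective borders.
    """
    if k1 < 1 or k1 % 2 == 0:
        raise ValidationError(f"k1 must be odd and >= 1, got {k1}")
    if sigma2 <= 0:
        raise ValidationError(f"sigma2 must be > 0, got {sigma2}")
    mask01 = np.asarray(mask, dtype=bool).astype(np.float64)
    highlight = _gaussian_soft(mask01, k1, sigma_from_kernel(k1))
    halo = _gaussian_soft(mask01, kernel_from_sigma(sigma2), sigma2)
    return highlight, halo


def dilate_mask(mask: np.ndarray, kernel_h: int = 10, kernel_w: int = 10) -> np.ndarray:
    """Binary dilation with an all-true ``kernel_h x kernel_w`` rectangle.

    The element anchor sits at (floor(h/2), floor(w/2)), so even sizes
    reach one pixel further toward the top/left.  Pixels outside the image
    are treated as background.
    """
    if kernel_h < 1 or kernel_w < 1:
        raise ValidationError(
            f"kernel sizes must be >= 1, got {kernel_h}x{kernel_w}"
        )
    mask = np.asarray(mask, dtype=bool)
    structure = np.ones((kernel_h, kernel_w), dtype=bool)
    return ndimage.binary_dilation(mask, structure=structure)


def transform_mask(
    mask: np.ndarray,
    rotation: int = 0,
    flip_h: bool = False,
    flip_v: bool = False,
) -> np.ndarray:
    """Rigid grid transform: rotate by a multiple of 90 degrees, then flip.

    Rotation is counterclockwise; 90/270 on non-square masks swap the
    output dimensions.  True-pixel count is conserved.
    """
    if rotation not in (0, 90, 180, 270):
        raise ValidationError(f"rotation must be one of 0/90/180/270, got {rotation}")
    out = np.asarray(mask)
    if rotation:
        out = np.rot90(out, k=rotation // 90)
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def mask_area_fraction(mask: np.ndarray) -> float:
    """Fraction of true pixels — QC statistic for degenerate-mask filtering."""
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum()) / mask.size


def filter_min_area(mask: np.ndarray, min_area: int = 0) -> np.ndarray:
    """Optional connected-component area filter (off at ``min_area=0``).

    The extraction pipeline applies no morphological filtering by default;
    this helper exists for users who want to drop fragmented high-intensity
    pixels that are not true specular reflections.
    """
    if min_area <= 0:
        return np.asarray(mask, dtype=bool).copy()
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask.copy()
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_area) + 1
    return np.isin(labels, keep)
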