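"""Bounding-box-guided crop, aspect-preserving square padding, and resize.

Polyp bounding boxes vary in aspect ratio; resizing a crop directly to the
network input size would distort the surface pattern, so the crop is first
padded to a square and only then resized.  "Coordination noise" jitters the
crop center by a uniform fraction of the box dimensions so repeated draws
of the same sample see slightly different surroundings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from specaug.io_manifest import BoundingBox, ValidationError, validate_image

TARGET_SIZES = (150, 224)


@dataclass(frozen=True)
class PreprocessConfig:
    """Crop/pad/resize parameters.

    target_size
        Square output side in pixels; the two supported network input
        sizes are 150 and 224.
    pad_value
        Intensity used for the square padding border (default 0: the
        endoscopic field outside the illuminated area is essentially black).
    alpha
        Coordination-noise amplitude as a fraction of box width/height;
        offsets are drawn from Uniform(-alpha, +alpha) per axis.
    """

    target_size: int = 224
    pad_value: int = 0
    alpha: float = 0.1

    def __post_init__(self) -> None:
        if self.target_size not in TARGET_SIZES:
            raise ValidationError(
                f"target_size must be one of {TARGET_SIZES}, got {self.target_size}"
            )
        if not 0 <= self.pad_value <= 255:
            raise ValidationError(f"pad_value must be in [0, 255], got {self.pad_value}")
        if self.alpha < 0:
            raise ValidationError(f"alpha must be >= 0, got {self.alpha}")


def pad_to_square(img: np.ndarray, pad_value: int = 0) -> np.ndarray:
    """Pad to S x S with S = max(H, W), content centered.

    When the total padding along an axis is odd, the extra pixel goes to
    the bottom/right.  Content pixels are never altered.
    """
    img = validate_image(img)
    h, w = img.shape[:2]
    side = max(h, w)
    pad_top = (side - h) // 2
    pad_bottom = side - h - pad_top
    pad_left = (side - w) // 2
    pad_right = side - w - pad_left
    return np.pad(
        img,
        ((pad_top, pad_bottom), (pad_left, pad_right), (0, 0)),
        mode="constant",
        constant_values=pad_value,
    )


def crop_with_coordination_noise(
    img: np.ndarray,
    bbox: BoundingBox,
    alpha: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Crop a bbox-sized patch around a jittered box center.

    Offsets delta_x, delta_y ~ Uniform(-alpha, +alpha) scale the box width
    and height respectively; the crop window keeps the original box size
    and is clamped back inside the image, so the output is always exactly
    ``bbox.height x bbox.width``.
    """
    img = validate_image(img)
    if alpha < 0:
        raise ValidationError(f"alpha must be >= 0, got {alpha}")
    bbox.validate_within(img.shape[0], img.shape[1])

    dx = rng.uniform(-alpha, alpha)
    dy = rng.uniform(-alpha, alpha)
    cx, cy = bbox.center
    cx += dx * bbox.width
    cy += dy * bbox.height

    x0 = int(round(cx - bbox.width / 2.0))
    y0 = int(round(cy - bbox.height / 2.0))
    # clamp the window fully inside the image
    x0 = min(max(x0, 0), img.shape[1] - bbox.width)
    y0 = min(max(y0, 0), img.shape[0] - bbox.height)
    return img[y0 : y0 + bbox.height, x0 : x0 + bbox.width]


def resize_bilinear(img: np.ndarray, height: int, width: int) -> np.ndarray:
    """Bilinear resize with anti-aliasing on downscale, back to uint8."""
    img = validate_image(img)
    if (height, width) == img.shape[:2]:
        return img.copy()
    shrinking = height < img.shape[0] or width < img.shape[1]
    out = _sk_resize(
        img.astype(np.float64),
        (height, width),
        order=1,
        mode="reflect",
        anti_aliasing=shrinking,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def preprocess_sample(
    img: np.ndarray,
    bbox: BoundingBox,
    cfg: PreprocessConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Full preprocessing: noisy crop -> pad to square -> bilinear resize."""
    patch = crop_with_coordination_noise(img, bbox, cfg.alpha, rng)
    squared = pad_to_square(patch, cfg.pad_value)
    return resize_bilinear(squared, cfg.target_size, cfg.target_size)
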