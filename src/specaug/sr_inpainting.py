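"""SR inpainting: detect, dilate, remove and refill specular highlights.

Specular highlights destroy the mucosal surface pattern underneath them;
this route restores structural continuity by masking the highlight (plus a
dilated rim, since the corruption bleeds past the saturated core) and
filling it from the surrounding tissue.  The fill is delegated to a
pluggable backend — any pure function ``fill(image, mask) -> image`` — so a
learned high-resolution inpainter can be slotted in without changing the
pipeline.  The built-in default is a classical harmonic (diffusion) fill.

Regardless of the backend, the pipeline composite guarantees that pixels
outside the dilated mask are bit-identical to the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol

import numpy as np

from specaug.io_manifest import (
    AnnotatedSample,
    DatasetManifest,
    ValidationError,
    read_image,
    validate_image,
    write_image,
    write_manifest,
)
from specaug.sr_mask import DEFAULT_THRESHOLD, dilate_mask, extract_sr_mask

logger = logging.getLogger("specaug")


class InpaintBackend(Protocol):
    """Contract for inpainting plugins: pure, dimension-preserving fill."""

    name: str

    def fill(self, image: np.ndarray, mask: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class SRInpConfig:
    """SR-inpainting parameters: detection threshold, rim dilation, backend."""

    threshold: int = DEFAULT_THRESHOLD
    dilate_h: int = 10
    dilate_w: int = 10
    backend: str = "diffusion"

    def __post_init__(self) -> None:
        if self.dilate_h < 1 or self.dilate_w < 1:
            raise ValidationError(
                f"dilation kernel must be >= 1, got {self.dilate_h}x{self.dilate_w}"
            )


def isolate_unaffected(img: np.ndarray, dilated: np.ndarray) -> np.ndarray:
    """Bitwise-mask out the SR region: inside pixels zeroed, outside kept."""
    img = validate_image(img)
    dilated = np.asarray(dilated, dtype=bool)
    if dilated.shape != img.shape[:2]:
        raise ValidationError(
            f"mask shape {dilated.shape} does not match image {img.shape[:2]}"
        )
    out = img.copy()
    out[dilated] = 0
    return out


def harmonic_fill(
    image: np.ndarray,
    mask: np.ndarray,
    tol: float = 0.1,
    max_iter: int = 500,
) -> np.ndarray:
    """Iterative harmonic (diffusion) fill of masked pixels.

    Masked pixels are repeatedly replaced by the mean of their
    4-neighbors (edge neighbors replicated at the image border) while
    unmasked pixels stay clamped to the originals, until the largest
    per-iteration change drops below ``tol`` intensity units or
    ``max_iter`` sweeps.  Channels are independent.  The converged result
    satisfies the discrete Laplace equation inside the mask, so filled
    values obey the maximum principle: they lie within the range of the
    mask's boundary values.
    """
    image = validate_image(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise ValidationError(
            f"mask shape {mask.shape} does not match image {image.shape[:2]}"
        )
    if not mask.any():
        return image.copy()
    work = image.astype(np.float64)
    # neutral start: masked pixels begin at the unmasked mean of each channel
    for c in range(3):
        ch = work[..., c]
        outside = ch[~mask]
        ch[mask] = outside.mean() if outside.size else 128.0
    for _ in range(max_iter):
        padded = np.pad(work, ((1, 1), (1, 1), (0, 0)), mode="edge")
        neigh = (
            padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:]
        ) / 4.0
        delta = np.abs(neigh[mask] - work[mask]).max() if mask.any() else 0.0
        work[mask] = neigh[mask]
        if delta < tol:
            break
    out = np.clip(np.rint(work), 0, 255).astype(np.uint8)
    out[~mask] = image[~mask]
    return out


class DiffusionBackend:
    """Built-in classical backend: harmonic fill by neighbor diffusion."""

    name = "diffusion"

    def fill(self, image: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return harmonic_fill(image, mask)


_BACKENDS: dict[str, InpaintBackend] = {}


class BackendConfigError(RuntimeError):
    """Unknown or duplicate inpainting backend."""


def register_backend(backend: InpaintBackend, replace: bool = False) -> None:
    """Make a backend resolvable by name in :class:`SRInpConfig`."""
    if backend.name in _BACKENDS and not replace:
        raise BackendConfigError(f"backend {backend.name!r} already registered")
    _BACKENDS[backend.name] = backend


def get_backend(name: str) -> InpaintBackend:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise BackendConfigError(
            f"unknown inpainting backend {name!r}; registered: {sorted(_BACKENDS)}"
        ) from None


register_backend(DiffusionBackend())


def inpaint_sr(
    img: np.ndarray, cfg: SRInpConfig = SRInpConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Detect, dilate, and refill SR regions; returns (inpainted, dilated mask).

    Pixels outside the dilated mask are bit-identical to the input — the
    composite enforces this even if the backend perturbs them.
    """
    img = validate_image(img)
    backend = get_backend(cfg.backend)
    mask = extract_sr_mask(img, cfg.threshold)
    if not mask.any():
        return img.copy(), mask
    dilated = dilate_mask(mask, cfg.dilate_h, cfg.dilate_w)
    try:
        filled = backend.fill(img, dilated)
    except Exception as exc:
        raise RuntimeError(
            f"inpainting backend {cfg.backend!r} failed: {exc}"
        ) from exc
    filled = validate_image(filled)
    if filled.shape != img.shape:
        raise ValidationError(
            f"backend {cfg.backend!r} changed image shape "
            f"{img.shape} -> {filled.shape}"
        )
    out = img.copy()
    out[dilated] = filled[dilated]
    logger.debug("inpaint_sr: filled %d pixels", int(dilated.sum()))
    return out, dilated


def augment_dataset_inp(
    manifest: DatasetManifest,
    cfg: SRInpConfig,
    out_dir: str | Path,
) -> DatasetManifest:
    """Emit exactly one inpainted image per input image (deterministic)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_samples = []
    for sample in manifest:
        img = read_image(sample.image_path)
        inp, dilated = inpaint_sr(img, cfg)
        stem = Path(sample.image_path).stem
        out_path = out_dir / f"{stem}_srinp.png"
        mask_path = out_dir / f"{stem}_srinp_mask.png"
        write_image(inp, out_path)
        write_image(dilated, mask_path)
        out_samples.append(
            AnnotatedSample(
                image_path=str(out_path),
                label=sample.label,
                bbox=sample.bbox,
                sr_mask_path=str(mask_path),
                metadata=dict(sample.metadata),
            )
        )
        logger.info("SR inpainting done for %s", sample.image_path)
    out_manifest = DatasetManifest(out_samples)
    write_manifest(out_manifest, out_dir / "manifest.csv")
    return out_manifest
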