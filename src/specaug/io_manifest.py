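"""Image and manifest I/O, core annotation types, seeding, and config.

Images are plain ``numpy`` arrays of shape ``(H, W, 3)`` and dtype
``uint8``, channel order RGB, regardless of what the codec stores
internally.  Dataset annotations travel in a flat CSV manifest with one row
per image: path, two-class label (``AD``/``HP``), a 0-based half-open
bounding box, and optionally a ground-truth SR-mask path plus arbitrary
extra covariate columns (location, size category, morphology, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from PIL import Image as PILImage

logger = logging.getLogger("specaug")

#: The two polyp classes: adenomatous and hyperplastic.
LABELS = ("AD", "HP")

_MANIFEST_CORE_COLUMNS = ["image_path", "label", "x_min", "y_min", "width", "height"]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


# ---------------------------------------------------------------------------
# Annotation types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundingBox:
    """0-based, half-open pixel box: ``[x_min, x_min+width) x [y_min, y_min+height)``."""

    x_min: int
    y_min: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(
                f"bounding box must have positive size, got {self.width}x{self.height}"
            )
        if self.x_min < 0 or self.y_min < 0:
            raise ValidationError(
                f"bounding box origin must be non-negative, got ({self.x_min}, {self.y_min})"
            )

    @property
    def x_max(self) -> int:
        return self.x_min + self.width

    @property
    def y_max(self) -> int:
        return self.y_min + self.height

    @property
    def center(self) -> tuple[float, float]:
        """(cx, cy) in pixel coordinates."""
        return (self.x_min + self.width / 2.0, self.y_min + self.height / 2.0)

    def validate_within(self, height: int, width: int) -> None:
        """Check the box lies fully inside an ``height x width`` image."""
        if self.x_max > width or self.y_max > height:
            raise ValidationError(
                f"bounding box {self} exceeds image bounds {height}x{width}"
            )


@dataclass
class AnnotatedSample:
    """One dataset record: image path, class label, polyp box, optional SR mask."""

    image_path: str
    label: str
    bbox: BoundingBox
    sr_mask_path: str | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(
                f"unknown label {self.label!r} for {self.image_path!r}; "
                f"expected one of {LABELS}"
            )


@dataclass
class DatasetManifest:
    """Ordered collection of annotated samples with per-label counts."""

    samples: list[AnnotatedSample]

    def __post_init__(self) -> None:
        paths = [s.image_path for s in self.samples]
        if len(set(paths)) != len(paths):
            dupes = sorted({p for p in paths if paths.count(p) > 1})
            raise ValidationError(f"duplicate image paths in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def label_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in LABELS}
        for s in self.samples:
            counts[s.label] += 1
        return counts

    def subset(self, indices) -> "DatasetManifest":
        return DatasetManifest([self.samples[i] for i in indices])

    def by_label(self, label: str) -> list[int]:
        """Indices of samples carrying ``label``, in manifest order."""
        return [i for i, s in enumerate(self.samples) if s.label == label]


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check an array is a valid H x W x 3 uint8 RGB image and return it."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValidationError(f"expected HxWx3 RGB image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValidationError(f"zero-size image: shape {img.shape}")
    if img.dtype != np.uint8:
        raise ValidationError(f"expected uint8 intensities, got dtype {img.dtype}")
    return img


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file into an RGB uint8 array.

    Grayscale files are replicated across 3 channels; alpha is dropped.
    """
    path = Path(path)
    try:
        with PILImage.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - codec specifics
        raise OSError(f"cannot decode image file {path}: {exc}") from exc
    return validate_image(arr)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an RGB image; PNG is lossless, JPEG is export-only (lossy).

    Single-channel boolean/uint8 masks are accepted and written as
    grayscale PNG (booleans scaled to 0/255).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(img)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    if arr.ndim == 3:
        arr = validate_image(arr)
    if path.suffix.lower() in (".jpg", ".jpeg"):
        logger.info("writing lossy JPEG export to %s", path)
    PILImage.fromarray(arr).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 single-channel PNG back into an H x W boolean mask."""
    with PILImage.open(Path(path)) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 127


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path, validate_images: bool = False) -> DatasetManifest:
    """Read a CSV manifest.

    Required header columns: ``image_path,label,x_min,y_min,width,height``;
    ``sr_mask_path`` is optional, and any further columns are kept as
    per-sample string metadata (used by the balance-test harness).

    With ``validate_images=True`` each referenced image is opened and the
    bounding box checked against its dimensions.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANIFEST_CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {path} missing columns: {missing}")
    extra = [
        c for c in df.columns if c not in _MANIFEST_CORE_COLUMNS + ["sr_mask_path"]
    ]
    samples = []
    for row_idx, row in df.iterrows():
        try:
            bbox = BoundingBox(
                x_min=int(row["x_min"]),
                y_min=int(row["y_min"]),
                width=int(row["width"]),
                height=int(row["height"]),
            )
            sample = AnnotatedSample(
                image_path=row["image_path"],
                label=row["label"],
                bbox=bbox,
                sr_mask_path=row.get("sr_mask_path") or None,
                metadata={c: row[c] for c in extra},
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"manifest {path} row {row_idx}: {exc}") from exc
        if validate_images:
            img = read_image(sample.image_path)
            try:
                bbox.validate_within(img.shape[0], img.shape[1])
            except ValidationError as exc:
                raise ValidationError(f"manifest {path} row {row_idx}: {exc}") from exc
        samples.append(sample)
    manifest = DatasetManifest(samples)
    logger.info(
        "read manifest %s: %d samples %s", path, len(manifest), manifest.label_counts
    )
    return manifest


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write a manifest as CSV; round-trips losslessly with :func:`read_manifest`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    extra_cols: list[str] = []
    for s in manifest.samples:
        for k in s.metadata:
            if k not in extra_cols:
                extra_cols.append(k)
    has_mask = any(s.sr_mask_path for s in manifest.samples)
    rows = []
    for s in manifest.samples:
        row = {
            "image_path": s.image_path,
            "label": s.label,
            "x_min": s.bbox.x_min,
            "y_min": s.bbox.y_min,
            "width": s.bbox.width,
            "height": s.bbox.height,
        }
        if has_mask:
            row["sr_mask_path"] = s.sr_mask_path or ""
        for k in extra_cols:
            row[k] = s.metadata.get(k, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Randomness and config
# ---------------------------------------------------------------------------


def seeded_rng(seed: int) -> np.random.Generator:
    """Deterministic random stream; equal seeds give identical sequences.

    Every randomized operation in the package takes one of these
    explicitly — there is no hidden global randomness.
    """
    if seed < 0:
        raise ValidationError(f"seed must be non-negative, got {seed}")
    return np.random.default_rng(seed)


def spawn_rng(seed: int, *keys: int) -> np.random.Generator:
    """Derive an independent child stream from (seed, keys).

    Used so per-item streams do not depend on processing order.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def load_config(path: str | Path) -> dict:
    """Load a flat-key YAML config holding pipeline hyperparameters."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ValidationError(f"config {path} must be a mapping of flat keys")
    return dict(cfg)
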