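"""Mammogram image-cleaning chain and per-image statistics.

The pipeline, applied in order: overexposure rejection (mean > 150),
binarization at threshold 50, largest-connected-component masking, masking of
the original image, CLAHE, left-orientation flip, and area-average
downsampling with normalization to [-1, 1].  Every step is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import exposure, measure

__all__ = [
    "ProcessedImage",
    "ImageStats",
    "PipelineResult",
    "reject_overexposed",
    "binarize_mask",
    "largest_component",
    "apply_mask",
    "clahe",
    "orient_left",
    "area_average_resize",
    "resize_normalize",
    "preprocess_pipeline",
    "image_stats",
]

OVEREXPOSURE_MEAN = 150.0   # reject strictly above this mean gray level
MASK_THRESHOLD = 50         # tissue mask keeps pixels strictly above this
DEFAULT_OUT_SHAPE = (244, 244)


@dataclass(frozen=True)
class ProcessedImage:
    """Final pipeline output: pixels in [-1, 1], with step provenance."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ImageStats:
    """Per-image summary on the 0-255 scale plus tissue-mask coverage."""

    mean_gray: float
    sd_gray: float
    tissue_fraction: float


@dataclass(frozen=True)
class PipelineResult:
    rejected: bool
    processed: ProcessedImage | None = None
    stats: ImageStats | None = None
    steps: tuple = ()


def _as_image(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    return arr


def reject_overexposed(image) -> bool:
    """True iff the image's mean gray level strictly exceeds 150."""
    return float(_as_image(image).mean()) > OVEREXPOSURE_MEAN


def binarize_mask(image) -> np.ndarray:
    """Boolean tissue mask: pixels strictly above 50 (a pixel of exactly 50
    is background by convention)."""
    return _as_image(image) > MASK_THRESHOLD


def largest_component(mask) -> np.ndarray:
    """Keep only the largest 8-connected true component of a boolean mask.

    Ties between equal-size components are broken by the smallest top-left
    (row-major) pixel coordinate; an all-false mask is returned unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    if len(candidates) > 1:
        flat = labels.ravel()
        first_idx = {c: int(np.flatnonzero(flat == c)[0]) for c in candidates}
        keep = min(candidates, key=lambda c: first_idx[c])
    else:
        keep = candidates[0]
    return labels == keep


def apply_mask(image, mask) -> np.ndarray:
    """Element-wise product; pixels outside the mask become exactly 0."""
    image = _as_image(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs mask {mask.shape}")
    return image * mask.astype(image.dtype)


def clahe(image, clip_limit: float = 0.01, tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    ``clip_limit`` is the normalized clipping fraction in (0, 1];
    ``tile_grid`` sets the number of contextual tiles per axis.  A constant
    image is returned unchanged (there is no contrast to equalize).
    """
    image = _as_image(image)
    if clip_limit <= 0 or tile_grid[0] <= 0 or tile_grid[1] <= 0:
        raise ValueError("clip_limit and tile_grid must be positive")
    arr = np.clip(np.round(image), 0, 255).astype(np.uint8)
    if arr.min() == arr.max():
        return arr
    kernel = (max(1, arr.shape[0] // tile_grid[0]), max(1, arr.shape[1] // tile_grid[1]))
    out = exposure.equalize_adapthist(arr, kernel_size=kernel, clip_limit=clip_limit)
    return np.round(out * 255.0).astype(np.uint8)


def orient_left(image, mask):
    """Mirror image and mask horizontally when most mask mass is on the right.

    Returns ``(image, mask)``; the flip triggers only when the right half's
    mask pixel count strictly exceeds the left half's, so the operation is
    idempotent.  An empty mask is a warned no-op.
    """
    image = _as_image(image)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("orient_left: empty mask, leaving image unchanged")
        return image, mask
    w = mask.shape[1]
    left = int(mask[:, : w // 2].sum())
    right = int(mask[:, (w + 1) // 2:].sum())
    if right > left:
        return image[:, ::-1], mask[:, ::-1]
    return image, mask


def _overlap_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic matrix averaging n_in samples into n_out equal intervals
    with exact fractional-edge weights (area interpolation along one axis)."""
    scale = n_in / n_out
    mat = np.zeros((n_out, n_in))
    for i in range(n_out):
        a, b = i * scale, (i + 1) * scale
        k0, k1 = int(np.floor(a)), int(np.ceil(b))
        for k in range(k0, min(k1, n_in)):
            mat[i, k] = max(0.0, min(k + 1.0, b) - max(float(k), a))
        mat[i] /= scale
    return mat


def area_average_resize(image, out_shape: tuple[int, int]) -> np.ndarray:
    """Exact area-average resampling (block averaging for integer factors)."""
    image = _as_image(image).astype(float)
    rows = _overlap_matrix(image.shape[0], out_shape[0])
    cols = _overlap_matrix(image.shape[1], out_shape[1])
    return rows @ image @ cols.T


def resize_normalize(image, out_shape: tuple[int, int] = DEFAULT_OUT_SHAPE,
                     provenance: dict | None = None) -> ProcessedImage:
    """Area-average downsample and map the 0-255 scale linearly to [-1, 1]."""
    small = area_average_resize(image, out_shape)
    pixels = small / 127.5 - 1.0
    return ProcessedImage(pixels, dict(provenance or {}))


def image_stats(image, mask) -> ImageStats:
    """Mean/sd gray level over all pixels (0-255 scale, population sd) and the
    tissue fraction |mask| / (h*w)."""
    image = _as_image(image)
    mask = np.asarray(mask, dtype=bool)
    return ImageStats(
        mean_gray=float(image.mean()),
        sd_gray=float(image.std()),
        tissue_fraction=float(mask.sum() / mask.size),
    )


def preprocess_pipeline(image, *, clip_limit: float = 0.01,
                        tile_grid: tuple[int, int] = (8, 8),
                        out_shape: tuple[int, int] = DEFAULT_OUT_SHAPE,
                        image_id: str | None = None) -> PipelineResult:
    """Run the full cleaning chain on one 8-bit grayscale image.

    Order: overexposure rejection -> binarize -> largest component -> mask ->
    CLAHE -> orient left -> resize+normalize.  Rejection is a typed outcome
    (``rejected=True``), not an error.  Image statistics are computed on the
    cleaned, CLAHE-equalized, left-oriented image at native resolution.
    """
    image = _as_image(image)
    steps = ["reject_overexposed"]
    if reject_overexposed(image):
        return PipelineResult(rejected=True, steps=("reject_overexposed",))
    mask = largest_component(binarize_mask(image))
    steps += ["binarize_mask", "largest_component", "apply_mask", "clahe", "orient_left"]
    cleaned = apply_mask(image, mask)
    equalized = apply_mask(clahe(cleaned, clip_limit, tile_grid), mask)
    oriented, mask = orient_left(equalized, mask)
    stats = image_stats(oriented, mask)
    steps.append("resize_normalize")
    processed = resize_normalize(
        oriented, out_shape,
        provenance={"image_id": image_id, "steps": tuple(steps)},
    )
    return PipelineResult(rejected=False, processed=processed, stats=stats,
                          steps=tuple(steps))
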