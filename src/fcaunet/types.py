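"""Core domain containers shared across the toolkit.

Grayscale images are plain 2-D integer :class:`numpy.ndarray` grids
(row-major, origin top-left) with an associated gray-level count ``GL``
(256 for 8-bit ultrasound frames).  Masks are binary arrays of the same
shape.  A :class:`LabeledSample` carries an image through the pipeline
together with its class label, optional ground-truth follicle mask and
provenance (original acquisition vs augmented copy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Recognised class labels; the positive class for all metrics is "infected".
LABELS = ("healthy", "infected")

HEALTHY = "healthy"
INFECTED = "infected"


def validate_gray_image(image: np.ndarray, gray_levels: int = 256) -> np.ndarray:
    """Validate a 2-D integer intensity grid and return it as an ndarray.

    Raises ``ValueError`` when the array is not 2-D, is empty, or holds
    values outside ``[0, gray_levels - 1]``.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"gray image must be 2-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("gray image must be nonempty")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("gray image must hold integer intensities")
        arr = np.round(arr).astype(np.int64)
    if arr.min() < 0 or arr.max() > gray_levels - 1:
        raise ValueError(
            f"pixel values must lie in [0, {gray_levels - 1}], "
            f"got range [{arr.min()}, {arr.max()}]"
        )
    return arr


def validate_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Validate a binary mask against the owning image's shape."""
    m = np.asarray(mask)
    if m.shape != tuple(shape):
        raise ValueError(f"mask shape {m.shape} != image shape {tuple(shape)}")
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask values must be in {0, 1}")
    return m.astype(np.uint8)


@dataclass
class LabeledSample:
    """An image plus label, optional follicle mask and provenance.

    ``source_id`` identifies the original acquisition a sample derives
    from; augmented copies inherit the parent's ``source_id`` so that
    leakage-safe splitting can group a family of images together.
    """

    image: np.ndarray
    label: str
    mask: Optional[np.ndarray] = None
    origin: str = "original"
    source_id: str = ""
    gray_levels: int = 256

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.origin not in ("original", "augmented"):
            raise ValueError(f"origin must be 'original' or 'augmented', got {self.origin!r}")
        self.image = validate_gray_image(self.image, self.gray_levels)
        if self.mask is not None:
            self.mask = validate_mask(self.mask, self.image.shape)

    def with_transform(self, fn, origin: str = "augmented") -> "LabeledSample":
        """Apply ``fn`` to image (and mask, identically) and return a copy."""
        new_mask = None if self.mask is None else validate_mask(fn(self.mask), fn(self.image).shape)
        return replace(self, image=fn(self.image), mask=new_mask, origin=origin)


@dataclass(frozen=True)
class AugmentationSpec:
    """Geometric fan-out applied to every original image.

    Defaults reproduce the study conditions: one horizontal flip, one
    vertical flip and twelve signed rotations, i.e. 14 augmented images
    per original.  Signed 180-degree (and 225/-135 etc.) pairs coincide
    geometrically but are enumerated literally so the fan-out stays 14.
    """

    do_hflip: bool = True
    do_vflip: bool = True
    rotation_angles: tuple[float, ...] = (
        45, -45, 90, -90, 135, -135, 180, -180, 225, -225, 270, -270,
    )
    interpolation: str = "nearest"  # 90-degree multiples stay exact permutations
    fill_value: int = 0

    @property
    def fan_out(self) -> int:
        return int(self.do_hflip) + int(self.do_vflip) + len(self.rotation_angles)

    def __post_init__(self) -> None:
        if self.interpolation not in ("nearest", "bilinear"):
            raise ValueError("interpolation must be 'nearest' or 'bilinear'")


@dataclass(frozen=True)
class SplitPlan:
    """Leakage-safe train/val/test split parameters.

    The test set is drawn from original images only (stratified by
    label); the val split is taken per source image so an original and
    its augmented copies never straddle train and val.
    """

    test_fraction: float = 0.2
    val_fraction: float = 0.2
    seed: int = 0
    stratify_by_label: bool = True

    def __post_init__(self) -> None:
        for name, frac in (("test_fraction", self.test_fraction),
                           ("val_fraction", self.val_fraction)):
            if not 0.0 < frac < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {frac}")
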