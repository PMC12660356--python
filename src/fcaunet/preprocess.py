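"""Dataset preparation: contour cropping, geometric augmentation, splitting.

The preparation chain mirrors a standard ultrasound-classification
workflow: each frame is cropped to the bounding box of its largest
bright contour (the fan-shaped scan region), every original image is
fanned out into 14 geometric variants (horizontal flip, vertical flip,
twelve signed rotations), and the dataset is split so that the test set
contains only original images while an original and its augmented
copies never straddle the train/val boundary.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .types import AugmentationSpec, LabeledSample, SplitPlan, validate_gray_image

__all__ = [
    "crop_to_largest_contour",
    "flip_h",
    "flip_v",
    "rotate",
    "augment_sample",
    "split_dataset",
]


def crop_to_largest_contour(
    image: np.ndarray,
    binarize_threshold: Optional[float] = None,
    gray_levels: int = 256,
) -> np.ndarray:
    """Crop to the extreme points of the largest bright contour.

    The image is binarized (Otsu threshold by default), 8-connected
    components of the foreground are extracted, and the axis-aligned
    box spanned by the top/bottom/left/right extreme points of the
    largest-area component is returned.  Area ties break toward the
    component appearing first in row-major scan order.  If no
    foreground pixel exists the input is returned unchanged.
    """
    img = validate_gray_image(image, gray_levels)
    if binarize_threshold is None:
        if img.min() == img.max():
            return img  # constant image: no contour is defined
        binarize_threshold = threshold_otsu(img)
    fg = img > binarize_threshold
    if not fg.any():
        return img
    labels = cc_label(fg, connectivity=2)  # 8-connectivity
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    # labels are assigned in raster order, argmax takes the first max
    biggest = int(np.argmax(areas))
    rows, cols = np.nonzero(labels == biggest)
    return img[rows.min():rows.max() + 1, cols.min():cols.max() + 1]


def flip_h(image: np.ndarray) -> np.ndarray:
    """Mirror columns: pixel (r, c) moves to (r, W-1-c)."""
    return np.asarray(image)[:, ::-1].copy()


def flip_v(image: np.ndarray) -> np.ndarray:
    """Mirror rows: pixel (r, c) moves to (H-1-r, c)."""
    return np.asarray(image)[::-1, :].copy()


def rotate(
    image: np.ndarray,
    theta_degrees: float,
    spec: AugmentationSpec = AugmentationSpec(),
) -> np.ndarray:
    """Rotate about the image center, preserving shape.

    Positive angles rotate counter-clockwise in the standard image
    convention (+90 degrees maps a pixel at centered coordinates
    (r, c) to (-c, r), i.e. ``np.rot90``).  Out-of-frame pixels take
    ``spec.fill_value``.  Multiples of 90 degrees are dispatched to
    exact index permutations so they are lossless for square images;
    other angles resample with nearest-neighbor or bilinear
    interpolation per ``spec.interpolation``.
    """
    img = np.asarray(image)
    theta = float(theta_degrees) % 360.0
    if theta == 0.0:
        return img.copy()
    if img.shape[0] == img.shape[1] and theta in (90.0, 180.0, 270.0):
        return np.rot90(img, k=int(theta // 90)).copy()
    order = 0 if spec.interpolation == "nearest" else 1
    out = ndi.rotate(
        img.astype(np.float64),
        angle=theta,
        reshape=False,
        order=order,
        mode="constant",
        cval=float(spec.fill_value),
        prefilter=False,
    )
    out = np.round(out)
    info_max = img.max(initial=spec.fill_value)
    info_min = min(int(img.min(initial=spec.fill_value)), int(spec.fill_value))
    return np.clip(out, info_min, info_max).astype(img.dtype)


def augment_sample(
    sample: LabeledSample, spec: AugmentationSpec = AugmentationSpec()
) -> list[LabeledSample]:
    """Fan an original sample out into its augmented variants.

    Produces, in order: horizontal flip, vertical flip, then the signed
    rotations in ``spec.rotation_angles`` order.  Labels and source ids
    are inherited; masks (when present) receive the identical geometric
    transform.  The default spec yields exactly 14 outputs per
    original.
    """
    if sample.origin != "original":
        raise ValueError("augment_sample expects an original sample")
    declared = int(spec.do_hflip) + int(spec.do_vflip) + len(spec.rotation_angles)
    if spec.fan_out != declared:
        raise ValueError("augmentation spec fan-out mismatch")
    out: list[LabeledSample] = []
    if spec.do_hflip:
        out.append(sample.with_transform(flip_h))
    if spec.do_vflip:
        out.append(sample.with_transform(flip_v))
    for theta in spec.rotation_angles:
        out.append(sample.with_transform(lambda a, t=theta: rotate(a, t, spec)))
    return out


def _pick(rng: np.random.Generator, items: list, k: int) -> tuple[list, list]:
    idx = rng.permutation(len(items))
    chosen = [items[i] for i in idx[:k]]
    rest = [items[i] for i in idx[k:]]
    return chosen, rest


def split_dataset(
    samples: Sequence[LabeledSample], plan: SplitPlan
) -> tuple[list[LabeledSample], list[LabeledSample], list[LabeledSample]]:
    """Split into (train, val, test) without augmentation leakage.

    The test set is drawn from original images only, stratified per
    class by default; the remaining originals plus all their augmented
    copies form the train+val pool, which is split at
    ``plan.val_fraction`` *by source image* so a family never straddles
    train and val.  Deterministic under ``plan.seed``.

    Augmented copies whose source was held out for testing would leak
    test content into training; if any exist they are excluded from all
    three partitions with a warning (the intended workflow augments
    only after the test split).
    """
    samples = list(samples)
    originals = [s for s in samples if s.origin == "original"]
    augmented = [s for s in samples if s.origin == "augmented"]
    if not originals:
        raise ValueError("split requires at least one original sample")
    known = {s.source_id for s in originals}
    orphans = {s.source_id for s in augmented} - known
    if orphans:
        raise ValueError(f"augmented samples reference unknown sources: {sorted(orphans)[:5]}")

    rng = np.random.default_rng(plan.seed)
    groups: dict[str, list[LabeledSample]] = {}
    if plan.stratify_by_label:
        for s in originals:
            groups.setdefault(s.label, []).append(s)
    else:
        groups["all"] = originals

    test: list[LabeledSample] = []
    pool_sources_by_group: dict[str, list[str]] = {}
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda s: s.source_id)
        n_test = int(round(plan.test_fraction * len(members)))
        if n_test < 1 or n_test >= len(members):
            raise ValueError(
                f"cannot draw a stratified test set for group {key!r} "
                f"({len(members)} originals, test_fraction {plan.test_fraction})"
            )
        chosen, rest = _pick(rng, members, n_test)
        test.extend(chosen)
        pool_sources_by_group[key] = [s.source_id for s in rest]

    test_sources = {s.source_id for s in test}
    leaked = [s for s in augmented if s.source_id in test_sources]
    if leaked:
        warnings.warn(
            f"{len(leaked)} augmented copies of held-out test originals were "
            "excluded from every partition; augment after splitting to avoid this.",
            stacklevel=2,
        )

    train_sources: set[str] = set()
    val_sources: set[str] = set()
    for key in sorted(pool_sources_by_group):
        sources = sorted(pool_sources_by_group[key])
        n_val = int(round(plan.val_fraction * len(sources)))
        chosen, rest = _pick(rng, sources, n_val)
        val_sources.update(chosen)
        train_sources.update(rest)

    by_source: dict[str, list[LabeledSample]] = {}
    for s in samples:
        by_source.setdefault(s.source_id, []).append(s)
    train = [s for sid in sorted(train_sources) for s in by_source[sid]]
    val = [s for sid in sorted(val_sources) for s in by_source[sid]]
    return train, val, test
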