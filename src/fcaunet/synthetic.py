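"""Seeded ovarian-ultrasound phantoms with ground-truth follicle masks.

Each phantom is a speckled grayscale field containing a darker
elliptical ovary; hypoechoic (dark) disc follicles are placed inside
the ovary.  The two classes differ in follicular morphology the way
clinical ultrasound does: healthy ovaries carry a few large follicles,
polycystic ovaries carry many small follicles arranged near the ovary
boundary (the "string of pearls" sign).  Speckle is multiplicative
gamma noise, the characteristic interference pattern of ultrasound.

In *easy* mode the class-conditional follicle-count ranges are
disjoint, so the classes are perfectly separable by construction; in
*hard* mode the ranges overlap and the contrast gap narrows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .types import HEALTHY, INFECTED, LABELS, LabeledSample

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "low_contrast_fixture"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, class morphology and noise of the phantom generator.

    Follicle-count ranges are inclusive.  Defaults give the easy-mode
    study conditions: healthy 1-3 large central follicles, infected
    8-15 small peripheral follicles, disjoint by construction.
    """

    image_size: tuple[int, int] = (64, 64)
    ovary_axes_frac: tuple[float, float] = (0.62, 0.78)  # semi-axes / half-size
    healthy_count: tuple[int, int] = (1, 3)
    infected_count: tuple[int, int] = (8, 15)
    healthy_radius_frac: tuple[float, float] = (0.09, 0.14)  # of min(H, W)
    infected_radius_frac: tuple[float, float] = (0.03, 0.05)
    background_level: int = 150
    ovary_offset: int = -30      # ovary tissue relative to background
    follicle_level: int = 30     # dark fluid-filled interior
    speckle_shape: float = 4.0   # gamma shape; lower = grainier
    mode: str = "easy"
    max_place_tries: int = 2000

    def __post_init__(self):
        h, w = self.image_size
        if h % 4 or w % 4:
            raise ValueError("image size must be divisible by 4")
        if self.mode not in ("easy", "hard"):
            raise ValueError("mode must be 'easy' or 'hard'")
        if self.mode == "easy" and self.infected_count[0] <= self.healthy_count[1]:
            raise ValueError("easy mode requires disjoint follicle-count ranges")

    def count_range(self, label: str) -> tuple[int, int]:
        lo, hi = self.healthy_count if label == HEALTHY else self.infected_count
        if self.mode == "hard":
            # overlap the ranges: stretch each toward the other class
            mid = (self.healthy_count[1] + self.infected_count[0]) // 2
            if label == HEALTHY:
                hi = max(hi, mid + 1)
            else:
                lo = min(lo, mid)
        return lo, hi

    def radius_range(self, label: str) -> tuple[float, float]:
        frac = self.healthy_radius_frac if label == HEALTHY else self.infected_radius_frac
        s = min(self.image_size)
        return frac[0] * s, frac[1] * s


def generate_phantom(
    label: str, spec: PhantomSpec = PhantomSpec(), seed: int = 0
) -> LabeledSample:
    """One phantom: speckled ovary image plus the binary follicle mask."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    rng = np.random.default_rng(seed)
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay = spec.ovary_axes_frac[0] * h / 2 * rng.uniform(0.92, 1.0)
    ax = spec.ovary_axes_frac[1] * w / 2 * rng.uniform(0.92, 1.0)
    ovary = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    base = np.full((h, w), float(spec.background_level))
    base[ovary] += spec.ovary_offset

    lo, hi = spec.count_range(label)
    n_foll = int(rng.integers(lo, hi + 1))
    rmin, rmax = spec.radius_range(label)
    # hard mode can inflate healthy counts; keep total follicle area sane
    if n_foll > max(spec.healthy_count[1], 1) and label == HEALTHY:
        shrink = spec.healthy_count[1] / n_foll
        rmin, rmax = rmin * shrink, rmax * shrink

    def try_layout(layout_rng: np.random.Generator):
        mask = np.zeros((h, w), dtype=np.uint8)
        fill = np.zeros((h, w), dtype=bool)
        centers: list[tuple[float, float, float]] = []
        for attempt in range(spec.max_place_tries):
            if len(centers) == n_foll:
                return mask, fill
            # shrink radii toward the feasible end as attempts accumulate
            squeeze = (1.0, 0.6, 0.35)[min(3 * attempt // spec.max_place_tries, 2)]
            r = layout_rng.uniform(rmin, rmin + (rmax - rmin) * squeeze)
            if label == INFECTED:
                # peripheral band: the string-of-pearls arrangement
                ang = layout_rng.uniform(0, 2 * math.pi)
                rad = layout_rng.uniform(0.45, 0.92)
                fy = cy + rad * (ay - r) * math.sin(ang)
                fx = cx + rad * (ax - r) * math.cos(ang)
            else:
                fy = cy + layout_rng.uniform(-0.55, 0.55) * ay
                fx = cx + layout_rng.uniform(-0.55, 0.55) * ax
            if (ay - r) <= 0 or (ax - r) <= 0:
                continue
            # keep the disc strictly inside the ovary ellipse
            if (((fy - cy) / (ay - r)) ** 2 + ((fx - cx) / (ax - r)) ** 2) > 1.0:
                continue
            # pairwise separation keeps mask components distinct
            if any(math.hypot(fy - py, fx - px) < r + pr + 2.0
                   for py, px, pr in centers):
                continue
            disc = (yy - fy) ** 2 + (xx - fx) ** 2 <= r * r
            fill |= disc
            mask |= disc.astype(np.uint8)
            centers.append((fy, fx, r))
        return None

    result = try_layout(rng)
    relayout = 0
    while result is None and relayout < 8:
        relayout += 1  # deterministic fresh layout stream
        result = try_layout(np.random.default_rng([seed, relayout]))
    if result is None:
        raise RuntimeError(
            f"could not place {n_foll} follicles inside the ovary "
            f"after {spec.max_place_tries} tries x {relayout + 1} layouts (seed {seed})"
        )
    mask, fill = result
    base[fill] = spec.follicle_level

    speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, size=(h, w))
    img = np.clip(np.round(base * speckle), 0, 255).astype(np.int64)
    return LabeledSample(image=img, label=label, mask=mask,
                         origin="original", source_id=f"{label}-{seed:08d}")


def generate_dataset(
    n_per_class: int,
    spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> list[LabeledSample]:
    """Balanced phantom dataset with unique source ids, seed-deterministic."""
    rng = np.random.default_rng(seed)
    # distinct per-sample seeds derived from the master seed
    sub = rng.integers(0, 2**31 - 1, size=2 * n_per_class)
    samples = []
    k = 0
    for label in LABELS:
        for _ in range(n_per_class):
            samples.append(generate_phantom(label, spec, seed=int(sub[k])))
            k += 1
    return samples


def manifest_frame(samples, split: Optional[dict] = None) -> pd.DataFrame:
    """Manifest rows (path,label,origin,source_id,split) for a sample list."""
    rows = []
    for i, s in enumerate(samples):
        rows.append({
            "path": f"{s.source_id}-{s.origin}-{i:06d}.png",
            "label": s.label,
            "origin": s.origin,
            "source_id": s.source_id,
            "split": (split or {}).get(id(s), ""),
        })
    return pd.DataFrame(rows)


def low_contrast_fixture(
    size: tuple[int, int] = (64, 64), seed: int = 0
) -> np.ndarray:
    """A dark, narrow-band image for exercising the enhancement chain.

    Intensities occupy roughly the lowest 5% of the 8-bit range, with
    the bulk of the pixels tied at the darkest occupied level and a
    spatial gradient in the remainder -- the regime where global
    equalization pins the dominant dark level to 0 while the
    clip-limited adaptive variant lifts it, and the fuzzy enhancer
    (whose memberships sit above the crossover) brightens strongly.
    """
    rng = np.random.default_rng(seed)
    h, w = size
    img = np.full((h, w), 6, dtype=np.int64)
    detail = rng.random((h, w)) < 0.35
    ramp = (np.linspace(0, 1, w)[None, :] + np.linspace(0, 1, h)[:, None]) / 2
    vals = 7 + np.round(ramp * 6 + rng.integers(0, 3, size=(h, w))).astype(np.int64)
    img[detail] = vals[detail]
    return img
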