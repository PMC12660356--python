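"""Brightness-enhancement operators and their selection machinery.

Three enhancers are provided, all monotone lookup-table maps on gray
levels:

* :func:`equalize_histogram` -- global histogram equalization via the
  cumulative distribution function.
* :func:`clahe` -- contrast-limited adaptive histogram equalization:
  per-tile equalization with histogram counts clipped at a fraction
  ``Q`` of the tile pixel count, the clipped excess redistributed
  uniformly over all gray levels, and bilinear blending between
  neighbouring tile mappings.
* :func:`fce` -- fuzzy contrast enhancement: gray levels are fuzzified
  into memberships, pushed away from the 0.5 crossover by the
  intensification operator, and defuzzified back to gray levels.

A simple atmospheric-style intensity model scores the candidates and
:func:`select_highest_intensity` keeps the brightest one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .types import validate_gray_image

__all__ = [
    "FCEParams",
    "ClaheParams",
    "IntensityModel",
    "equalize_histogram",
    "clahe",
    "fuzzify",
    "intensify",
    "defuzzify",
    "fce",
    "brightness_percent",
    "scene_intensity",
    "select_highest_intensity",
    "psnr",
]


@dataclass(frozen=True)
class FCEParams:
    """Fuzzifier constants and gray-level bounds of the fuzzy enhancer.

    ``fe`` (exponential fuzzifier) and ``fd`` (denominational fuzzifier)
    control the amount of grayness retained: membership of gray level
    ``gl`` is ``[1 + (gl_max - gl)/fd]**(-fe)``.  The default ``fd`` of
    8*(GL-1) keeps memberships well above the 0.5 crossover so dark
    ultrasound frames are lifted toward the bright end, matching the
    enhancer's role as the brightness-maximising candidate.
    ``crossover_n`` is the gray level mapped from membership 0.5; when
    ``None`` it defaults to the image's median gray level.
    """

    fe: float = 1.0
    fd: float = 2040.0
    gl_min: int = 0
    gl_max: int = 255
    crossover_n: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fd <= 0 or self.fe <= 0:
            raise ValueError("fuzzifiers FE and FD must be positive")
        if self.crossover_n is not None and not (
            self.gl_min < self.crossover_n < self.gl_max
        ):
            raise ValueError("gl_min < crossover_n < gl_max required")


@dataclass(frozen=True)
class ClaheParams:
    """Tile layout and clip fraction for adaptive equalization."""

    tile_shape: tuple[int, int] = (8, 8)
    clip_fraction: float = 0.2  # of the tile pixel count; 1 = unlimited stretch

    def __post_init__(self) -> None:
        if not 0.0 < self.clip_fraction <= 1.0:
            raise ValueError("clip fraction Q must lie in (0, 1]")
        if min(self.tile_shape) < 1:
            raise ValueError("tile shape must be positive")


@dataclass(frozen=True)
class IntensityModel:
    """Scene-radiance intensity model with exponential transmission.

    Transmission ``t = exp(-beta * d)`` attenuates with the
    color-density coefficient ``beta`` and distance factor ``d``; the
    validated intensity is ``SR + L_alpha * (1 - t)`` where ``SR`` is
    the scene radiance and ``L_alpha`` the scattering coefficient.
    """

    beta: float = 1.0
    d: float = 1.0
    sr: Optional[float] = None       # None: use image mean
    l_alpha: Optional[float] = None  # None: use image standard deviation

    def __post_init__(self) -> None:
        if self.beta < 0 or self.d < 0:
            raise ValueError("beta and d must be non-negative")


def _hist_mapping(hist: np.ndarray, gray_levels: int) -> np.ndarray:
    """Equalization lookup table from a (possibly fractional) histogram.

    Uses the classic normalized-cdf map
    ``round((cdf - cdf_min)/(N - cdf_min) * (GL - 1))``.  A histogram
    with a single occupied integer level yields the identity map (a
    constant region carries no contrast to stretch).
    """
    n = hist.sum()
    cdf = np.cumsum(hist)
    occupied = np.nonzero(hist)[0]
    if occupied.size <= 1:
        return np.arange(gray_levels)
    cdf_min = cdf[occupied[0]]
    denom = n - cdf_min
    if denom <= 0:
        return np.arange(gray_levels)
    lut = np.floor((cdf - cdf_min) / denom * (gray_levels - 1) + 0.5)
    return np.clip(lut, 0, gray_levels - 1).astype(np.int64)


def equalize_histogram(image: np.ndarray, gray_levels: int = 256) -> np.ndarray:
    """Global histogram equalization (monotone LUT; constant images pass through)."""
    if gray_levels < 2:
        raise ValueError("need at least two gray levels")
    img = validate_gray_image(image, gray_levels)
    hist = np.bincount(img.ravel(), minlength=gray_levels).astype(np.float64)
    return _hist_mapping(hist, gray_levels)[img]


def _clipped_hist(values: np.ndarray, q: float, gray_levels: int) -> np.ndarray:
    hist = np.bincount(values.ravel(), minlength=gray_levels).astype(np.float64)
    clip = q * values.size
    excess = np.maximum(hist - clip, 0.0).sum()
    hist = np.minimum(hist, clip)
    hist += excess / gray_levels  # uniform single-pass redistribution
    return hist


def clahe(
    image: np.ndarray,
    params: ClaheParams = ClaheParams(),
    gray_levels: int = 256,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is padded (edge replication) so tiles cover it evenly;
    each tile's histogram is clipped at ``Q * tile_pixels`` with the
    excess spread uniformly over all gray levels, equalized with the
    same cdf map as :func:`equalize_histogram`, and per-pixel outputs
    are bilinearly blended between the four nearest tile mappings.
    With ``Q = 1`` and a single whole-image tile this reduces exactly
    to global equalization.
    """
    img = validate_gray_image(image, gray_levels)
    th, tw = params.tile_shape
    h, w = img.shape
    if th > h or tw > w:
        raise ValueError(f"tile {params.tile_shape} larger than image {img.shape}")
    nty, ntx = math.ceil(h / th), math.ceil(w / tw)
    pad_h, pad_w = nty * th - h, ntx * tw - w
    padded = np.pad(img, ((0, pad_h), (0, pad_w)), mode="edge")

    luts = np.empty((nty, ntx, gray_levels), dtype=np.float64)
    for ty in range(nty):
        for tx in range(ntx):
            tile = padded[ty * th:(ty + 1) * th, tx * tw:(tx + 1) * tw]
            if tile.min() == tile.max():
                luts[ty, tx] = np.arange(gray_levels)  # constant tile: identity
            else:
                hist = _clipped_hist(tile, params.clip_fraction, gray_levels)
                luts[ty, tx] = _hist_mapping(hist, gray_levels)

    if nty == ntx == 1:
        out = luts[0, 0][padded].astype(np.int64)
        return out[:h, :w]

    ph, pw = padded.shape
    ys = (np.arange(ph) + 0.5) / th - 0.5  # position in tile-center units
    xs = (np.arange(pw) + 0.5) / tw - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, nty - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, ntx - 1)
    y1 = np.minimum(y0 + 1, nty - 1)
    x1 = np.minimum(x0 + 1, ntx - 1)
    wy = np.clip(ys - y0, 0.0, 1.0)[:, None]
    wx = np.clip(xs - x0, 0.0, 1.0)[None, :]

    v = padded
    gy0 = y0[:, None]
    gy1 = y1[:, None]
    gx0 = x0[None, :].repeat(ph, axis=0)
    gx1 = x1[None, :].repeat(ph, axis=0)
    m00 = luts[gy0.repeat(pw, axis=1), gx0, v]
    m01 = luts[gy0.repeat(pw, axis=1), gx1, v]
    m10 = luts[gy1.repeat(pw, axis=1), gx0, v]
    m11 = luts[gy1.repeat(pw, axis=1), gx1, v]
    blended = ((1 - wy) * ((1 - wx) * m00 + wx * m01)
               + wy * ((1 - wx) * m10 + wx * m11))
    out = np.clip(np.floor(blended + 0.5), 0, gray_levels - 1).astype(np.int64)
    return out[:h, :w]


def fuzzify(gl, p: FCEParams):
    """Gray level -> fuzzy membership, ``[1 + (gl_max - gl)/FD]**(-FE)``."""
    if p.fd <= 0:
        raise ValueError("FD must be positive")
    gl = np.asarray(gl, dtype=np.float64)
    if np.any(gl < p.gl_min) or np.any(gl > p.gl_max):
        raise ValueError(f"gray level outside [{p.gl_min}, {p.gl_max}]")
    return (1.0 + (p.gl_max - gl) / p.fd) ** (-p.fe)


def intensify(mu):
    """Intensification operator: push memberships away from the 0.5 crossover.

    ``2*mu**2`` below the crossover, ``1 - 2*(1 - mu)**2`` above; fixed
    points are 0, 0.5 and 1 and the range stays [0, 1].
    """
    mu = np.asarray(mu, dtype=np.float64)
    if np.any(mu < 0) or np.any(mu > 1):
        raise ValueError("membership must lie in [0, 1]")
    return np.where(mu <= 0.5, 2.0 * mu**2, 1.0 - 2.0 * (1.0 - mu) ** 2)


def defuzzify(mu, p: FCEParams, crossover: Optional[float] = None):
    """Membership -> gray level around the crossover ``n`` (round half-up)."""
    mu = np.asarray(mu, dtype=np.float64)
    if np.any(mu < 0) or np.any(mu > 1):
        raise ValueError("membership must lie in [0, 1]")
    n = crossover if crossover is not None else p.crossover_n
    if n is None:
        raise ValueError("crossover level n is required for defuzzification")
    out = np.where(
        mu <= 0.5,
        n - (n - p.gl_min) * (1.0 - 2.0 * mu),
        n + (p.gl_max - n) * (2.0 * mu - 1.0),
    )
    out = np.clip(out, p.gl_min, p.gl_max)
    return np.floor(out + 0.5).astype(np.int64)


def fce(
    image: np.ndarray, p: FCEParams = FCEParams(), gray_levels: int = 256
) -> np.ndarray:
    """Fuzzy contrast enhancement: defuzzify(intensify(fuzzify(gl))) per level.

    The composition is evaluated once per gray level (lookup-table
    semantics), so identical input levels always map identically and
    the map is monotone.
    """
    img = validate_gray_image(image, gray_levels)
    n = p.crossover_n if p.crossover_n is not None else float(np.median(img))
    n = min(max(n, p.gl_min + 0.5), p.gl_max - 0.5)
    levels = np.arange(gray_levels, dtype=np.float64)
    levels_c = np.clip(levels, p.gl_min, p.gl_max)
    lut = defuzzify(intensify(fuzzify(levels_c, p)), p, crossover=n)
    return lut[img]


def brightness_percent(image: np.ndarray, gray_levels: int = 256) -> float:
    """Mean intensity as a percentage of the full gray-level range."""
    img = validate_gray_image(image, gray_levels)
    return 100.0 * float(img.mean()) / (gray_levels - 1)


def scene_intensity(image: np.ndarray, m: IntensityModel = IntensityModel()) -> float:
    """Validated pixel intensity ``SR + L_alpha * (1 - exp(-beta*d))``."""
    img = np.asarray(image, dtype=np.float64)
    sr = float(img.mean()) if m.sr is None else m.sr
    l_alpha = float(img.std()) if m.l_alpha is None else m.l_alpha
    t = math.exp(-m.beta * m.d)
    return sr + l_alpha * (1.0 - t)


#: Fixed tie-break order when candidate scores coincide.
_TAG_ORDER = {"he": 0, "clahe": 1, "fce": 2}


def select_highest_intensity(
    candidates: Mapping[str, np.ndarray], m: IntensityModel = IntensityModel()
) -> str:
    """Return the tag of the candidate with the highest scene intensity.

    Ties break toward the later entry in the fixed order
    HE < CLAHE < FCE (unknown tags sort before known ones).
    """
    if not candidates:
        raise ValueError("need at least one candidate image")
    best_tag, best_key = None, None
    for tag, img in candidates.items():
        key = (scene_intensity(img, m), _TAG_ORDER.get(tag, -1))
        if best_key is None or key >= best_key:
            best_tag, best_key = tag, key
    return best_tag


def psnr(image: np.ndarray, reference: np.ndarray, gray_levels: int = 256) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    a = np.asarray(image, dtype=np.float64)
    b = np.asarray(reference, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * math.log10((gray_levels - 1) ** 2 / mse)
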