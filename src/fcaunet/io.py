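"""Image and manifest I/O.

Images are 8-bit grayscale PNG/JPEG/TIFF; masks are 8-bit PNG with
{0, 255} mapped to {0, 1}.  Dataset manifests are CSV files with
columns ``path,label,origin,source_id,split``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .types import LABELS, LabeledSample

MANIFEST_COLUMNS = ["path", "label", "origin", "source_id", "split"]


def read_image(path) -> np.ndarray:
    """Load an image as an 8-bit grayscale grid.

    Color inputs are converted by luma weighting (with a warning);
    16-bit inputs are rescaled to 8-bit (with a warning).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    img = Image.open(p)
    if img.mode in ("RGB", "RGBA", "P"):
        warnings.warn(f"{p.name}: color image converted to grayscale by luma weighting",
                      stacklevel=2)
        img = img.convert("L")
        arr = np.asarray(img, dtype=np.int64)
    elif img.mode in ("I", "I;16", "I;16B"):
        warnings.warn(f"{p.name}: 16-bit image rescaled to 8-bit", stacklevel=2)
        arr = np.asarray(img, dtype=np.float64)
        arr = np.round(arr / 65535.0 * 255.0).astype(np.int64)
    else:
        arr = np.asarray(img.convert("L"), dtype=np.int64)
    return arr


def write_image(image: np.ndarray, path) -> None:
    arr = np.asarray(image)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("8-bit output requires values in [0, 255]")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def read_mask(path) -> np.ndarray:
    arr = read_image(path)
    return (arr >= 128).astype(np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    write_image(np.asarray(mask) * 255, path)


def write_manifest(df: pd.DataFrame, path) -> None:
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    bad = df[~df["label"].isin(LABELS)]
    if len(bad):
        row = bad.index[0]
        raise ValueError(f"manifest row {row}: unknown label {bad.iloc[0]['label']!r}")
    dup = df["path"].duplicated()
    if dup.any():
        raise ValueError(f"manifest row {int(np.argmax(dup.values))}: duplicate path "
                         f"{df.loc[dup, 'path'].iloc[0]!r}")
    return df


def save_dataset(samples: Sequence[LabeledSample], out_dir,
                 splits: Optional[dict[int, str]] = None) -> pd.DataFrame:
    """Write images (+masks) and the manifest CSV; returns the manifest."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        name = f"{s.source_id}-{s.origin}-{i:06d}.png"
        write_image(s.image, out / "images" / name)
        if s.mask is not None:
            write_mask(s.mask, out / "masks" / name)
        rows.append({"path": f"images/{name}", "label": s.label,
                     "origin": s.origin, "source_id": s.source_id,
                     "split": (splits or {}).get(i, "")})
    df = pd.DataFrame(rows)
    write_manifest(df, out / "manifest.csv")
    return df


def load_dataset(root) -> list[LabeledSample]:
    """Load samples listed in ``root/manifest.csv`` (masks when present)."""
    root = Path(root)
    df = read_manifest(root / "manifest.csv")
    samples = []
    for _, row in df.iterrows():
        img = read_image(root / row["path"])
        mask_path = root / row["path"].replace("images/", "masks/")
        mask = read_mask(mask_path) if mask_path.exists() and "images/" in row["path"] else None
        samples.append(LabeledSample(image=img, label=row["label"],
                                     mask=mask, origin=row["origin"] or "original",
                                     source_id=row["source_id"]))
    return samples
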