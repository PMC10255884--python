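"""Image/mask I/O, mean-shift preprocessing and dataset indexing.

Masks follow the PMD2023 two-color convention: marbling foreground is
RGB (128, 0, 0), everything else (lean and the board) is (0, 0, 0).
Images are stored row-major with the origin at the top-left; all
coordinates are 0-based half-open ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["FOREGROUND_RGB", "BACKGROUND_RGB", "load_image", "save_image",
           "load_mask", "save_mask", "mean_shift_filter", "make_folds",
           "crop", "DatasetRecord", "DatasetIndex"]

FOREGROUND_RGB = (128, 0, 0)
BACKGROUND_RGB = (0, 0, 0)


class MaskFormatError(ValueError):
    """A mask pixel matches neither palette color."""


def load_image(path) -> np.ndarray:
    """Read a JPEG/PNG image as an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def save_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def load_mask(path, foreground: tuple = FOREGROUND_RGB,
              background: tuple = BACKGROUND_RGB, tolerance: int = 0) -> np.ndarray:
    """Read a two-color palette/RGB mask into a {0,1} uint8 label grid.

    Matching is exact on (R, G, B) by default; ``tolerance`` (per-channel
    max deviation) accommodates JPEG-compressed masks.  A pixel matching
    neither palette entry raises :class:`MaskFormatError` naming the
    offending color.
    """
    rgb = load_image(path)
    fg = np.abs(rgb.astype(int) - np.array(foreground)).max(axis=2) <= tolerance
    bg = np.abs(rgb.astype(int) - np.array(background)).max(axis=2) <= tolerance
    bad = ~(fg | bg)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        color = tuple(int(v) for v in rgb[i, j])
        raise MaskFormatError(
            f"{path}: pixel at ({i}, {j}) has color {color}, which matches "
            f"neither foreground {foreground} nor background {background}")
    return fg.astype(np.uint8)


def save_mask(path, mask: np.ndarray, foreground: tuple = FOREGROUND_RGB,
              background: tuple = BACKGROUND_RGB) -> None:
    """Write a {0,1} mask as a palette PNG under the two-color convention."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be 0 or 1")
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = list(background) + list(foreground) + [0] * (254 * 3)
    im.putpalette(palette)
    im.save(path)


def crop(image: np.ndarray, rect: tuple[int, int, int, int]) -> np.ndarray:
    """Crop (top, left, height, width) from an image or mask (0-based, half-open)."""
    top, left, height, width = rect
    h, w = image.shape[:2]
    if not (0 <= top < top + height <= h and 0 <= left < left + width <= w):
        raise ValueError(f"rect {rect} outside image of size {h}x{w}")
    return image[top:top + height, left:left + width].copy()


def mean_shift_filter(image: np.ndarray, spatial_radius: int = 5,
                      color_radius: float = 10, max_iter: int = 5,
                      tol: float = 0.5) -> np.ndarray:
    """Edge-preserving mean-shift smoothing (Comaniciu–Meer style).

    Each pixel's color iteratively moves to the mean color of the
    spatial neighbours (disk of ``spatial_radius``) whose color lies
    within ``color_radius`` (Euclidean in RGB) of its current value.
    Homogeneous regions flatten toward their modal color while edges
    larger than the color radius are preserved.  Used to suppress
    specular reflections on the wet meat surface and sharpen marbling
    edges before training and inference.
    """
    if spatial_radius <= 0 or color_radius <= 0:
        raise ValueError("radii must be positive")
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got {img.shape}")
    h, w = img.shape[:2]
    src = img.astype(np.float32)
    cur = src.copy()
    r = int(spatial_radius)
    offsets = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)
               if dy * dy + dx * dx <= r * r]
    r2 = float(color_radius) ** 2
    pad = [(r, r), (r, r), (0, 0)]
    for _ in range(max_iter):
        ref = np.pad(src, pad, mode="reflect")
        acc = np.zeros_like(cur)
        cnt = np.zeros((h, w, 1), dtype=np.float32)
        for dy, dx in offsets:
            nb = ref[r + dy:r + dy + h, r + dx:r + dx + w]
            d2 = ((nb - cur) ** 2).sum(axis=2)
            sel = (d2 <= r2)[..., None]
            acc += np.where(sel, nb, 0.0)
            cnt += sel
        new = acc / np.maximum(cnt, 1.0)
        shift = np.abs(new - cur).max()
        cur = new
        if shift < tol:
            break
    return np.clip(np.rint(cur), 0, 255).astype(np.uint8)


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Assign n records to k cross-validation folds of near-equal size.

    After a seeded shuffle, the first ``n mod k`` folds receive the
    extra record, so fold sizes differ by at most 1 (e.g. 173 records in
    5 folds gives sizes 35/35/35/34/34).  Deterministic in ``seed``.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = np.full(k, n // k)
    sizes[:n % k] += 1
    fold = np.empty(n, dtype=int)
    start = 0
    for f, size in enumerate(sizes):
        fold[perm[start:start + size]] = f
        start += size
    return fold


@dataclass
class DatasetRecord:
    """One image/mask pair with optional reference measurements."""
    image: str
    mask: str
    imf: float | None = None    # intramuscular fat content, percent
    score: float | None = None  # visual marbling score, 1-10 scale
    fold: int = 0


@dataclass
class DatasetIndex:
    """A CSV-backed index of image/mask pairs with cross-validation folds."""
    records: list[DatasetRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def assign_folds(self, k: int, seed: int) -> None:
        for rec, f in zip(self.records, make_folds(len(self.records), k, seed)):
            rec.fold = int(f)

    def split(self, fold: int) -> tuple[list[DatasetRecord], list[DatasetRecord]]:
        """(train records, validation records) for leave-one-fold-out."""
        train = [r for r in self.records if r.fold != fold]
        val = [r for r in self.records if r.fold == fold]
        return train, val

    def to_csv(self, path) -> None:
        pd.DataFrame([{"image": r.image, "mask": r.mask, "imf": r.imf,
                       "score": r.score, "fold": r.fold}
                      for r in self.records]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetIndex":
        df = pd.read_csv(path)
        recs = []
        for row in df.itertuples(index=False):
            recs.append(DatasetRecord(
                image=str(row.image), mask=str(row.mask),
                imf=None if pd.isna(row.imf) else float(row.imf),
                score=None if pd.isna(row.score) else float(row.score),
                fold=int(row.fold)))
        return cls(recs)

    def resolve(self, root) -> "DatasetIndex":
        """Return a copy with image/mask paths joined onto ``root``."""
        root = Path(root)
        return DatasetIndex([
            DatasetRecord(str(root / r.image), str(root / r.mask),
                          r.imf, r.score, r.fold) for r in self.records])
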