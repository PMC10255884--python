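"""Grid slicing of images into training patches and joint geometric
augmentation of image/mask pairs.

Patches are cut sequentially left-to-right, top-to-bottom without
overlap, so a 400 x 800 image yields 128 / 32 / 8 / 2 patches at sizes
50 / 100 / 200 / 400.  Augmentation is applied online (per epoch, per
sample), always identically to image and mask; masks are resampled with
nearest-neighbour interpolation so labels stay in {0, 1}.  Whole-image
inference never uses patching or augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["PatchSample", "AugmentationConfig", "slice_grid", "reassemble",
           "augment", "export_patches"]


@dataclass
class PatchSample:
    """An s x s image/mask pair with its provenance on the source grid."""
    image: np.ndarray   # (s, s, 3) uint8
    mask: np.ndarray    # (s, s) uint8 in {0, 1}
    source_id: str = ""
    grid_row: int = 0
    grid_col: int = 0


@dataclass
class AugmentationConfig:
    """Probabilities and magnitudes of the sequential geometric transforms.

    Applied in order: horizontal flip, counterclockwise 90-degree
    rotation, free rotation (uniform in +-rot_limit degrees), then a
    combined shift (+-shift_limit as a fraction of the side) and scale
    (factor 1 +- scale_limit).  Exposed borders are filled with black /
    label 0, matching the black acquisition board.
    """
    p_hflip: float = 0.5
    p_rot90: float = 0.5
    p_rot_free: float = 0.2
    rot_limit: float = 180.0
    p_shift_scale: float = 0.2
    shift_limit: float = 0.0625
    scale_limit: float = 0.2

    def __post_init__(self):
        for name in ("p_hflip", "p_rot90", "p_rot_free", "p_shift_scale"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} is not a probability")


def slice_grid(image: np.ndarray, mask: np.ndarray, patch_size: int,
               source_id: str = "", strict: bool = True) -> list[PatchSample]:
    """Cut an image/mask pair into non-overlapping patch_size tiles.

    Returns (H/s)*(W/s) patches in row-major order; concatenating them
    back reconstructs the input exactly.  With ``strict`` (default),
    non-divisible dimensions raise an error naming the residue; in
    lenient mode partial border tiles are dropped.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape[:2]} disagree")
    h, w = image.shape[:2]
    rh, rw = h % patch_size, w % patch_size
    if strict and (rh or rw):
        raise ValueError(
            f"image size {h}x{w} not divisible by patch size {patch_size} "
            f"(residues {rh}x{rw}); use strict=False to drop partial tiles")
    out = []
    for gi in range(h // patch_size):
        for gj in range(w // patch_size):
            top, left = gi * patch_size, gj * patch_size
            out.append(PatchSample(
                image=image[top:top + patch_size, left:left + patch_size].copy(),
                mask=mask[top:top + patch_size, left:left + patch_size].copy(),
                source_id=source_id, grid_row=gi, grid_col=gj))
    return out


def reassemble(patches: list[PatchSample]) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`slice_grid` for a complete row-major patch list."""
    if not patches:
        raise ValueError("no patches to reassemble")
    s = patches[0].image.shape[0]
    nrow = max(p.grid_row for p in patches) + 1
    ncol = max(p.grid_col for p in patches) + 1
    image = np.zeros((nrow * s, ncol * s, 3), dtype=patches[0].image.dtype)
    mask = np.zeros((nrow * s, ncol * s), dtype=patches[0].mask.dtype)
    for p in patches:
        image[p.grid_row * s:(p.grid_row + 1) * s,
              p.grid_col * s:(p.grid_col + 1) * s] = p.image
        mask[p.grid_row * s:(p.grid_row + 1) * s,
             p.grid_col * s:(p.grid_col + 1) * s] = p.mask
    return image, mask


def _rotate_pair(image, mask, angle):
    img = ndimage.rotate(image, angle, axes=(1, 0), reshape=False, order=1,
                         mode="constant", cval=0.0)
    msk = ndimage.rotate(mask, angle, axes=(1, 0), reshape=False, order=0,
                         mode="constant", cval=0)
    return img, msk


def _shift_scale_pair(image, mask, shift_y, shift_x, scale):
    h, w = mask.shape
    # output <- input affine map: center, scale, then translate
    m = np.array([[1.0 / scale, 0.0], [0.0, 1.0 / scale]])
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - m @ (center + np.array([shift_y * h, shift_x * w]))
    img = np.stack([ndimage.affine_transform(image[..., ch], m, offset=offset,
                                             order=1, mode="constant", cval=0.0)
                    for ch in range(image.shape[2])], axis=2)
    msk = ndimage.affine_transform(mask, m, offset=offset, order=0,
                                   mode="constant", cval=0)
    return img, msk


def augment(sample: PatchSample, cfg: AugmentationConfig,
            rng: np.random.Generator) -> PatchSample:
    """Apply the seeded augmentation schedule jointly to image and mask.

    The identical geometric transform is used for both; the mask is
    nearest-neighbour resampled, so output labels remain in {0, 1} and
    output dimensions are unchanged.  Deterministic given the generator
    state.
    """
    image = sample.image.astype(np.float32)
    mask = sample.mask.copy()
    if rng.random() < cfg.p_hflip:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
    if mask.shape[0] == mask.shape[1] and rng.random() < cfg.p_rot90:
        image = np.rot90(image).copy()      # counterclockwise; square tiles only
        mask = np.rot90(mask).copy()
    if rng.random() < cfg.p_rot_free:
        angle = rng.uniform(-cfg.rot_limit, cfg.rot_limit)
        image, mask = _rotate_pair(image, mask, angle)
    if rng.random() < cfg.p_shift_scale:
        sy = rng.uniform(-cfg.shift_limit, cfg.shift_limit)
        sx = rng.uniform(-cfg.shift_limit, cfg.shift_limit)
        sc = 1.0 + rng.uniform(-cfg.scale_limit, cfg.scale_limit)
        image, mask = _shift_scale_pair(image, mask, sy, sx, sc)
    return PatchSample(image=np.clip(np.rint(image), 0, 255).astype(np.uint8),
                       mask=mask.astype(np.uint8),
                       source_id=sample.source_id,
                       grid_row=sample.grid_row, grid_col=sample.grid_col)


def export_patches(patches: list[PatchSample], out_dir) -> None:
    """Write patches as paired PNGs plus a manifest CSV (source, row, col)."""
    from .data_io import save_image, save_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(patches):
        img_name = f"patch_{i:05d}.png"
        msk_name = f"patch_{i:05d}_mask.png"
        save_image(out / img_name, p.image)
        save_mask(out / msk_name, p.mask)
        rows.append({"image": img_name, "mask": msk_name,
                     "source_id": p.source_id, "row": p.grid_row, "col": p.grid_col})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
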