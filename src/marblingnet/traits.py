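"""Marbling trait quantification from segmentation masks.

Two distinct denominators are exposed deliberately: per-piece pixel
*proportions* are relative to the entire image area, while the marbling
*ratio* divides by the muscle surface (lean + marbling), the trait that
correlates with intramuscular fat content and visual marbling score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage import measure

__all__ = ["TraitReport", "RegressionResult", "muscle_mask", "marbling_ratio",
           "piece_statistics", "regress", "trait_report"]

# piece-size histogram cutoffs as fractions of the whole image
TINY_CUTOFF = 1e-4    # 0.01 %
LARGE_CUTOFF = 1e-3   # 0.1 %


@dataclass
class TraitReport:
    """Per-image marbling quantification."""
    image_id: str
    marbling_ratio: float
    piece_counts: list[int]
    piece_proportions: list[float]  # of the entire image
    muscle_pixels: int
    n_tiny: int = 0    # pieces below 0.01 % of the image
    n_large: int = 0   # pieces above 0.1 % of the image


@dataclass
class RegressionResult:
    """Ordinary least squares fit y = slope * x + intercept."""
    slope: float
    intercept: float
    r_squared: float
    n: int


def muscle_mask(image: np.ndarray, board_intensity_threshold: int = 40) -> np.ndarray:
    """Delimit the muscle surface from the near-black board.

    Pixels whose maximum channel intensity exceeds the threshold count
    as muscle; morphological hole filling then pulls interior marbling
    (and any dark specks) into the mask.
    """
    if not 0 <= board_intensity_threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got {img.shape}")
    raw = img.max(axis=2) > board_intensity_threshold
    return ndimage.binary_fill_holes(raw).astype(np.uint8)


def marbling_ratio(marbling: np.ndarray, muscle: np.ndarray) -> float:
    """Marbling pixels divided by muscle pixels (muscle = lean + marbling)."""
    marbling = np.asarray(marbling).astype(bool)
    muscle = np.asarray(muscle).astype(bool)
    if marbling.shape != muscle.shape:
        raise ValueError("marbling and muscle masks must have the same shape")
    n_muscle = int(muscle.sum())
    if n_muscle == 0:
        raise ValueError("empty muscle mask")
    outside = marbling & ~muscle
    if outside.any():
        warnings.warn(f"{int(outside.sum())} marbling pixels outside the muscle "
                      "mask were clipped")
        marbling = marbling & muscle
    return float(marbling.sum()) / n_muscle


def piece_statistics(mask: np.ndarray, connectivity: int = 8
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Connected-component sizes of the marbling foreground.

    Returns (piece pixel counts, piece proportions of the whole image)
    under 4- or 8-connectivity (default 8: diagonally touching flecks
    read as one piece).  The counts always sum to the total foreground.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask)
    labels = measure.label(mask > 0, connectivity=1 if connectivity == 4 else 2)
    counts = np.bincount(labels.ravel())[1:]  # drop background
    counts = counts[counts > 0]
    proportions = counts / mask.size
    return counts.astype(int), proportions


def trait_report(image_id: str, marbling: np.ndarray,
                 muscle: np.ndarray | None = None,
                 connectivity: int = 8) -> TraitReport:
    """Assemble the full per-image trait report."""
    counts, props = piece_statistics(marbling, connectivity)
    if muscle is None:
        muscle = np.ones_like(np.asarray(marbling))
    return TraitReport(
        image_id=image_id,
        marbling_ratio=marbling_ratio(marbling, muscle),
        piece_counts=list(counts),
        piece_proportions=list(props),
        muscle_pixels=int(np.asarray(muscle).astype(bool).sum()),
        n_tiny=int((props < TINY_CUTOFF).sum()),
        n_large=int((props > LARGE_CUTOFF).sum()))


def regress(x, y) -> RegressionResult:
    """Simple linear regression of reference measurements on a trait.

    Ordinary least squares y = a*x + b with the coefficient of
    determination R^2; used to relate the marbling ratio to IMF content
    and to the visual marbling score.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2), n=len(x))
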