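"""Seeded synthetic pork-loin image/mask generator.

Emulates the statistical structure of smartphone images of the pork
longissimus dorsi surface: a near-black acquisition board, one smooth
pink lean region covering most of the frame, and sparse whitish
marbling drawn as tiny flecks (down to 2 px) and random-walk stripes
(1-4 px wide), together occupying 0.5-3.5 % of the image.  A few pure
white specular spots are painted on the lean but never enter the
ground-truth mask — they are reflection noise, not fat.

Everything is driven by a single numpy Generator, so identical seeds
give bit-identical images and masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_io import DatasetIndex, DatasetRecord, save_image, save_mask

__all__ = ["SyntheticParams", "SyntheticSample", "SyntheticDataset",
           "generate_image", "generate_dataset"]


@dataclass
class SyntheticParams:
    """Knobs of the synthetic image generator (defaults fit 400 x 800)."""
    height: int = 400
    width: int = 800
    proportion_range: tuple[float, float] = (0.005, 0.035)  # of the whole image
    fleck_count_range: tuple[int, int] = (10, 40)
    fleck_size_range: tuple[int, int] = (2, 32)             # pixels per fleck
    stripe_count_range: tuple[int, int] = (2, 8)
    stripe_width_range: tuple[float, float] = (1.0, 4.0)    # pixels
    stripe_length_range: tuple[float, float] = (40.0, 600.0)
    lean_color: tuple[int, int, int] = (188, 118, 126)      # pinkish
    lean_sigma: float = 7.0
    board_color: tuple[int, int, int] = (14, 11, 11)        # near-black board
    marbling_color: tuple[int, int, int] = (232, 216, 208)  # creamy white fat
    specular_rate: float = 2.0                              # mean spots per image
    max_attempts: int = 5

    def __post_init__(self):
        lo, hi = self.proportion_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"proportion_range {self.proportion_range} not in (0, 1)")
        if min(self.fleck_size_range) < 1 or min(self.stripe_width_range) <= 0:
            raise ValueError("piece sizes must be positive")

    @classmethod
    def for_size(cls, height: int, width: int, **kwargs) -> "SyntheticParams":
        """Defaults rescaled to another canvas size (lengths by the linear
        factor, piece counts by the area factor)."""
        lin = np.sqrt((height * width) / (400.0 * 800.0))
        base = cls()
        kwargs.setdefault("stripe_length_range",
                          (max(8.0, base.stripe_length_range[0] * lin),
                           max(20.0, base.stripe_length_range[1] * lin)))
        kwargs.setdefault("fleck_count_range",
                          (max(3, round(base.fleck_count_range[0] * lin * lin)),
                           max(6, round(base.fleck_count_range[1] * lin * lin))))
        kwargs.setdefault("stripe_count_range",
                          (max(1, round(base.stripe_count_range[0] * lin * lin)),
                           max(2, round(base.stripe_count_range[1] * lin * lin))))
        return cls(height=height, width=width, **kwargs)


@dataclass
class SyntheticSample:
    image: np.ndarray            # (H, W, 3) uint8
    mask: np.ndarray             # (H, W) uint8 in {0, 1}
    lean: np.ndarray             # (H, W) uint8; muscle surface incl. marbling
    proportion: float            # marbling pixels / image pixels
    ratio: float                 # marbling pixels / muscle pixels


@dataclass
class SyntheticDataset:
    samples: list[SyntheticSample]
    imf: np.ndarray              # synthetic intramuscular fat, percent
    scores: np.ndarray           # synthetic marbling scores, 1-10
    index: DatasetIndex = field(default_factory=DatasetIndex)

    @property
    def ratios(self) -> np.ndarray:
        return np.array([s.ratio for s in self.samples])


# ---------------------------------------------------------------------------

def _lean_blob(p: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Smooth star-convex blob covering at least half the canvas."""
    h, w = p.height, p.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    cy = h / 2 + rng.uniform(-0.03, 0.03) * h
    cx = w / 2 + rng.uniform(-0.03, 0.03) * w
    dy = (yy - cy) / (0.47 * h)
    dx = (xx - cx) / (0.47 * w)
    r = np.sqrt(dy * dy + dx * dx)
    theta = np.arctan2(dy, dx)
    bound = np.ones_like(r)
    for harm in range(2, 6):  # low-frequency radial perturbation
        amp = rng.normal(0, 0.03)
        phase = rng.uniform(0, 2 * np.pi)
        bound += amp * np.cos(harm * theta + phase)
    return (r <= bound).astype(np.uint8)


def _fleck_pixels(n: int, cy: int, cx: int, rng: np.random.Generator,
                  shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of a roughly elliptical fleck of ~n pixels."""
    h, w = shape
    if n <= 4:  # exact tiny pieces: a pixel chain
        step = rng.integers(0, 2)  # grow down or right
        ys = cy + (np.arange(n) if step else np.zeros(n, dtype=int))
        xs = cx + (np.zeros(n, dtype=int) if step else np.arange(n))
    else:
        aspect = rng.uniform(0.4, 1.0)
        ry = max(1.0, np.sqrt(n / np.pi / aspect))
        rx = max(1.0, n / np.pi / ry)
        ang = rng.uniform(0, np.pi)
        span = int(np.ceil(max(ry, rx))) + 1
        yy, xx = np.mgrid[-span:span + 1, -span:span + 1].astype(float)
        yr = yy * np.cos(ang) - xx * np.sin(ang)
        xr = yy * np.sin(ang) + xx * np.cos(ang)
        inside = (yr / ry) ** 2 + (xr / rx) ** 2 <= 1.0
        ys, xs = np.nonzero(inside)
        ys = ys - span + cy
        xs = xs - span + cx
    keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    return ys[keep].astype(int), xs[keep].astype(int)


def _stripe_pixels(p: SyntheticParams, cy: int, cx: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A smoothed random-walk polyline rasterized with a given width."""
    h, w = p.height, p.width
    length = rng.uniform(*p.stripe_length_range)
    width = rng.uniform(*p.stripe_width_range)
    step = 1.0
    n_steps = max(2, int(length / step))
    heading = rng.uniform(0, 2 * np.pi)
    turns = rng.normal(0, 0.12, n_steps)
    headings = heading + np.cumsum(turns)
    ys = cy + np.concatenate([[0.0], np.cumsum(step * np.sin(headings))])
    xs = cx + np.concatenate([[0.0], np.cumsum(step * np.cos(headings))])
    canvas = np.zeros((h, w), dtype=bool)
    rad = width / 2.0
    ri = max(0, int(np.floor(rad)))
    offs = [(dy, dx) for dy in range(-ri - 1, ri + 2) for dx in range(-ri - 1, ri + 2)
            if dy * dy + dx * dx <= rad * rad + 0.25]
    pyi = np.rint(ys).astype(int)
    pxi = np.rint(xs).astype(int)
    for dy, dx in offs:
        yy = pyi + dy
        xx = pxi + dx
        keep = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        canvas[yy[keep], xx[keep]] = True
    return np.nonzero(canvas)


def generate_image(params: SyntheticParams | None = None,
                   rng: np.random.Generator | None = None) -> SyntheticSample:
    """Render one synthetic loin image with its ground-truth marbling mask.

    The realized marbling proportion (of the whole image) is guaranteed
    to fall inside ``params.proportion_range``; an infeasible
    combination of piece parameters raises after bounded retries.
    """
    p = params or SyntheticParams()
    rng = rng or np.random.default_rng()
    h, w = p.height, p.width
    npix = h * w
    lo = int(np.ceil(p.proportion_range[0] * npix))
    hi = int(np.floor(p.proportion_range[1] * npix))
    target = int(round(npix * (p.proportion_range[0] +
                               rng.beta(1.3, 2.5) * (p.proportion_range[1]
                                                     - p.proportion_range[0]))))
    target = min(max(target, lo), hi)

    for _ in range(p.max_attempts):
        lean = _lean_blob(p, rng)
        interior = ndimage.binary_erosion(lean, iterations=3)
        iy, ix = np.nonzero(interior)
        if len(iy) < npix // 20:
            continue
        mask = np.zeros((h, w), dtype=bool)
        n_flecks = int(rng.integers(p.fleck_count_range[0], p.fleck_count_range[1] + 1))
        n_stripes = int(rng.integers(p.stripe_count_range[0], p.stripe_count_range[1] + 1))
        queue = ["fleck"] * n_flecks + ["stripe"] * n_stripes
        rng.shuffle(queue)
        count = 0
        for kind in queue + ["fleck"] * 200:  # extra flecks to top up to target
            if count >= target:
                break
            pos = rng.integers(0, len(iy))
            cy, cx = int(iy[pos]), int(ix[pos])
            if kind == "stripe":
                ys, xs = _stripe_pixels(p, cy, cx, rng)
            else:
                lo_s, hi_s = p.fleck_size_range
                size = int(np.exp(rng.uniform(np.log(lo_s), np.log(hi_s + 1))))
                size = min(size, max(2, target - count))
                ys, xs = _fleck_pixels(size, cy, cx, rng, (h, w))
            keep = interior[ys, xs]
            ys, xs = ys[keep], xs[keep]
            gain = int(np.count_nonzero(~mask[ys, xs]))
            if count + gain > hi:
                continue  # would overshoot the allowed range
            mask[ys, xs] = True
            count += gain
        if lo <= count <= hi:
            break
    else:
        raise RuntimeError(
            f"could not realize a marbling proportion in {p.proportion_range} "
            f"after {p.max_attempts} attempts; piece parameters too coarse")

    # ---- render ---------------------------------------------------------
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = p.board_color
    img += rng.normal(0, 2.0, img.shape)

    texture = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=max(4, h // 10))
    # amplitude keeps the brightest lean below marbling brightness
    # (low-but-positive contrast)
    texture = 1.0 + 0.18 * texture / max(np.abs(texture).max(), 1e-6)
    lean_rgb = (np.array(p.lean_color, dtype=np.float32)[None, None]
                * texture[..., None]
                + rng.normal(0, p.lean_sigma, (h, w, 3)))
    lb = lean.astype(bool)
    img[lb] = lean_rgb[lb]

    # absolute alpha scaling: even an isolated 2-px fleck renders white-ish
    # (a lone pixel blurred at sigma 0.7 peaks near 0.32)
    alpha = ndimage.gaussian_filter(mask.astype(np.float32), 0.7)
    alpha = np.clip(alpha / 0.32, 0, 1) * 0.88
    img = img * (1 - alpha[..., None]) + np.array(
        p.marbling_color, dtype=np.float32)[None, None] * alpha[..., None]

    n_spec = rng.poisson(p.specular_rate)
    for _ in range(n_spec):  # reflection noise: bright, tiny, never in the mask
        pos = rng.integers(0, len(iy))
        sy, sx = int(iy[pos]), int(ix[pos])
        rr = int(rng.integers(1, 3))
        yy, xx = np.mgrid[-rr:rr + 1, -rr:rr + 1]
        sel = yy * yy + xx * xx <= rr * rr
        ys = np.clip(sy + yy[sel], 0, h - 1)
        xs = np.clip(sx + xx[sel], 0, w - 1)
        keep = ~mask[ys, xs]  # specular glare must not overwrite true marbling
        img[ys[keep], xs[keep]] = 255.0

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    mask8 = mask.astype(np.uint8)
    return SyntheticSample(image=img, mask=mask8, lean=lean,
                           proportion=count / npix,
                           ratio=count / int(lean.sum()))


def _score_from_ratio(ratio: np.ndarray) -> np.ndarray:
    """Monotone binned transform of the marbling ratio onto the 1-10 scale."""
    return (1 + np.floor(9 * np.clip(np.asarray(ratio) / 0.06, 0, 0.9999))).astype(int)


def generate_dataset(n: int, params: SyntheticParams | None = None,
                     imf_model: tuple[float, float, float] = (60.0, 1.0, 0.45),
                     seed: int = 0, out_dir=None, k_folds: int = 5
                     ) -> SyntheticDataset:
    """Generate n image/mask pairs with synthetic reference measurements.

    Synthetic IMF is linear in the marbling ratio,
    ``imf = a * ratio + b + N(0, sigma)`` with ``(a, b, sigma) =
    imf_model``; the marbling score is a monotone binning of the ratio
    into the 1-10 scale.  With ``out_dir`` set, images, palette masks
    and an ``index.csv`` are written in the package's standard formats.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = params or SyntheticParams()
    rng = np.random.default_rng(seed)
    samples = [generate_image(p, rng) for _ in range(n)]
    a, b, sigma = imf_model
    ratios = np.array([s.ratio for s in samples])
    imf = a * ratios + b + (rng.normal(0, sigma, n) if sigma > 0 else 0.0)
    scores = _score_from_ratio(ratios)

    index = DatasetIndex()
    for i in range(n):
        index.records.append(DatasetRecord(
            image=f"img_{i:04d}.png", mask=f"img_{i:04d}_mask.png",
            imf=float(imf[i]), score=float(scores[i])))
    if k_folds and n >= k_folds:
        index.assign_folds(k_folds, seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec, s in zip(index.records, samples):
            save_image(out / rec.image, s.image)
            save_mask(out / rec.mask, s.mask)
        index.to_csv(out / "index.csv")
    return SyntheticDataset(samples=samples, imf=np.asarray(imf, dtype=float),
                            scores=scores, index=index)
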