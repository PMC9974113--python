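"""Synthetic lung-like masks with ground truth.

The generator emulates the pipeline's input: an HU-threshold lung mask in
which juxtapleural nodules have been carved out of the pleural boundary.
A *truth* mask holds two smooth, disjoint, ellipse-like lobes (mild
low-frequency radial perturbation, a few pixels in amplitude, so the
boundary is realistic rather than analytically circular); the *defective*
mask is the truth minus disk-shaped notches centered on boundary points —
the concave "missed nodule" defects the correction stage must re-include.

Everything is a pure function of (dimensions, parameters, seed); a single
``numpy.random.Generator`` stream is used per fixture and no global RNG
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster_io import PointRC, as_mask
from .supportive import extract_boundary

__all__ = [
    "NotchSpec",
    "FixtureCase",
    "make_lung_truth",
    "carve_notches",
    "make_primitive",
]


@dataclass(frozen=True)
class NotchSpec:
    """One simulated excluded juxtapleural region.

    center lies on the truth-mask boundary; the notch is the disk of the
    given radius around it, subtracted from the foreground.
    """

    center: PointRC
    radius: float
    lobe: str  # "left" | "right"


@dataclass
class FixtureCase:
    """A (truth, defective) mask pair plus the notch metadata that links them."""

    truth: np.ndarray
    defective: np.ndarray
    notches: list[NotchSpec] = field(default_factory=list)
    seed: int = 0


def make_lung_truth(height: int, width: int, seed: int) -> np.ndarray:
    """Generate a two-lobe lung-like binary mask.

    Each lobe is a filled ellipse (semi-axes 0.30*height by 0.15*width,
    centered left/right of the midline) whose radius is perturbed by a
    low-frequency cosine series of total amplitude <= 2.5 px, keeping the
    boundary smooth at the scale a snake or keypoint detector sees.
    """
    if height < 128 or width < 128:
        raise ValueError(f"dimensions must be >= 128, got {height}x{width}")
    rng = np.random.default_rng(seed)
    rows = np.arange(height, dtype=np.float64)[:, None]
    cols = np.arange(width, dtype=np.float64)[None, :]
    mask = np.zeros((height, width), dtype=np.uint8)
    a_row = 0.30 * height  # semi-axis along rows
    a_col = 0.15 * width   # semi-axis along cols
    for col_frac in (0.28, 0.72):
        cr, cc = 0.52 * height, col_frac * width
        dr, dc = rows - cr, cols - cc
        phi = np.arctan2(dr, dc)
        # unperturbed boundary radius of the ellipse along direction phi
        r_ell = 1.0 / np.sqrt((np.sin(phi) / a_row) ** 2 + (np.cos(phi) / a_col) ** 2)
        amps = rng.uniform(0.3, 1.0, size=3)
        amps *= 2.5 / amps.sum()  # total radial perturbation <= 2.5 px
        phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
        pert = sum(
            a * np.cos(m * phi + p)
            for a, m, p in zip(amps, (2, 3, 4), phases)
        )
        mask |= (np.hypot(dr, dc) <= r_ell + pert).astype(np.uint8)
    return mask


def carve_notches(
    truth: np.ndarray,
    n_notches: int,
    radius_range: tuple[float, float] = (8.0, 15.0),
    seed: int = 0,
) -> FixtureCase:
    """Subtract disk notches centered at uniformly sampled boundary points.

    Notch centers are kept pairwise >= 3x the maximum radius apart so the
    defects never merge; placement is rejection-sampled with a 1000-draw
    budget per notch.
    """
    truth = as_mask(truth)
    h, w = truth.shape
    r_lo, r_hi = radius_range
    if not (4.0 < r_lo <= r_hi < min(h, w) / 8.0):
        raise ValueError(
            f"notch radii must lie within (4, {min(h, w) / 8:g}), got {radius_range}"
        )
    rng = np.random.default_rng(seed)
    boundary = extract_boundary(truth).points
    defective = truth.copy()
    notches: list[NotchSpec] = []
    centers: list[np.ndarray] = []
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    for _ in range(n_notches):
        for _attempt in range(1000):
            center = boundary[rng.integers(len(boundary))]
            if all(np.hypot(*(center - c)) >= 3.0 * r_hi for c in centers):
                break
        else:
            raise RuntimeError(
                f"could not place {n_notches} notches with separation "
                f">= {3.0 * r_hi:g} px after 1000 draws"
            )
        radius = float(rng.uniform(r_lo, r_hi))
        disk = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2
        defective[disk] = 0
        centers.append(center)
        notches.append(
            NotchSpec(
                center=PointRC(int(center[0]), int(center[1])),
                radius=radius,
                lobe="left" if center[1] < w / 2 else "right",
            )
        )
    return FixtureCase(truth=truth, defective=defective, notches=notches, seed=seed)


def make_primitive(kind: str, size: int) -> np.ndarray:
    """Canonical centered test shapes for unit tests of tracing, SIFT and GVF.

    kinds: ``square`` (filled, side size//2), ``disk`` (radius size//4),
    ``pixel`` (single foreground pixel at the center), ``ramp`` (grayscale
    float raster whose value is the column index).
    """
    if size < 3:
        raise ValueError(f"size must be >= 3, got {size}")
    if kind == "ramp":
        return np.tile(np.arange(size, dtype=np.float64), (size, 1))
    out = np.zeros((size, size), dtype=np.uint8)
    c = size // 2
    if kind == "pixel":
        out[c, c] = 1
    elif kind == "square":
        half = max(1, size // 4)
        out[c - half : c + half, c - half : c + half] = 1
    elif kind == "disk":
        r = size // 4
        rows = np.arange(size)[:, None]
        cols = np.arange(size)[None, :]
        out[(rows - c) ** 2 + (cols - c) ** 2 <= r**2] = 1
    else:
        raise ValueError(f"unknown primitive kind: {kind!r}")
    return out
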