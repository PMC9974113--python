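"""Difference-of-Gaussians keypoint detection on binary lung masks.

A juxtapleural notch interrupts an otherwise smooth pleural boundary, so it
shows up as corner points and endpoints — exactly the structures a DoG
scale-space extremum detector responds to, while smooth arcs (near-straight
ridges in the DoG) are suppressed by the principal-curvature ratio test.
Only the detector half of SIFT is built: keypoint positions, scales and
orientations. No 128-D descriptors, no matching — downstream stages only
need *where* the boundary curvature misbehaves.

The input mask is consumed as a float raster in [0, 1]; a binary mask is
cast, not pre-blurred, so level 0 of the pyramid is exactly G(sigma0) * I.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "ScaleSpaceConfig",
    "Octave",
    "ScaleSpace",
    "GradientSample",
    "KeyPoint",
    "build_scale_space",
    "scale_space_extrema",
    "detect_keypoints",
    "gradient_at",
    "assign_orientation",
    "detect",
    "keypoint_pixels",
]

_TWO_PI = 2.0 * math.pi
_N_BINS = 36


@dataclass
class ScaleSpaceConfig:
    """Parameters of the Gaussian scale space and keypoint filters.

    sigma0 is the base smoothing scale in pixels; k the multiplicative scale
    factor between adjacent levels (defaults to 2**(1/scales_per_octave) so
    one octave doubles the scale); contrast_thresh is applied to |DoG| on
    rasters scaled to [0, 1]; edge_ratio is the maximum allowed ratio of
    principal curvatures of the 2x2 spatial Hessian (Lowe's r).
    """

    sigma0: float = 1.6
    scales_per_octave: int = 3
    n_octaves: int = 4
    k: float | None = None
    contrast_thresh: float = 0.01
    edge_ratio: float = 5.0
    refine: bool = True

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.scales_per_octave < 3:
            raise ValueError("scales_per_octave must be >= 3")
        if self.k is None:
            self.k = 2.0 ** (1.0 / self.scales_per_octave)
        if self.k <= 1:
            raise ValueError("k must be > 1")
        if self.contrast_thresh < 0:
            raise ValueError("contrast_thresh must be >= 0")
        if self.edge_ratio <= 1:
            raise ValueError("edge_ratio must be > 1")


@dataclass
class Octave:
    gaussians: list[np.ndarray]
    dogs: list[np.ndarray]
    sigmas: list[float]  # effective sigma per gaussian level, in input pixels
    scale: int  # 2**octave_index, the downsampling factor vs the input


@dataclass
class ScaleSpace:
    octaves: list[Octave]
    cfg: ScaleSpaceConfig


@dataclass(frozen=True)
class GradientSample:
    """Central-difference gradient terms at one pixel.

    m1/m2 are the squared column/row differences, m their combination
    (sum of squares in the as-printed convention, else its square root);
    d1/d2 the raw row/column differences and theta = atan2(d1, d2) in
    [0, 2*pi).
    """

    m1: float
    m2: float
    m: float
    d1: float
    d2: float
    theta: float


@dataclass(frozen=True)
class KeyPoint:
    """A scale-space extremum in input-image coordinates."""

    row: float
    col: float
    sigma: float
    octave: int
    orientation: float = 0.0
    response: float = 0.0


def build_scale_space(image: np.ndarray, cfg: ScaleSpaceConfig) -> ScaleSpace:
    """Build the Gaussian pyramid and its DoG stacks.

    Per octave, gaussians are smoothed at sigma0 * k**i relative to the
    octave base; the next octave base is the level with twice the base
    smoothing, downsampled 2x. DoG level i is gaussian[i+1] - gaussian[i].
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {img.shape}")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    kernel = 2 * math.ceil(4.0 * cfg.sigma0) + 1  # scipy truncates at 4 sigma
    if min(img.shape) < 2 * kernel:
        raise ValueError(
            f"image {img.shape} smaller than twice the truncated Gaussian "
            f"kernel ({kernel} px) at base scale {cfg.sigma0}"
        )
    n_levels = cfg.scales_per_octave + 3
    octaves: list[Octave] = []
    base = img
    for o in range(cfg.n_octaves):
        if min(base.shape) < 2 * kernel:
            break
        rel_sigmas = [cfg.sigma0 * cfg.k**i for i in range(n_levels)]
        gaussians = [ndimage.gaussian_filter(base, s) for s in rel_sigmas]
        dogs = [gaussians[i + 1] - gaussians[i] for i in range(n_levels - 1)]
        octaves.append(
            Octave(
                gaussians=gaussians,
                dogs=dogs,
                sigmas=[s * 2**o for s in rel_sigmas],
                scale=2**o,
            )
        )
        # sigma0 * k**scales_per_octave == 2 * sigma0: the next octave base
        base = gaussians[cfg.scales_per_octave][::2, ::2]
    return ScaleSpace(octaves=octaves, cfg=cfg)


def scale_space_extrema(ss: ScaleSpace) -> list[tuple[int, int, int, int]]:
    """Raw candidates: strict extrema over the 26 scale-space neighbors.

    Returns (octave, dog_level, row, col) tuples in deterministic order.
    Border pixels and the outermost DoG levels are excluded (they lack a
    full neighborhood).
    """
    fp = np.ones((3, 3, 3), dtype=bool)
    fp[1, 1, 1] = False
    out: list[tuple[int, int, int, int]] = []
    for oi, octv in enumerate(ss.octaves):
        if len(octv.dogs) < 3:
            continue
        D = np.stack(octv.dogs)
        mx = ndimage.maximum_filter(D, footprint=fp, mode="constant", cval=-np.inf)
        mn = ndimage.minimum_filter(D, footprint=fp, mode="constant", cval=np.inf)
        cand = (D > mx) | (D < mn)
        cand[[0, -1], :, :] = False
        cand[:, [0, -1], :] = False
        cand[:, :, [0, -1]] = False
        out.extend((oi, int(l), int(r), int(c)) for l, r, c in np.argwhere(cand))
    return out


def _edge_like(level: np.ndarray, r: int, c: int, edge_ratio: float) -> bool:
    """Principal-curvature ratio test on the 2x2 spatial Hessian of a DoG level."""
    v = level[r, c]
    dxx = level[r, c + 1] + level[r, c - 1] - 2.0 * v
    dyy = level[r + 1, c] + level[r - 1, c] - 2.0 * v
    dxy = 0.25 * (
        level[r + 1, c + 1] + level[r - 1, c - 1]
        - level[r + 1, c - 1] - level[r - 1, c + 1]
    )
    tr = dxx + dyy
    det = dxx * dyy - dxy * dxy
    if det <= 0:
        return True
    return tr * tr / det > (edge_ratio + 1.0) ** 2 / edge_ratio


def _refine(
    D: np.ndarray, l: int, r: int, c: int
) -> tuple[int, int, int, np.ndarray, float] | None:
    """Quadratic (3-D Taylor) sub-pixel/sub-scale refinement, <= 5 hops."""
    nl, nr, nc = D.shape
    for _ in range(5):
        g = 0.5 * np.array(
            [
                D[l + 1, r, c] - D[l - 1, r, c],
                D[l, r + 1, c] - D[l, r - 1, c],
                D[l, r, c + 1] - D[l, r, c - 1],
            ]
        )
        v = D[l, r, c]
        H = np.empty((3, 3))
        H[0, 0] = D[l + 1, r, c] + D[l - 1, r, c] - 2 * v
        H[1, 1] = D[l, r + 1, c] + D[l, r - 1, c] - 2 * v
        H[2, 2] = D[l, r, c + 1] + D[l, r, c - 1] - 2 * v
        H[0, 1] = H[1, 0] = 0.25 * (
            D[l + 1, r + 1, c] - D[l + 1, r - 1, c]
            - D[l - 1, r + 1, c] + D[l - 1, r - 1, c]
        )
        H[0, 2] = H[2, 0] = 0.25 * (
            D[l + 1, r, c + 1] - D[l + 1, r, c - 1]
            - D[l - 1, r, c + 1] + D[l - 1, r, c - 1]
        )
        H[1, 2] = H[2, 1] = 0.25 * (
            D[l, r + 1, c + 1] - D[l, r + 1, c - 1]
            - D[l, r - 1, c + 1] + D[l, r - 1, c - 1]
        )
        try:
            off = -np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return None
        if np.all(np.abs(off) <= 0.5):
            return l, r, c, off, float(v + 0.5 * g @ off)
        l = int(np.clip(l + round(off[0]), 1, nl - 2))
        r = int(np.clip(r + round(off[1]), 1, nr - 2))
        c = int(np.clip(c + round(off[2]), 1, nc - 2))
    return None


def detect_keypoints(ss: ScaleSpace, cfg: ScaleSpaceConfig) -> list[KeyPoint]:
    """Filter raw extrema into keypoints.

    Pipeline per candidate: |DoG| contrast gate, spatial-Hessian edge gate,
    then (optionally) sub-pixel/sub-scale quadratic refinement. Coordinates
    are returned in input-image pixels regardless of octave.
    """
    kps: list[KeyPoint] = []
    stacks = [np.stack(o.dogs) if len(o.dogs) >= 3 else None for o in ss.octaves]
    for oi, l, r, c in scale_space_extrema(ss):
        octv = ss.octaves[oi]
        D = stacks[oi]
        if abs(D[l, r, c]) < cfg.contrast_thresh:
            continue
        if _edge_like(octv.dogs[l], r, c, cfg.edge_ratio):
            continue
        if cfg.refine:
            res = _refine(D, l, r, c)
            if res is None:
                continue
            l2, r2, c2, off, response = res
            lvl = l2 + off[0]
            row = (r2 + off[1]) * octv.scale
            col = (c2 + off[2]) * octv.scale
        else:
            lvl, row, col = float(l), float(r * octv.scale), float(c * octv.scale)
            response = float(D[l, r, c])
        h, w = ss.octaves[0].gaussians[0].shape
        if not (0 <= row < h and 0 <= col < w):
            continue
        kps.append(
            KeyPoint(
                row=float(row),
                col=float(col),
                sigma=float(cfg.sigma0 * cfg.k**lvl * octv.scale),
                octave=oi,
                response=response,
            )
        )
    return kps


def gradient_at(
    L: np.ndarray, row: int, col: int, squared: bool = True
) -> GradientSample:
    """Gradient terms at an interior pixel of a smoothed raster.

    m1 is the squared central difference along columns, m2 along rows; with
    ``squared`` (the as-printed convention) m = m1 + m2, otherwise
    m = sqrt(m1 + m2). theta is the two-argument arctangent of the row
    difference d1 over the column difference d2, mapped to [0, 2*pi).
    """
    h, w = L.shape
    if not (1 <= row < h - 1 and 1 <= col < w - 1):
        raise ValueError(f"({row}, {col}) is a border pixel of a {h}x{w} raster")
    d2 = float(L[row, col + 1] - L[row, col - 1])
    d1 = float(L[row + 1, col] - L[row - 1, col])
    m1 = d2 * d2
    m2 = d1 * d1
    m = m1 + m2 if squared else math.sqrt(m1 + m2)
    theta = math.atan2(d1, d2) % _TWO_PI
    return GradientSample(m1=m1, m2=m2, m=m, d1=d1, d2=d2, theta=theta)


def assign_orientation(
    L: np.ndarray, kp: KeyPoint, window_radius: float
) -> list[KeyPoint]:
    """Dominant gradient orientation(s) from a 36-bin histogram.

    Pixels within the circular window vote with weight m times a Gaussian
    spatial weight of scale 1.5 * kp.sigma. Every histogram peak reaching
    80% of the maximum yields one keypoint with that bin's center angle.
    An all-zero window yields a single keypoint with orientation 0.
    """
    h, w = L.shape
    r0, c0 = int(round(kp.row)), int(round(kp.col))
    rad = int(math.ceil(window_radius))
    if not (rad + 1 <= r0 < h - rad - 1 and rad + 1 <= c0 < w - rad - 1):
        raise ValueError(
            f"keypoint ({kp.row:.1f}, {kp.col:.1f}) lacks margin {window_radius}"
        )
    hist = np.zeros(_N_BINS)
    sw = 1.5 * kp.sigma
    for dr in range(-rad, rad + 1):
        for dc in range(-rad, rad + 1):
            if dr * dr + dc * dc > window_radius * window_radius:
                continue
            g = gradient_at(L, r0 + dr, c0 + dc)
            if g.m == 0.0:
                continue
            weight = g.m * math.exp(-(dr * dr + dc * dc) / (2.0 * sw * sw))
            hist[int(g.theta / (_TWO_PI / _N_BINS)) % _N_BINS] += weight
    peak = hist.max()
    if peak == 0.0:
        return [replace(kp, orientation=0.0)]
    out = []
    for b in range(_N_BINS):
        if hist[b] >= 0.8 * peak and hist[b] >= hist[b - 1] and hist[b] >= hist[(b + 1) % _N_BINS]:
            out.append(replace(kp, orientation=(b + 0.5) * (_TWO_PI / _N_BINS)))
    return out


def detect(image: np.ndarray, cfg: ScaleSpaceConfig | None = None) -> list[KeyPoint]:
    """Convenience: build the scale space and detect keypoints in one call."""
    cfg = cfg or ScaleSpaceConfig()
    return detect_keypoints(build_scale_space(image, cfg), cfg)


def keypoint_pixels(kps: list[KeyPoint], shape: tuple[int, int]) -> np.ndarray:
    """Round keypoints to unique integer (row, col) pixels, clipped to shape."""
    if not kps:
        return np.empty((0, 2), dtype=int)
    pts = np.array([(round(k.row), round(k.col)) for k in kps], dtype=int)
    pts[:, 0] = np.clip(pts[:, 0], 0, shape[0] - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, shape[1] - 1)
    seen: dict[tuple[int, int], None] = {}
    for r, c in pts:
        seen.setdefault((int(r), int(c)), None)
    return np.array(list(seen), dtype=int).reshape(-1, 2)
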