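"""Gradient-vector-flow snake repair of flagged blocks.

A flagged block contains a lung-boundary notch. The repair evolves a closed
contour, initialized as a rectangle just inside the ER border (outside the
object), under three forces:

* an internal force ``lambda1 * X'' - lambda2 * X''''`` (elasticity plus
  fourth-difference rigidity) that keeps the curve smooth and stiff enough
  to bridge the notch mouth instead of following it;
* the GVF force ``kappa1 * V``, where V is the diffusion of the edge-map
  gradient — smooth, nonzero far from edges, and pointing toward them, which
  gives the outside-initialized curve its long capture range;
* a balloon force ``-kappa2 * N`` along the inward normal that deflates the
  curve where the field is silent.

One evolution step is the semi-implicit solve
``x_{t+1} = (gamma I - A)^{-1} (gamma x_t + kappa1 Vx - kappa2 Nx)`` (same
for y), where A is the cyclic penta-diagonal internal operator. The interior
of the converged curve, united with the original foreground (no lung pixel
recorded before correction is ever lost), is the corrected block; only the
OR portion (the ORCR) is pasted back into the full mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.linalg import circulant, lu_factor, lu_solve
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter

from .raster_io import as_mask
from .recognize import BlockRegion

__all__ = [
    "SnakeConfig",
    "GVFConfig",
    "GVFField",
    "SnakeState",
    "CyclicBandMatrix",
    "edge_map",
    "compute_gvf",
    "init_contour",
    "internal_matrix",
    "outward_normals",
    "evolve",
    "interior_mask",
    "polygon_area",
    "correct_block",
    "apply_corrections",
    "DEFAULT_INSET",
]

DEFAULT_INSET = 2.0


@dataclass
class SnakeConfig:
    """Snake force weights and iteration control.

    lambda1/lambda2 weight elasticity and rigidity; kappa1 the GVF force;
    kappa2 the (inward) balloon force; gamma the implicit step weight;
    sigma_edge the Gaussian scale of the edge map in pixels. The loop stops
    when the mean per-point displacement drops below tol (pixels) or after
    max_iter steps. With normalize_gvf the sampled field is scaled to unit
    magnitude so kappa1 is an advance speed in px/step.
    """

    lambda1: float = 0.04
    lambda2: float = 3.0
    kappa1: float = 0.5
    kappa2: float = 0.001
    gamma: float = 1.0
    sigma_edge: float = 1.2
    n_points: int = 40
    max_iter: int = 400
    tol: float = 0.05
    normalize_gvf: bool = True

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "kappa1", "kappa2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")


@dataclass
class GVFConfig:
    """Explicit diffusion scheme for the GVF field.

    Stability on the unit grid requires dt <= 1/(4*mu).
    """

    mu: float = 0.2
    n_iter: int = 2000
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.dt > 1.0 / (4.0 * self.mu):
            raise ValueError(
                f"dt = {self.dt} violates the stability bound 1/(4*mu) = "
                f"{1.0 / (4.0 * self.mu):g}"
            )


@dataclass
class GVFField:
    u: np.ndarray  # col component
    v: np.ndarray  # row component
    f: np.ndarray  # edge map


@dataclass
class SnakeState:
    """Closed evolving contour; xs are columns, ys are rows (both float)."""

    xs: np.ndarray
    ys: np.ndarray
    iteration: int = 0
    mean_step: float = np.inf


@dataclass
class CyclicBandMatrix:
    """Cyclic penta-diagonal internal operator lambda1*D2 - lambda2*D4.

    Rows sum to zero (difference operators annihilate constants); on the
    circulant eigenvector cos(2*pi*m*i/n) it scales by
    lambda1*(2*cos(theta) - 2) - lambda2*(2*cos(theta) - 2)**2.
    """

    n: int
    lambda1: float
    lambda2: float
    dense: np.ndarray

    def apply(self, vec: np.ndarray) -> np.ndarray:
        return self.dense @ vec


def edge_map(block: np.ndarray, sigma_edge: float) -> np.ndarray:
    """Squared gradient magnitude of the Gaussian-smoothed block, max-normalized.

    The smoothing realizes the line energy, the squared gradient the (negated)
    edge energy; the result is the scalar field whose gradient seeds the GVF.
    """
    img = np.asarray(block, dtype=np.float64)
    gc = ndimage.gaussian_filter(img, sigma_edge, order=(0, 1))
    gr = ndimage.gaussian_filter(img, sigma_edge, order=(1, 0))
    f = gc * gc + gr * gr
    peak = f.max()
    return f / peak if peak > 0 else f


def _laplacian(a: np.ndarray) -> np.ndarray:
    p = np.pad(a, 1, mode="edge")
    return p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * a


def compute_gvf(f: np.ndarray, cfg: GVFConfig | None = None) -> GVFField:
    """Diffuse the edge-map gradient into a gradient vector flow field.

    Fixed-point iteration (explicit scheme, Neumann borders) of
    ``u <- u + dt * (mu * lap(u) - (fx^2 + fy^2) * (u - fx))`` and likewise
    for v with fy, initialized at (fx, fy). Near strong edges the data term
    pins (u, v) to the edge gradient; elsewhere diffusion extends it.
    """
    cfg = cfg or GVFConfig()
    f = np.asarray(f, dtype=np.float64)
    if not np.isfinite(f).all():
        raise ValueError("edge map contains non-finite values")
    fr, fc = np.gradient(f)
    b = fc * fc + fr * fr
    u = fc.copy()
    v = fr.copy()
    for _ in range(cfg.n_iter):
        u += cfg.dt * (cfg.mu * _laplacian(u) - b * (u - fc))
        v += cfg.dt * (cfg.mu * _laplacian(v) - b * (v - fr))
    return GVFField(u=u, v=v, f=f)


def init_contour(
    ext_rect_dims: tuple[int, int], n_points: int, inset: float = DEFAULT_INSET
) -> SnakeState:
    """n_points equally spaced clockwise on a rectangle inset inside the block."""
    h, w = ext_rect_dims
    if inset < 1:
        raise ValueError("inset must be >= 1")
    top, left = inset, inset
    bottom, right = h - 1 - inset, w - 1 - inset
    if bottom - top < 1 or right - left < 1:
        raise ValueError(f"block {ext_rect_dims} too small for inset {inset}")
    sh, sw = bottom - top, right - left
    perim = 2.0 * (sh + sw)
    if perim < n_points:
        raise ValueError("rectangle perimeter shorter than n_points")
    t = np.arange(n_points, dtype=np.float64) * perim / n_points
    xs = np.empty(n_points)
    ys = np.empty(n_points)
    for i, ti in enumerate(t):  # clockwise from the top-left corner
        if ti < sw:
            ys[i], xs[i] = top, left + ti
        elif ti < sw + sh:
            ys[i], xs[i] = top + (ti - sw), right
        elif ti < 2 * sw + sh:
            ys[i], xs[i] = bottom, right - (ti - sw - sh)
        else:
            ys[i], xs[i] = bottom - (ti - 2 * sw - sh), left
    return SnakeState(xs=xs, ys=ys)


def internal_matrix(n: int, lambda1: float, lambda2: float) -> CyclicBandMatrix:
    """Cyclic internal operator A = lambda1 * D2 - lambda2 * D4 (unit spacing)."""
    if n < 5:
        raise ValueError("need >= 5 contour points")
    col = np.zeros(n)
    col[0] = -2.0 * lambda1 - 6.0 * lambda2
    col[1] = col[-1] = lambda1 + 4.0 * lambda2
    col[2] = col[-2] = -lambda2
    return CyclicBandMatrix(n=n, lambda1=lambda1, lambda2=lambda2, dense=circulant(col))


def polygon_area(xs: np.ndarray, ys: np.ndarray) -> float:
    """Signed shoelace area of the closed polygon (positive = CCW in x/y)."""
    return 0.5 * float(np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys))


def outward_normals(state: SnakeState) -> np.ndarray:
    """Unit outward normals from central-difference tangents.

    Orientation is fixed by the signed polygon area so the normals point
    away from the interior for either traversal direction. Returns an (n, 2)
    array of (x, y) components.
    """
    xs, ys = state.xs, state.ys
    tx = np.roll(xs, -1) - np.roll(xs, 1)
    ty = np.roll(ys, -1) - np.roll(ys, 1)
    norm = np.hypot(tx, ty)
    if np.any(norm < 1e-12):
        raise ValueError("degenerate contour: coincident points")
    area = polygon_area(xs, ys)
    if abs(area) < 1e-12:
        raise ValueError("degenerate contour: zero area")
    # CCW (positive area in x/y): rotating the tangent clockwise points outward
    sign = 1.0 if area > 0 else -1.0
    nx = sign * ty / norm
    ny = -sign * tx / norm
    return np.stack([nx, ny], axis=1)


def _normals_tolerant(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Like outward_normals but zeroing normals at coincident points.

    During evolution points may transiently pile up (e.g. clipped at the
    block border); the balloon force simply vanishes there instead of
    aborting the iteration.
    """
    tx = np.roll(xs, -1) - np.roll(xs, 1)
    ty = np.roll(ys, -1) - np.roll(ys, 1)
    norm = np.hypot(tx, ty)
    ok = norm > 1e-12
    safe = np.where(ok, norm, 1.0)
    sign = 1.0 if polygon_area(xs, ys) >= 0 else -1.0
    nx = np.where(ok, sign * ty / safe, 0.0)
    ny = np.where(ok, -sign * tx / safe, 0.0)
    return np.stack([nx, ny], axis=1)


def _sample_field(field: GVFField, xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coords = np.vstack([ys, xs])
    u = ndimage.map_coordinates(field.u, coords, order=1, mode="nearest")
    v = ndimage.map_coordinates(field.v, coords, order=1, mode="nearest")
    return u, v


def evolve(
    state: SnakeState,
    field: GVFField,
    A: CyclicBandMatrix,
    cfg: SnakeConfig,
    record: list | None = None,
) -> SnakeState:
    """Iterate the semi-implicit snake update until the contour settles.

    Each step solves ``(gamma I - A) x_{t+1} = gamma x_t + F_x`` (same for
    y) where F combines the GVF attraction (kappa1, toward edges) and the
    deflating balloon force (kappa2, along -N). Points are clipped to the
    block; iteration stops when the mean displacement drops below cfg.tol or
    at cfg.max_iter. Pass ``record`` to collect an (xs, ys) snapshot per
    iteration.
    """
    if A.n != len(state.xs):
        raise ValueError("matrix size does not match contour length")
    h, w = field.f.shape
    lu = lu_factor(cfg.gamma * np.eye(A.n) - A.dense)
    xs, ys = state.xs.copy(), state.ys.copy()
    it, mean_step = 0, np.inf
    for it in range(1, cfg.max_iter + 1):
        u, v = _sample_field(field, xs, ys)
        if cfg.normalize_gvf:
            mag = np.hypot(u, v)
            ok = mag > 1e-12
            u = np.where(ok, u / np.where(ok, mag, 1.0), 0.0)
            v = np.where(ok, v / np.where(ok, mag, 1.0), 0.0)
        normals = _normals_tolerant(xs, ys)
        fx = cfg.kappa1 * u - cfg.kappa2 * normals[:, 0]
        fy = cfg.kappa1 * v - cfg.kappa2 * normals[:, 1]
        xs_new = lu_solve(lu, cfg.gamma * xs + fx)
        ys_new = lu_solve(lu, cfg.gamma * ys + fy)
        if not (np.isfinite(xs_new).all() and np.isfinite(ys_new).all()):
            raise FloatingPointError(f"non-finite snake coordinates at iteration {it}")
        xs_new = np.clip(xs_new, 0.0, w - 1.0)
        ys_new = np.clip(ys_new, 0.0, h - 1.0)
        mean_step = float(np.mean(np.hypot(xs_new - xs, ys_new - ys)))
        xs, ys = xs_new, ys_new
        if record is not None:
            record.append((xs.copy(), ys.copy()))
        if mean_step < cfg.tol:
            break
    return SnakeState(xs=xs, ys=ys, iteration=it, mean_step=mean_step)


def interior_mask(state: SnakeState, dims: tuple[int, int]) -> np.ndarray:
    """Rasterize the closed contour: even-odd interior plus the polyline pixels."""
    xs, ys = state.xs, state.ys
    if abs(polygon_area(xs, ys)) < 1.0:
        raise ValueError("degenerate contour: area below one pixel")
    out = np.zeros(dims, dtype=np.uint8)
    rr, cc = draw_polygon(ys, xs, shape=dims)
    out[rr, cc] = 1
    rr, cc = polygon_perimeter(
        np.round(ys).astype(int), np.round(xs).astype(int), shape=dims, clip=True
    )
    out[rr, cc] = 1
    return out


def _correct_block_detailed(
    blockreg: BlockRegion,
    snake_cfg: SnakeConfig | None = None,
    gvf_cfg: GVFConfig | None = None,
) -> tuple[np.ndarray, SnakeState]:
    snake_cfg = snake_cfg or SnakeConfig()
    gvf_cfg = gvf_cfg or GVFConfig()
    if not blockreg.flagged:
        raise ValueError("correct_block requires a flagged block")
    block = as_mask(blockreg.block)
    # add a thin background outskirt so the object always has an enclosing
    # edge, even where the lung runs off the ER crop: the snake then has a
    # closed boundary to settle on all the way around
    pad = 3
    padded = np.pad(block, pad)
    field = compute_gvf(edge_map(padded, snake_cfg.sigma_edge), gvf_cfg)
    state = init_contour(padded.shape, snake_cfg.n_points)
    A = internal_matrix(snake_cfg.n_points, snake_cfg.lambda1, snake_cfg.lambda2)
    final = evolve(state, field, A, snake_cfg)
    interior = interior_mask(final, padded.shape)[pad:-pad, pad:-pad]
    corrected = interior | block
    return corrected, final


def correct_block(
    blockreg: BlockRegion,
    snake_cfg: SnakeConfig | None = None,
    gvf_cfg: GVFConfig | None = None,
) -> np.ndarray:
    """Snake-correct one flagged ER crop.

    The result is the union of the snake interior with the original crop
    foreground: the restore rule guarantees no originally-segmented lung
    pixel is lost to a snake that stalled in a local optimum.
    """
    corrected, _ = _correct_block_detailed(blockreg, snake_cfg, gvf_cfg)
    return corrected


def apply_corrections(
    mask: np.ndarray,
    blocks: list[BlockRegion],
    corrected: list[np.ndarray | None],
) -> np.ndarray:
    """Paste each flagged block's ORCR back into the full mask.

    Only the OR sub-rectangle of the corrected ER crop is written, by union
    with the existing foreground, so overlapping ORs combine safely and the
    output is pixelwise >= the input.
    """
    if len(blocks) != len(corrected):
        raise ValueError("blocks and corrected lists must be aligned")
    out = as_mask(mask).copy()
    for blk, corr in zip(blocks, corrected):
        if not blk.flagged or corr is None:
            continue
        orr, err = blk.orig_rect, blk.ext_rect
        local = (
            slice(orr.row0 - err.row0, orr.row1 - err.row0),
            slice(orr.col0 - err.col0, orr.col1 - err.col0),
        )
        out[orr.slices] |= corr[local]
    return out
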