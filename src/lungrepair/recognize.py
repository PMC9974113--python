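"""Block recognition via Fourier descriptors of closed contours.

For each supportive line: take its minimum enclosing axis-aligned rectangle
(the *original rectangle*, OR), pad it with background margin (the *extended
rectangle*, ER) so the cropped object has a closed outer boundary, trace
that boundary (Moore-neighbor, clockwise), transform the complex-encoded
contour with a DFT, and flag the block when the high-frequency band of the
descriptor — the part that encodes sharp curvature detail rather than
overall shape — exceeds a threshold.

Descriptor conventions: z(n) = col(n) + j*row(n); Z(k) is the plain forward
DFT sum (no 1/N factor); Z(0) is zeroed (translation invariance) and the
normalized descriptor divides by Z(1) (rotation/scale/start-point magnitude
invariance). Conjugate symmetry is honored by banding on min(k, N-k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster_io import as_mask
from .supportive import SupportiveLine

__all__ = [
    "RectRC",
    "ContourDescriptor",
    "BlockRegion",
    "RecognitionConfig",
    "mer",
    "expand_rect",
    "trace_closed_boundary",
    "fourier_descriptor",
    "classify_block",
    "build_blocks",
]

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)

# Moore neighborhood in clockwise order (row axis points down the image)
_CLOCKWISE = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)
_DIR_INDEX = {d: i for i, d in enumerate(_CLOCKWISE)}


@dataclass(frozen=True)
class RectRC:
    """Axis-aligned rectangle, half-open [row0, row1) x [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError(f"degenerate rectangle {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row1 - self.row0, self.col1 - self.col0)

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row1), slice(self.col0, self.col1))

    def contains(self, other: "RectRC") -> bool:
        return (
            self.row0 <= other.row0
            and self.col0 <= other.col0
            and self.row1 >= other.row1
            and self.col1 >= other.col1
        )


@dataclass
class ContourDescriptor:
    """DFT of a complex-encoded closed contour plus its banded maximum.

    Zn is the Z(1)-normalized series (None when normalization is off and the
    first harmonic vanishes); band_max/band_argmax summarize the magnitude
    over harmonics with min(k, N-k) >= k_min.
    """

    N: int
    z: np.ndarray
    Z: np.ndarray
    Zn: np.ndarray | None
    band_max: float
    band_argmax: int


@dataclass
class RecognitionConfig:
    """ER margin and descriptor flagging rule.

    The flag fires when the high-frequency band maximum strictly exceeds
    ``threshold``. With ``use_normalized`` the band is evaluated on
    |Z(k)/Z(1)| (scale-invariant, default); otherwise on raw |Z(k)|, the
    convention under which the classical 10000 level was reported for
    full-slice coordinates.
    """

    margin: int = 15
    threshold: float = 0.004
    k_min: int = 10
    use_normalized: bool = True

    def __post_init__(self) -> None:
        if self.margin < 1:
            raise ValueError("margin must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")


@dataclass
class BlockRegion:
    line_id: int
    orig_rect: RectRC
    ext_rect: RectRC
    block: np.ndarray  # ER crop of the lung mask
    descriptor: ContourDescriptor | None
    flagged: bool


def mer(line: SupportiveLine) -> RectRC:
    """Minimum enclosing axis-aligned rectangle of a supportive line."""
    pts = np.asarray(line.points)
    if pts.size == 0:
        raise ValueError("cannot bound an empty line")
    return RectRC(
        row0=int(pts[:, 0].min()),
        col0=int(pts[:, 1].min()),
        row1=int(pts[:, 0].max()) + 1,
        col1=int(pts[:, 1].max()) + 1,
    )


def expand_rect(orig: RectRC, margin: int, bounds: tuple[int, int]) -> RectRC:
    """Grow a rectangle by *margin* on all sides, clipped to image bounds."""
    if margin < 1:
        raise ValueError("margin must be >= 1")
    h, w = bounds
    return RectRC(
        row0=max(0, orig.row0 - margin),
        col0=max(0, orig.col0 - margin),
        row1=min(h, orig.row1 + margin),
        col1=min(w, orig.col1 + margin),
    )


def _largest_component(block: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(block, structure=_EIGHT)
    if n <= 1:
        return block
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return (labels == sizes.argmax()).astype(np.uint8)


def trace_closed_boundary(block: np.ndarray) -> np.ndarray:
    """Moore-neighbor trace of the largest foreground component.

    Clockwise, starting at the uppermost-then-leftmost foreground pixel;
    consecutive points are 8-adjacent and the last point is 8-adjacent to
    the first. Pixels on one-pixel-wide spurs may repeat. Returns an (N, 2)
    int array of (row, col).
    """
    m = as_mask(block)
    if m.sum() == 0:
        raise ValueError("no object in ER")
    m = _largest_component(m)
    start = tuple(int(v) for v in np.argwhere(m)[0])
    h, w = m.shape

    def fg(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < h and 0 <= p[1] < w and m[p] == 1

    b0 = (start[0], start[1] - 1)  # entered from the left; background by scan order
    contour = [start]
    cur, back = start, b0
    seen = {(cur, back)}
    max_steps = 8 * int(m.sum()) + 8
    for _ in range(max_steps):
        d = (back[0] - cur[0], back[1] - cur[1])
        i = _DIR_INDEX[d]
        nxt = None
        back_cand = back
        for step in range(1, 9):
            dd = _CLOCKWISE[(i + step) % 8]
            cand = (cur[0] + dd[0], cur[1] + dd[1])
            if fg(cand):
                nxt = cand
                break
            back_cand = cand
        if nxt is None:
            return np.array(contour, dtype=int)  # isolated pixel
        back = back_cand
        cur = nxt
        # a repeated (pixel, backtrack) walk state means the cycle is closed
        if (cur, back) in seen:
            break
        seen.add((cur, back))
        contour.append(cur)
    return np.array(contour, dtype=int)


def fourier_descriptor(
    contour: np.ndarray, k_min: int = 10, use_normalized: bool = True
) -> ContourDescriptor:
    """DFT descriptor of a closed contour of N >= 8 points.

    z(n) = col(n) + j*row(n); Z = forward DFT sum; Z(0) := 0; the normalized
    series divides by Z(1). band_max is the largest magnitude (of |Zn| when
    ``use_normalized`` else of |Z|) over harmonics k with min(k, N-k) >=
    k_min; 0 when the band is empty.
    """
    pts = np.asarray(contour)
    N = len(pts)
    if N < 8:
        raise ValueError(f"contour must have >= 8 points, got {N}")
    z = pts[:, 1].astype(np.float64) + 1j * pts[:, 0].astype(np.float64)
    Z = np.fft.fft(z)  # numpy's forward convention: sum z(n) exp(-j 2 pi k n / N)
    Z[0] = 0.0
    # |Z(1)| of any real contour is O(N * extent); below this it is roundoff
    degenerate = abs(Z[1]) <= 1e-12 * N * max(np.abs(z).max(), 1.0)
    if not degenerate:
        Zn = Z / Z[1]
        Zn[1] = 1.0 + 0.0j  # exact by construction
    elif use_normalized:
        raise ValueError("degenerate first harmonic: |Z(1)| = 0")
    else:
        Zn = None
    series = Zn if use_normalized else Z
    ks = np.arange(1, N)
    band = ks[np.minimum(ks, N - ks) >= k_min]
    if band.size == 0:
        band_max, band_argmax = 0.0, 0
    else:
        mags = np.abs(series[band])
        j = int(mags.argmax())
        band_max, band_argmax = float(mags[j]), int(band[j])
    return ContourDescriptor(
        N=N, z=z, Z=Z, Zn=Zn, band_max=band_max, band_argmax=band_argmax
    )


def classify_block(desc: ContourDescriptor, cfg: RecognitionConfig) -> bool:
    """A block needs correction iff its band maximum strictly exceeds the threshold."""
    return desc.band_max > cfg.threshold


def build_blocks(
    mask: np.ndarray,
    lines: list[SupportiveLine],
    cfg: RecognitionConfig | None = None,
) -> list[BlockRegion]:
    """One BlockRegion per supportive line: MER -> ER -> trace -> descriptor -> flag.

    Lines whose ER crop has no foreground, or whose traced contour is too
    short for a descriptor, produce a logged warning and (respectively) are
    dropped or left unflagged.
    """
    cfg = cfg or RecognitionConfig()
    mask = as_mask(mask)
    blocks: list[BlockRegion] = []
    for line in lines:
        orig = mer(line)
        ext = expand_rect(orig, cfg.margin, mask.shape)
        crop = mask[ext.slices].copy()
        if crop.sum() == 0:
            logger.warning("line %d: ER crop has no foreground, dropped", line.component_id)
            continue
        contour = trace_closed_boundary(crop)
        if len(contour) < 8:
            logger.warning(
                "line %d: contour of %d points too short for a descriptor",
                line.component_id, len(contour),
            )
            desc, flagged = None, False
        else:
            desc = fourier_descriptor(contour, cfg.k_min, cfg.use_normalized)
            flagged = classify_block(desc, cfg)
        blocks.append(
            BlockRegion(
                line_id=line.component_id,
                orig_rect=orig,
                ext_rect=ext,
                block=crop,
                descriptor=desc,
                flagged=flagged,
            )
        )
    return blocks
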