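"""Supportive boundary lines.

Keypoints flag *where* the lung boundary misbehaves; this module turns them
into connected boundary segments the recognition stage can crop and judge.
The steps are: extract the inner boundary of the mask, snap every keypoint
to its nearest boundary pixel (non-edge keypoints still carry a signal, but
only boundary pixels are useful downstream), keep the boundary pixels within
radius R of any anchor, and split the kept set into 8-connected components.

Boundary membership uses 4-neighborhood background contact (the image border
counts as background); line connectivity uses 8-neighborhood so diagonal
boundary runs stay connected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .raster_io import as_mask

__all__ = [
    "BoundaryPointSet",
    "SupportiveLine",
    "extract_boundary",
    "project_to_boundary",
    "supportive_mask",
    "split_lines",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class BoundaryPointSet:
    """Integer boundary pixels of a mask, with the source-mask dimensions."""

    points: np.ndarray  # (N, 2) int array of (row, col)
    shape: tuple[int, int]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.points)


@dataclass
class SupportiveLine:
    """One 8-connected run of suspicious boundary pixels."""

    points: np.ndarray  # (N, 2) int array of (row, col)
    component_id: int


def extract_boundary(mask: np.ndarray) -> BoundaryPointSet:
    """Return the foreground pixels with at least one background 4-neighbor."""
    m = as_mask(mask)
    p = np.pad(m, 1, mode="constant", constant_values=0)
    has_bg_neighbor = (
        (p[:-2, 1:-1] == 0)
        | (p[2:, 1:-1] == 0)
        | (p[1:-1, :-2] == 0)
        | (p[1:-1, 2:] == 0)
    )
    boundary = (m == 1) & has_bg_neighbor
    return BoundaryPointSet(points=np.argwhere(boundary), shape=m.shape)


def project_to_boundary(
    points: np.ndarray, boundary: BoundaryPointSet
) -> np.ndarray:
    """Snap each point to its Euclidean-nearest boundary pixel.

    Points already on the boundary map to themselves (their distance is 0);
    duplicates are collapsed keeping first occurrence. Returns an (M, 2) int
    array of anchors.
    """
    if len(boundary.points) == 0:
        raise ValueError("no lung boundary present")
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.size == 0:
        return np.empty((0, 2), dtype=int)
    tree = cKDTree(boundary.points)
    _, idx = tree.query(pts)
    anchors = boundary.points[np.asarray(idx, dtype=int)]
    seen: dict[tuple[int, int], None] = {}
    for r, c in anchors:
        seen.setdefault((int(r), int(c)), None)
    return np.array(list(seen), dtype=int).reshape(-1, 2)


def supportive_mask(
    boundary: BoundaryPointSet, anchors: np.ndarray, R: float
) -> BoundaryPointSet:
    """Keep boundary pixels within distance R (inclusive) of some anchor."""
    if R < 0:
        raise ValueError(f"R must be >= 0, got {R}")
    anchors = np.atleast_2d(np.asarray(anchors))
    if anchors.size == 0 or len(boundary.points) == 0:
        return BoundaryPointSet(np.empty((0, 2), dtype=int), boundary.shape)
    tree = cKDTree(anchors)
    d, _ = tree.query(boundary.points)
    return BoundaryPointSet(boundary.points[d <= R], boundary.shape)


def split_lines(support: BoundaryPointSet, min_len: int = 5) -> list[SupportiveLine]:
    """Split the supportive set into 8-connected components.

    Components shorter than *min_len* pixels are discarded as debris; the
    survivors are ordered by their (min row, min col) corner and numbered
    from 0 in that order.
    """
    if len(support.points) == 0:
        return []
    grid = np.zeros(support.shape, dtype=np.uint8)
    grid[support.points[:, 0], support.points[:, 1]] = 1
    labels, n = ndimage.label(grid, structure=_EIGHT)
    comps = []
    for lab in range(1, n + 1):
        pts = np.argwhere(labels == lab)
        if len(pts) >= min_len:
            comps.append((int(pts[:, 0].min()), int(pts[:, 1].min()), pts))
    comps.sort(key=lambda t: (t[0], t[1]))
    return [
        SupportiveLine(points=pts, component_id=i)
        for i, (_, _, pts) in enumerate(comps)
    ]
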