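"""Raster I/O for binary lung masks.

Conventions shared by every module in the package:

* a **mask** is a 2-D ``numpy`` array with values in ``{0, 1}`` (stored as
  ``uint8``); foreground (lung parenchyma) is ``1`` and renders white;
* pixel coordinates are 0-based ``(row, col)`` with the row axis pointing
  down the image — no ``x``/``y`` ambiguity anywhere in the package;
* on disk a mask is an 8-bit single-channel PNG or TIFF with foreground 255.

Upstream Hounsfield-unit thresholding, CT windowing and DICOM handling are
out of scope: the pipeline starts from the already-binarized lung mask.
"""

from __future__ import annotations

import os
from typing import NamedTuple

import numpy as np
from PIL import Image

__all__ = [
    "MaskFormatError",
    "PointRC",
    "as_mask",
    "read_mask",
    "write_mask",
    "read_gray",
]


class MaskFormatError(ValueError):
    """Raised when a raster does not satisfy the binary-mask contract."""


class PointRC(NamedTuple):
    """A pixel position as (row, col); row increases downward."""

    row: float
    col: float


def as_mask(arr: np.ndarray) -> np.ndarray:
    """Validate *arr* as a binary mask and return it as ``uint8`` {0, 1}.

    Raises :class:`MaskFormatError` if the array is not 2-D, is smaller than
    3x3, or contains values other than 0 and 1.
    """
    a = np.asarray(arr)
    if a.ndim != 2:
        raise MaskFormatError(f"mask must be 2-D, got shape {a.shape}")
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise MaskFormatError(f"mask must be at least 3x3, got shape {a.shape}")
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise MaskFormatError(f"mask values must be 0/1, found {vals[:10]}")
    return a.astype(np.uint8, copy=False)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read an 8/16-bit single-channel image as a binary mask.

    Foreground is every pixel strictly above half the dtype maximum (so the
    canonical {0, 255} files map to {0, 1}).
    """
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise MaskFormatError(
            f"expected a single-channel 2-D image, got shape {arr.shape} from {path}"
        )
    if np.issubdtype(arr.dtype, np.integer):
        half = np.iinfo(arr.dtype).max / 2.0
    else:
        half = 0.5
    return as_mask((arr > half).astype(np.uint8))


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a binary mask as an 8-bit file with foreground = 255."""
    m = as_mask(mask)
    Image.fromarray((m * 255).astype(np.uint8), mode="L").save(path)


def read_gray(path: str | os.PathLike) -> np.ndarray:
    """Read a grayscale raster as float64 in [0, 1] (visualization only)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("F"), dtype=np.float64)
    peak = arr.max()
    return arr / peak if peak > 0 else arr
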