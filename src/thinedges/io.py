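"""Core raster conventions and file I/O for boundary and edge images.

Two in-memory image kinds are used throughout the package:

* *gray image* -- ``uint8`` array of shape ``(h, w)``; pixel intensity in
  ``[0, 255]`` encodes per-pixel boundary confidence, ``0`` is background.
* *binary image* -- ``bool`` array of shape ``(h, w)``; ``True`` marks an
  edge pixel.

Coordinates are ``(row, col)``, 0-based, origin at the top-left.  The
4-neighborhood is {N, S, E, W}; the 8-neighborhood adds the diagonals.
On disk binary maps are 8-bit PNGs with ``1 -> 255`` and ``0 -> 0``.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = [
    "as_gray",
    "as_binary",
    "read_gray",
    "write_edge_map",
    "binarize",
    "DegenerateImageError",
]

# ITU-R BT.601 luma weights, the standard grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


class DegenerateImageError(ValueError):
    """An image violates a structural precondition (e.g. no background)."""


def as_gray(img: np.ndarray) -> np.ndarray:
    """Validate and coerce *img* to a ``uint8`` gray image.

    Raises :class:`ValueError` if the array is not 2-D, is empty, or holds
    values outside ``[0, 255]``.
    """
    a = np.asarray(img)
    if a.ndim != 2:
        raise ValueError(f"gray image must be 2-D, got shape {a.shape}")
    if a.size == 0:
        raise ValueError("gray image must have h >= 1 and w >= 1")
    if a.dtype != np.uint8:
        if not np.issubdtype(a.dtype, np.integer):
            raise ValueError(f"gray image must hold integers, got {a.dtype}")
        if a.min() < 0 or a.max() > 255:
            raise ValueError("gray intensities must lie in [0, 255]")
        a = a.astype(np.uint8)
    return a


def as_binary(img: np.ndarray) -> np.ndarray:
    """Validate and coerce *img* to a ``bool`` binary image."""
    a = np.asarray(img)
    if a.ndim != 2:
        raise ValueError(f"binary image must be 2-D, got shape {a.shape}")
    if a.size == 0:
        raise ValueError("binary image must have h >= 1 and w >= 1")
    if a.dtype != bool:
        if not np.isin(a, (0, 1)).all():
            raise ValueError("binary image values must be 0 or 1")
        a = a.astype(bool)
    return a


def read_gray(path) -> np.ndarray:
    """Read an 8-bit grayscale image; RGB(A) inputs are luma-converted.

    Returns a ``uint8`` array of shape ``(h, w)``.
    """
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio wraps decoder failures variously
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"zero-sized image: {path!r}")
    if raw.ndim == 3:
        raw = np.rint(raw[..., :3].astype(float) @ _LUMA)
    return np.clip(np.rint(raw), 0, 255).astype(np.uint8)


def write_edge_map(img: np.ndarray, path) -> None:
    """Write a binary edge map as an 8-bit PNG (``1 -> 255``, ``0 -> 0``)."""
    b = as_binary(img)
    iio.imwrite(path, b.astype(np.uint8) * 255)


def binarize(g: np.ndarray) -> np.ndarray:
    """Map a gray boundary image to binary: any positive intensity is edge."""
    return as_gray(g) > 0
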