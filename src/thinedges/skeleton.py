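"""Skeletonization of boundaries into 1-pixel, 8-connected thin edges.

Three methods are dispatched through :func:`apply_skeletonize`:

``'GWPS'``
    Gray-Weighted Path Skeletonize -- ridge extraction on the gray-weighted
    distance transform of the boundary.  Foreground pixels are visited in
    ascending order of their GWDT cost (ties broken by row-major index, so
    the procedure is fully deterministic) and deleted whenever deletion
    preserves local topology; low-cost flanks of the boundary are peeled
    away first and the high-cost crest -- the ridge -- survives.
``'2D'``
    Classic 2-D medial-axis thinning (Zhang--Suen) of the binarized
    boundary.
``'3D'``
    3-D thinning (Lee et al.) of the binarized boundary embedded as a
    single-slice volume, projected back to 2-D.

A pixel is *deletable* when its eight-way neighborhood number ``N_c``
equals 1 (removal keeps the local foreground 8-connectivity intact) and it
has at least two foreground 8-neighbors (endpoints of open curves are
preserved; spur removal is the pruning stage's job).  Isolated pixels have
``N_c == 0`` and are never removed.
"""

from __future__ import annotations

import heapq

import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize

from .gwdt import gwdt
from .io import as_binary, as_gray, binarize

__all__ = [
    "neighborhood_number",
    "gwps",
    "apply_skeletonize",
    "SKELETON_METHODS",
]

SKELETON_METHODS = ("2D", "3D", "GWPS")

# Neighbor offsets (row, col) in the x1..x8 numbering around a center
# pixel: x1=E, x2=NE, x3=N, x4=NW, x5=W, x6=SW, x7=S, x8=SE
# (counterclockwise); index arithmetic wraps so x9 == x1.
NEIGHBOR_OFFSETS = (
    (0, 1),
    (-1, 1),
    (-1, 0),
    (-1, -1),
    (0, -1),
    (1, -1),
    (1, 0),
    (1, 1),
)


def neighborhood_number(neighbors) -> int:
    """Eight-way neighborhood number ``N_c`` of a center pixel.

    Parameters
    ----------
    neighbors
        Sequence of the eight neighbor values ``x1..x8`` (0/1 or bool) in
        the E, NE, N, NW, W, SW, S, SE order of :data:`NEIGHBOR_OFFSETS`.

    Returns
    -------
    int
        ``N_c = sum_{k in {1,3,5,7}} (x̄_k - x̄_k * x̄_{k+1} * x̄_{k+2})``
        with ``x̄ = 1 - x`` and ``x9 == x1``; always in ``{0, 1, 2, 3, 4}``.
        ``N_c`` counts the 8-connected foreground groups that would remain
        around the center; deleting a pixel with ``N_c == 1`` does not
        split or merge anything locally.
    """
    if len(neighbors) != 8:
        raise ValueError("expected the 8 neighbor values x1..x8")
    xb = [0 if v else 1 for v in neighbors]
    total = 0
    for k in (0, 2, 4, 6):
        total += xb[k] - xb[k] * xb[(k + 1) % 8] * xb[(k + 2) % 8]
    return total


def _neighbor_values(fg: np.ndarray, i: int, j: int) -> list:
    """x1..x8 values around (i, j); positions outside the image are 0."""
    h, w = fg.shape
    return [
        bool(fg[i + di, j + dj]) if 0 <= i + di < h and 0 <= j + dj < w else False
        for di, dj in NEIGHBOR_OFFSETS
    ]


def gwps(t: np.ndarray) -> np.ndarray:
    """Gray-Weighted Path Skeletonize: thin edge from a GWDT cost image.

    Ordered homotopic thinning: foreground pixels (positive cost) are
    processed from a priority queue keyed by ``(cost, row-major index)``;
    a popped pixel is deleted iff it is currently deletable, and each
    deletion re-enqueues the surviving foreground 8-neighbors.  The loop
    ends when no pixel is deletable, so the output contains no deletable
    pixel, keeps the number of 8-connected foreground components of the
    input, and its support is a subset of the input support.
    """
    t = np.asarray(t)
    if t.ndim != 2:
        raise ValueError("cost image must be 2-D")
    h, w = t.shape
    out = t > 0

    heap = [
        (int(t[i, j]), int(i) * w + int(j)) for i, j in zip(*np.nonzero(out))
    ]
    heapq.heapify(heap)
    while heap:
        _, idx = heapq.heappop(heap)
        i, j = divmod(idx, w)
        if not out[i, j]:
            continue
        nb = _neighbor_values(out, i, j)
        if sum(nb) >= 2 and neighborhood_number(nb) == 1:
            out[i, j] = False
            for di, dj in NEIGHBOR_OFFSETS:
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and out[ni, nj]:
                    heapq.heappush(heap, (int(t[ni, nj]), ni * w + nj))
    return out


def apply_skeletonize(g: np.ndarray, beta: str) -> np.ndarray:
    """Reduce a gray boundary image to a thin edge with method *beta*.

    ``beta`` is one of ``'2D'``, ``'3D'``, ``'GWPS'`` (case-insensitive).
    The output foreground is always a subset of the binarized input's
    foreground.
    """
    method = str(beta).upper()
    if method not in SKELETON_METHODS:
        raise ValueError(
            f"unknown skeletonize method {beta!r}; expected one of {SKELETON_METHODS}"
        )
    g = as_gray(g)
    if method == "GWPS":
        return gwps(gwdt(g))
    b = binarize(g)
    if method == "2D":
        return as_binary(_sk_skeletonize(b, method="zhang"))
    # '3D': single-slice volume through the 3-D thinning, projected back.
    vol = b[np.newaxis, :, :]
    return as_binary(_sk_skeletonize(vol, method="lee")[0])
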