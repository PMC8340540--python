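"""Gray-Weighted Distance Transform (GWDT).

For every foreground pixel of a gray boundary image the GWDT is the minimal
accumulated intensity along a 4-connected pixel path that ends at a
background (zero) pixel.  The path cost sums the intensity of the start
pixel and of every intermediate foreground pixel; the terminal background
pixel contributes zero.  Background pixels map to cost 0.

The transform is computed *exactly* by multi-source lowest-cost-first
propagation (Dijkstra over the 4-connected node-cost grid, seeded at every
foreground pixel adjacent to background).  Costs are exact integers -- sums
of 8-bit values -- so there is no floating-point drift.

Image borders are *not* treated as background: a path must terminate at an
in-image zero pixel, so an image without any background pixel is a
degenerate input and raises :class:`~thinedges.io.DegenerateImageError`.
"""

from __future__ import annotations

import heapq

import numpy as np

from .io import DegenerateImageError, as_gray

__all__ = ["gwdt"]

_STEPS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


def gwdt(g: np.ndarray) -> np.ndarray:
    """Exact gray-weighted distance transform of a gray boundary image.

    Parameters
    ----------
    g
        Gray image (``uint8``-compatible, shape ``(h, w)``) with at least
        one zero-valued pixel.

    Returns
    -------
    numpy.ndarray
        ``int64`` cost image: 0 on background, and on every foreground
        pixel the minimal accumulated intensity of a 4-connected path to
        the background.
    """
    f = as_gray(g).astype(np.int64)
    h, w = f.shape
    bg = f == 0
    if not bg.any():
        raise DegenerateImageError(
            "no background reachable: image contains no zero-valued pixel"
        )

    cost = np.where(bg, 0, np.iinfo(np.int64).max)

    # Seed with foreground pixels 4-adjacent to the background; their best
    # cost is their own intensity (one step out, the background adds 0).
    adj = np.zeros_like(bg)
    adj[1:, :] |= bg[:-1, :]
    adj[:-1, :] |= bg[1:, :]
    adj[:, 1:] |= bg[:, :-1]
    adj[:, :-1] |= bg[:, 1:]
    heap = []
    for i, j in zip(*np.nonzero(adj & ~bg)):
        c = int(f[i, j])
        cost[i, j] = c
        heap.append((c, int(i), int(j)))
    heapq.heapify(heap)

    while heap:
        c, i, j = heapq.heappop(heap)
        if c != cost[i, j]:
            continue  # stale entry
        for di, dj in _STEPS4:
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and not bg[ni, nj]:
                nc = c + int(f[ni, nj])
                if nc < cost[ni, nj]:
                    cost[ni, nj] = nc
                    heapq.heappush(heap, (nc, ni, nj))
    return cost
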