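"""Shared helpers: independent oracles and small random-image factories."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra


def count_components8(b: np.ndarray) -> int:
    """Number of 8-connected foreground components (scipy labelling)."""
    return ndi.label(np.asarray(b) > 0, structure=np.ones((3, 3)))[1]


def dijkstra_oracle(g: np.ndarray) -> np.ndarray:
    """Brute-force gray-weighted distance transform via scipy's Dijkstra.

    Independent of the package implementation: builds the explicit
    4-connected grid graph where an edge into pixel (i, j) costs the
    pixel's intensity, then runs multi-source shortest paths from every
    background pixel.  Edges are only drawn into foreground pixels, so
    all weights are positive.
    """
    g = np.asarray(g, dtype=np.int64)
    h, w = g.shape
    n = h * w
    rows, cols, data = [], [], []
    for i in range(h):
        for j in range(w):
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and g[ni, nj] > 0:
                    rows.append(i * w + j)
                    cols.append(ni * w + nj)
                    data.append(g[ni, nj])
    mat = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    sources = np.flatnonzero(g.ravel() == 0)
    d = _csgraph_dijkstra(mat, indices=sources, min_only=True)
    out = d.reshape(h, w)
    out[g == 0] = 0
    return np.rint(out).astype(np.int64)


def random_gray_with_background(rng: np.random.Generator, shape=(16, 16),
                                zero_frac: float = 0.15) -> np.ndarray:
    """Random 8-bit image guaranteed to contain background pixels."""
    g = rng.integers(0, 256, shape).astype(np.uint8)
    g[rng.random(shape) < zero_frac] = 0
    if (g == 0).sum() < max(1, int(0.1 * g.size)):
        idx = rng.choice(g.size, size=int(0.1 * g.size), replace=False)
        g.ravel()[idx] = 0
    return g


def implant_spurs(height: int, width: int, rng: np.random.Generator,
                  n_spurs: int = 4, max_len: int = 6):
    """A horizontal thin line with perpendicular spurs of known lengths.

    Returns ``(skeleton, spurs)`` where ``spurs`` is a list of
    ``(pixel tuple, length)``.  Spur columns are spaced so branches do
    not interact and stay >= 10 columns from the line ends (so the line's
    own end-branches are longer than any tested limit).  Lengths are
    >= 2: a single orthogonal stub has three 8-neighbors, hence no
    endpoint, and is not a spur at all.
    """
    r = height // 2
    skel = np.zeros((height, width), dtype=bool)
    skel[r, 2:width - 2] = True
    candidates = list(range(10, width - 10, 4))
    rng.shuffle(candidates)
    spurs = []
    for c in candidates[:n_spurs]:
        length = int(rng.integers(2, max_len + 1))
        direction = -1 if rng.random() < 0.5 else 1
        length = min(length, r - 1 if direction < 0 else height - r - 2)
        if length < 2:
            continue
        pix = tuple((r + direction * s, c) for s in range(1, length + 1))
        for p in pix:
            skel[p] = True
        spurs.append((pix, length))
    return skel, spurs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
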