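"""Spur pruning for thin edge maps.

A *spur* is a branch of a skeleton that starts at an endpoint (a pixel
with exactly one foreground 8-neighbor) and terminates where it meets the
rest of the skeleton (a junction).  Spurs arise from small irregularities
in the predicted boundary and are removed up to a maximum length ``l``
derived from the pruning percentage ``gamma`` and the image diagonal:

    l = (gamma / 100) * sqrt(w**2 + h**2)

which makes pruning strength comparable across image sizes.

Branch length is the number of pixels from the endpoint up to, but not
including, the junction; a branch is removed when its length is <= ``l``
(the junction is always retained).  Pruning iterates to a fixed point,
since removing one spur can expose another.  Components that are entire
open curves (endpoint to endpoint, no junction) and closed loops are
never removed: pruning targets artifacts hanging off an edge, not the
edge itself.

Junction detection on 8-connected skeletons needs care: the base pixel of
a spur attached to a straight run is diagonally adjacent to several run
pixels, so a plain "three or more neighbors" rule would misplace the
junction.  The branch walk therefore groups the unvisited neighbors ahead
of the walk by mutual 8-adjacency:

* one group of three or more pixels -- the walk has hit the flank of a
  straight run; the current pixel is the spur's base (last branch pixel);
* two or more groups -- the current pixel is itself the junction and is
  excluded from the branch;
* one group of two mutually adjacent pixels -- the curve merely steps
  around a corner; the walk continues through the 4-adjacent one.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

from .io import as_binary
from .skeleton import NEIGHBOR_OFFSETS

__all__ = ["spur_length_limit", "prune_spurs", "trace_branches", "Branch"]


class Branch(NamedTuple):
    """A walk from an endpoint of a thin edge to its terminator.

    ``pixels`` excludes the terminating junction; ``kind`` is
    ``'junction'``, ``'endpoint'`` (the component is a whole open curve)
    or ``'none'`` (the walk closed onto itself).
    """

    pixels: tuple
    kind: str


def spur_length_limit(gamma: float, w: int, h: int) -> float:
    """Maximum spur length in pixels for pruning percentage *gamma*."""
    if not 0 <= gamma <= 100:
        raise ValueError(f"gamma must be in [0, 100], got {gamma}")
    if w < 1 or h < 1:
        raise ValueError("image dimensions must be >= 1")
    return (gamma / 100.0) * math.hypot(w, h)


def _fg_neighbors(fg: np.ndarray, i: int, j: int) -> list:
    h, w = fg.shape
    out = []
    for di, dj in NEIGHBOR_OFFSETS:
        ni, nj = i + di, j + dj
        if 0 <= ni < h and 0 <= nj < w and fg[ni, nj]:
            out.append((ni, nj))
    return out


def _clusters(cells: list) -> list:
    """Group cells of a 3x3 ring by mutual 8-adjacency."""
    groups = []
    for c in cells:
        merged = None
        for g in groups:
            if any(max(abs(c[0] - o[0]), abs(c[1] - o[1])) <= 1 for o in g):
                if merged is None:
                    g.append(c)
                    merged = g
                else:  # c bridges two groups
                    merged.extend(g)
                    groups.remove(g)
        if merged is None:
            groups.append([c])
    return groups


def _walk(fg: np.ndarray, start: tuple) -> Branch:
    path = [start]
    visited = {start}
    cur = start
    while True:
        cands = [n for n in _fg_neighbors(fg, *cur) if n not in visited]
        if not cands:
            # Reached the far end of an open curve, or closed onto the
            # already-walked pixels; either way the component has no
            # junction along this walk and is exempt.
            kind = (
                "endpoint"
                if cur != start and len(_fg_neighbors(fg, *cur)) == 1
                else "none"
            )
            return Branch(tuple(path), kind)
        if len(cands) == 1:
            nxt = cands[0]
        else:
            groups = _clusters(cands)
            if len(groups) >= 2:
                # cur is the junction itself; it stays.
                path.pop()
                return Branch(tuple(path), "junction")
            if len(groups[0]) >= 3:
                # Flank of a straight run: cur is the spur's base pixel.
                return Branch(tuple(path), "junction")
            # An adjacent pair: the curve steps around a corner.  Continue
            # through the 4-adjacent candidate (deterministic row-major
            # tie-break).
            orth = [c for c in cands if abs(c[0] - cur[0]) + abs(c[1] - cur[1]) == 1]
            nxt = min(orth) if orth else min(cands)
        path.append(nxt)
        visited.add(nxt)
        cur = nxt


def trace_branches(edge: np.ndarray) -> list:
    """Walk from every endpoint of a thin edge map to its terminator.

    Returns one :class:`Branch` per endpoint, in row-major endpoint order.
    """
    fg = as_binary(edge)
    branches = []
    for i, j in zip(*np.nonzero(fg)):
        p = (int(i), int(j))
        if len(_fg_neighbors(fg, *p)) == 1:
            branches.append(_walk(fg, p))
    return branches


def prune_spurs(edge: np.ndarray, l: float) -> np.ndarray:
    """Remove every endpoint-to-junction branch of length <= *l* pixels.

    Branches are removed one at a time, shortest first (row-major
    endpoint on ties), re-tracing after each removal, until no removable
    branch remains.  The junction pixel is always retained, so the number
    of 8-connected components never changes; whole open curves, closed
    loops and isolated pixels are never touched.
    """
    out = as_binary(edge).copy()
    while True:
        removable = [
            b.pixels
            for b in trace_branches(out)
            if b.kind == "junction" and len(b.pixels) <= l
        ]
        if not removable:
            return out
        pixels = min(removable, key=lambda p: (len(p), p[0]))
        for i, j in pixels:
            out[i, j] = False
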