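"""Discrete combinatorial search over the {alpha, beta, gamma} triple.

Every combination in a :class:`SearchGrid` is evaluated on a validation
set of (boundary, ground-truth) pairs: the edge-extraction pipeline is run
and mean SDE and mean IoU-box are recorded.  The combination minimizing
mean SDE wins; mean IoU-box is reported but never used for selection.
Iteration order is alpha (outer, ascending as declared), then beta, then
gamma, and ties keep the first-encountered combination, so the search is
fully deterministic.

The default grid follows a coarse-but-practical stepping: every tenth
alpha value (0, 10, ..., 250), all three skeletonize methods, and gamma
over every integer 0..10 plus every tenth value 20..100 -- 1482
combinations in total.

Thresholding + skeletonization is cached across gamma values (pruning is
the only stage that depends on gamma); caching cannot change results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DegenerateImageError, as_binary, as_gray
from .metrics import iou_box, sde
from .pipeline import ParamSet, threshold
from .prune import prune_spurs, spur_length_limit
from .skeleton import SKELETON_METHODS, apply_skeletonize

__all__ = ["SearchGrid", "SearchResult", "default_grid", "grid_search"]


@dataclass(frozen=True)
class SearchGrid:
    """Ordered, duplicate-free candidate values for alpha, beta, gamma."""

    alphas: tuple
    betas: tuple
    gammas: tuple

    def __post_init__(self):
        object.__setattr__(self, "alphas", tuple(self.alphas))
        object.__setattr__(
            self, "betas", tuple(str(b).upper() for b in self.betas)
        )
        object.__setattr__(self, "gammas", tuple(self.gammas))
        for name, values in (("alphas", self.alphas), ("betas", self.betas), ("gammas", self.gammas)):
            if not values:
                raise ValueError(f"{name} must be non-empty")
            if len(set(values)) != len(values):
                raise ValueError(f"{name} contains duplicates: {values}")
        for a in self.alphas:
            if not 0 <= a <= 255:
                raise ValueError(f"alpha {a} outside [0, 255]")
        for b in self.betas:
            if b not in SKELETON_METHODS:
                raise ValueError(f"unknown skeletonize method {b!r}")
        for g in self.gammas:
            if not 0 <= g <= 100:
                raise ValueError(f"gamma {g} outside [0, 100]")

    def __len__(self) -> int:
        return len(self.alphas) * len(self.betas) * len(self.gammas)


@dataclass
class SearchResult:
    """Winning parameters plus the full evaluated table."""

    best: ParamSet
    best_mean_sde: float
    table: list  # (ParamSet, mean_sde, mean_iou_box) per combination

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "alpha": p.alpha,
                    "beta": p.beta,
                    "gamma": p.gamma,
                    "mean_sde": s,
                    "mean_iou_box": i,
                }
                for p, s, i in self.table
            ]
        )


def default_grid() -> SearchGrid:
    """Coarse default grid: 26 alphas x 3 betas x 19 gammas."""
    return SearchGrid(
        alphas=tuple(range(0, 260, 10)),
        betas=SKELETON_METHODS,
        gammas=tuple(range(0, 11)) + tuple(range(20, 101, 10)),
    )


def grid_search(boundaries, gts, grid: SearchGrid | None = None,
                progress=None) -> SearchResult:
    """Exhaustively evaluate *grid* and return the argmin-by-mean-SDE.

    Parameters
    ----------
    boundaries, gts
        Equal-length lists of gray boundary images and binary ground-truth
        edge maps with matching per-pair dimensions.
    grid
        Candidate values; :func:`default_grid` if omitted.
    progress
        Optional callable invoked as ``progress(ParamSet, mean_sde)`` after
        each evaluated combination.

    A pipeline failure on one image (e.g. a degenerate all-foreground
    input under GWPS) scores that image with an empty map -- the metrics'
    center-pixel correction then applies -- rather than aborting the
    search.
    """
    boundaries = [as_gray(b) for b in boundaries]
    gts = [as_binary(g) for g in gts]
    if not boundaries:
        raise ValueError("boundary list must be non-empty")
    if len(boundaries) != len(gts):
        raise ValueError(
            f"got {len(boundaries)} boundaries but {len(gts)} ground-truth maps"
        )
    for b, g in zip(boundaries, gts):
        if b.shape != g.shape:
            raise ValueError(
                f"pair dimension mismatch: {b.shape} vs {g.shape}"
            )
    if grid is None:
        grid = default_grid()

    table = []
    best = None
    for alpha in grid.alphas:
        for beta in grid.betas:
            skels = []
            for b in boundaries:
                try:
                    skels.append(apply_skeletonize(threshold(b, alpha), beta))
                except DegenerateImageError:
                    skels.append(None)
            for gamma in grid.gammas:
                sdes, ious = [], []
                for skel, b, gt in zip(skels, boundaries, gts):
                    if skel is None:
                        pred = np.zeros_like(gt)
                    else:
                        h, w = b.shape
                        pred = prune_spurs(
                            skel, spur_length_limit(gamma, w, h)
                        )
                    sdes.append(sde(pred, gt))
                    ious.append(iou_box(pred, gt))
                p = ParamSet(alpha, beta, gamma)
                row = (p, float(np.mean(sdes)), float(np.mean(ious)))
                table.append(row)
                if best is None or row[1] < best[1]:
                    best = row
                if progress is not None:
                    progress(p, row[1])
    return SearchResult(best=best[0], best_mean_sde=best[1], table=table)
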