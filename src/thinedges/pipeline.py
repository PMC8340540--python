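"""The edge-extraction function: threshold, skeletonize, prune.

A predicted boundary image (gray, intensity = confidence) is mapped to a
binary 1-pixel thin edge in three parameterized stages:

1. *threshold* by ``alpha``: intensities strictly below ``alpha`` become
   zero (a rudimentary noise filter); pixels at or above ``alpha`` keep
   their value.
2. *skeletonize* by ``beta``: one of ``'2D'``, ``'3D'``, ``'GWPS'``.
3. *prune* by ``gamma``: spurs up to ``(gamma/100) * image diagonal``
   pixels long are removed.

The parameter triple is bounded: ``0 <= alpha <= 255``,
``beta in {'2D', '3D', 'GWPS'}``, ``0 <= gamma <= 100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import as_gray
from .prune import prune_spurs, spur_length_limit
from .skeleton import SKELETON_METHODS, apply_skeletonize

__all__ = ["ParamSet", "threshold", "extract_edges"]


@dataclass(frozen=True)
class ParamSet:
    """The {alpha, beta, gamma} triple parameterizing edge extraction."""

    alpha: int
    beta: str
    gamma: int

    def __post_init__(self):
        if not 0 <= self.alpha <= 255:
            raise ValueError(f"alpha must be in [0, 255], got {self.alpha}")
        object.__setattr__(self, "beta", str(self.beta).upper())
        if self.beta not in SKELETON_METHODS:
            raise ValueError(
                f"beta must be one of {SKELETON_METHODS}, got {self.beta!r}"
            )
        if not 0 <= self.gamma <= 100:
            raise ValueError(f"gamma must be in [0, 100], got {self.gamma}")


def threshold(g: np.ndarray, alpha: int) -> np.ndarray:
    """Zero every pixel strictly below *alpha*; others keep their value."""
    if not 0 <= alpha <= 255:
        raise ValueError(f"alpha must be in [0, 255], got {alpha}")
    g = as_gray(g)
    return np.where(g < alpha, 0, g).astype(np.uint8)


def extract_edges(g: np.ndarray, p: ParamSet) -> np.ndarray:
    """Full edge extraction: threshold -> skeletonize -> prune.

    Returns a binary thin-edge map whose foreground is contained in
    ``{(i, j): g[i, j] >= p.alpha}``.  With ``gamma == 0`` the pruning
    stage is the identity.
    """
    g = as_gray(g)
    h, w = g.shape
    skel = apply_skeletonize(threshold(g, p.alpha), p.beta)
    return prune_spurs(skel, spur_length_limit(p.gamma, w, h))
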