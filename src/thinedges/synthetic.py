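"""Synthetic ramp-boundary generator.

Stands in for a boundary predictor: a known 1-pixel ground-truth curve is
rendered as a *ramp edge* -- intensity falls off from a peak at the curve
with a Gaussian cross-profile -- optionally degraded with additive noise,
small irregularities (short side-stubs that induce skeleton spurs) and
gaps (zeroed runs emulating incomplete boundaries).  Every pipeline stage
and the parameter search are therefore testable against a known answer
without any external data.

Defaults model a confident predictor on a mid-sized image: 96 x 96
pixels, ramp sigma 2 px, peak intensity 200, additive Gaussian noise with
standard deviation 8 (well below useful threshold values, so parameter
recovery is well-posed), no gaps, no irregularities.  All randomness runs
through ``numpy.random.default_rng`` seeded from the config, so output is
fully reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import CubicSpline
from skimage.draw import line as _draw_line

from .io import as_binary, write_edge_map

__all__ = [
    "GeneratorConfig",
    "SyntheticSample",
    "generate_curve",
    "render_boundary",
    "generate_sample",
    "generate_dataset",
]

CURVE_KINDS = ("open-spline", "closed-ellipse")

_MARGIN = 3  # ground-truth curves stay >= _MARGIN pixels from the border


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic boundary sample.

    height, width
        Image size in pixels.
    curve
        ``'open-spline'`` (a wavy left-to-right curve) or
        ``'closed-ellipse'`` (a jittered ellipse loop).
    sigma
        Gaussian cross-profile width of the ramp, pixels.
    peak
        Peak intensity on the curve, in [1, 255].
    noise
        Standard deviation of additive Gaussian pixel noise.
    gap_prob
        Per curve-segment probability of zeroing a short run,
        emulating an incomplete boundary.
    irregularity
        Maximum length (pixels) of short stubs grown off the curve before
        rendering; they thicken the boundary locally and induce spurs.
    seed
        Base seed for all randomness.
    """

    height: int = 96
    width: int = 96
    curve: str = "open-spline"
    sigma: float = 2.0
    peak: int = 200
    noise: float = 8.0
    gap_prob: float = 0.0
    irregularity: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.curve not in CURVE_KINDS:
            raise ValueError(f"curve must be one of {CURVE_KINDS}")
        if self.height < 8 * _MARGIN or self.width < 8 * _MARGIN:
            raise ValueError(
                f"image too small for a curve: need at least "
                f"{8 * _MARGIN} x {8 * _MARGIN} pixels"
            )
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 1 <= self.peak <= 255:
            raise ValueError("peak intensity must be in [1, 255]")
        if self.noise < 0:
            raise ValueError("noise level must be non-negative")
        if not 0 <= self.gap_prob <= 1:
            raise ValueError("gap probability must be in [0, 1]")
        if self.irregularity < 0:
            raise ValueError("irregularity amplitude must be non-negative")


@dataclass(frozen=True)
class SyntheticSample:
    """A rendered boundary image paired with its 1-pixel ground truth."""

    boundary: np.ndarray
    gt_edge: np.ndarray
    config: GeneratorConfig


def _thin_chain(points: list, closed: bool) -> list:
    """Drop chain pixels whose two chain-neighbors are already 8-adjacent.

    Iterates to a fixed point, yielding a minimal 8-connected digital
    path (or loop) through the sampled curve.
    """
    pts = list(dict.fromkeys(points))  # dedupe, order-preserving
    changed = True
    while changed and len(pts) > 3:
        changed = False
        kept = []
        n = len(pts)
        skip_prev = False
        for idx in range(n):
            if not closed and (idx == 0 or idx == n - 1):
                kept.append(pts[idx])
                continue
            if skip_prev:
                skip_prev = False
                kept.append(pts[idx])
                continue
            a = pts[(idx - 1) % n]
            b = pts[(idx + 1) % n]
            if max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 1:
                changed = True  # drop pts[idx]
                skip_prev = True
            else:
                kept.append(pts[idx])
        pts = kept
    return pts


def _rasterize(rows: np.ndarray, cols: np.ndarray, closed: bool) -> list:
    """Round a dense parametric curve to an 8-connected pixel chain."""
    ri = np.rint(rows).astype(int)
    ci = np.rint(cols).astype(int)
    chain = []
    n = len(ri)
    stop = n if not closed else n + 1
    for k in range(stop - 1):
        a = (ri[k % n], ci[k % n])
        b = (ri[(k + 1) % n], ci[(k + 1) % n])
        rr, cc = _draw_line(a[0], a[1], b[0], b[1])
        seg = list(zip(rr.tolist(), cc.tolist()))
        if chain and seg and seg[0] == chain[-1]:
            seg = seg[1:]
        chain.extend(seg)
    if closed and chain and chain[-1] == chain[0]:
        chain.pop()
    return _thin_chain(chain, closed)


def _curve_chain(cfg: GeneratorConfig, rng: np.random.Generator) -> tuple:
    """Ordered pixel chain of the ground-truth curve, plus closedness."""
    h, w = cfg.height, cfg.width
    if cfg.curve == "open-spline":
        # A wavy function col -> row: monotone in the column, so the curve
        # never self-intersects or self-touches.
        n_ctrl = int(rng.integers(4, 7))
        xs = np.linspace(_MARGIN, w - 1 - _MARGIN, n_ctrl)
        ys = rng.uniform(_MARGIN + 2, h - 3 - _MARGIN, size=n_ctrl)
        spline = CubicSpline(xs, ys)
        t = np.linspace(xs[0], xs[-1], 6 * w)
        rows = np.clip(spline(t), _MARGIN, h - 1 - _MARGIN)
        return _rasterize(rows, t, closed=False), False
    # closed-ellipse
    cy = h / 2 + rng.uniform(-h * 0.05, h * 0.05)
    cx = w / 2 + rng.uniform(-w * 0.05, w * 0.05)
    a = rng.uniform(0.28, 0.40) * (w - 2 * _MARGIN)
    b = rng.uniform(0.28, 0.40) * (h - 2 * _MARGIN)
    phi = rng.uniform(0, np.pi)
    t = np.linspace(0, 2 * np.pi, 1440, endpoint=False)
    rows = cy + b * np.sin(t) * np.cos(phi) + a * np.cos(t) * np.sin(phi)
    cols = cx + a * np.cos(t) * np.cos(phi) - b * np.sin(t) * np.sin(phi)
    rows = np.clip(rows, _MARGIN, h - 1 - _MARGIN)
    cols = np.clip(cols, _MARGIN, w - 1 - _MARGIN)
    return _rasterize(rows, cols, closed=True), True


def generate_curve(cfg: GeneratorConfig) -> np.ndarray:
    """Rasterize the sample's random smooth curve as a thin binary map.

    The curve is 8-connected, 1 pixel wide, and stays at least 2 pixels
    away from the image border.  An open spline has exactly two
    endpoints; a closed ellipse forms a single loop in which every pixel
    has exactly two foreground neighbors.
    """
    rng = np.random.default_rng(cfg.seed)
    chain, _ = _curve_chain(cfg, rng)
    gt = np.zeros((cfg.height, cfg.width), dtype=bool)
    for i, j in chain:
        gt[i, j] = True
    return gt


def _zero_intensity_radius(cfg: GeneratorConfig) -> float:
    """Distance beyond which the rendered ramp rounds to zero."""
    return cfg.sigma * np.sqrt(2.0 * np.log(2.0 * cfg.peak))


def _apply_gaps(chain: list, cfg: GeneratorConfig,
                rng: np.random.Generator) -> list:
    """Remove short runs of curve pixels, one possible gap per segment.

    The removed run is long enough (relative to the ramp's footprint)
    that the rendered intensity decays to zero inside the gap, splitting
    the boundary into separate blobs.
    """
    run = int(np.ceil(2 * _zero_intensity_radius(cfg))) + 5
    seg_len = run + 10
    n = len(chain)
    keep = np.ones(n, dtype=bool)
    for start in range(0, n, seg_len):
        seg = range(start, min(start + seg_len, n))
        if len(seg) < run + 2:
            continue
        if rng.random() < cfg.gap_prob:
            mid = start + len(seg) // 2
            lo = max(seg[0] + 1, mid - run // 2)
            keep[lo:lo + run] = False
    return [p for p, k in zip(chain, keep) if k]


def _apply_irregularities(support: np.ndarray, chain: list,
                          cfg: GeneratorConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Grow short random stubs off the curve into the support mask."""
    max_len = int(np.ceil(cfg.irregularity))
    if max_len == 0 or not chain:
        return support
    h, w = support.shape
    out = support.copy()
    n_stubs = max(1, len(chain) // 12)
    anchors = rng.choice(len(chain), size=n_stubs, replace=False)
    for a in anchors:
        i, j = chain[a]
        di, dj = 0, 0
        while di == 0 and dj == 0:
            di, dj = int(rng.integers(-1, 2)), int(rng.integers(-1, 2))
        length = int(rng.integers(1, max_len + 1))
        for step in range(1, length + 1):
            ni, nj = i + step * di, j + step * dj
            if not (0 <= ni < h and 0 <= nj < w):
                break
            out[ni, nj] = True
    return out


def render_boundary(gt: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Render a thin ground-truth curve as a gray ramp-boundary image.

    Intensity at distance ``d`` from the nearest curve pixel is
    ``round(peak * exp(-d**2 / (2 sigma**2)))``, zeroed where it falls
    below 1, then degraded with gaps, irregularities and additive noise
    as configured.
    """
    gt = as_binary(gt)
    if not gt.any():
        raise ValueError("ground-truth curve must be non-empty")
    rng = np.random.default_rng([int(cfg.seed), 0x5EED])

    support = gt.copy()
    chain = _order_curve(gt)
    if cfg.gap_prob > 0 and chain:
        kept = _apply_gaps(chain, cfg, rng)
        support = np.zeros_like(gt)
        for i, j in kept:
            support[i, j] = True
        if not support.any():  # everything gapped away: keep one pixel
            support[chain[0]] = True
    if cfg.irregularity > 0:
        support = _apply_irregularities(support, chain, cfg, rng)

    d = ndi.distance_transform_edt(~support)
    img = np.rint(cfg.peak * np.exp(-(d ** 2) / (2.0 * cfg.sigma ** 2)))
    img[img < 1] = 0
    if cfg.noise > 0:
        img = img + rng.normal(0.0, cfg.noise, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _order_curve(gt: np.ndarray) -> list:
    """Order the pixels of a thin curve from an endpoint (or loop start).

    Returns the ordered chain of the largest traversal; used to place
    gaps and irregularities along the curve.
    """
    from .prune import _fg_neighbors  # local import avoids a cycle

    fg = gt.copy()
    coords = list(zip(*np.nonzero(fg)))
    if not coords:
        return []
    degrees = {p: len(_fg_neighbors(fg, *p)) for p in coords}
    endpoints = [p for p, dg in degrees.items() if dg == 1]
    start = min(endpoints) if endpoints else min(coords)
    chain = [start]
    visited = {start}
    cur = start
    while True:
        nxt = None
        for nb in _fg_neighbors(fg, *cur):
            if nb not in visited:
                nxt = nb
                break
        if nxt is None:
            break
        chain.append(nxt)
        visited.add(nxt)
        cur = nxt
    return [(int(i), int(j)) for i, j in chain]


def generate_sample(cfg: GeneratorConfig) -> SyntheticSample:
    """One (boundary, ground truth) pair under *cfg*."""
    gt = generate_curve(cfg)
    return SyntheticSample(render_boundary(gt, cfg), gt, cfg)


def generate_dataset(n: int, cfg: GeneratorConfig,
                     out_dir: str | None = None) -> list:
    """Generate *n* samples with per-sample seeds ``cfg.seed + index``.

    With *out_dir* set, writes ``boundaries/NNN.png`` and ``gt/NNN.png``
    pairs plus a ``manifest.json`` recording the base configuration.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    samples = [
        generate_sample(replace(cfg, seed=cfg.seed + k)) for k in range(n)
    ]
    if out_dir is not None:
        import imageio.v3 as iio

        bdir = os.path.join(out_dir, "boundaries")
        gdir = os.path.join(out_dir, "gt")
        os.makedirs(bdir, exist_ok=True)
        os.makedirs(gdir, exist_ok=True)
        for k, s in enumerate(samples):
            iio.imwrite(os.path.join(bdir, f"{k:03d}.png"), s.boundary)
            write_edge_map(s.gt_edge, os.path.join(gdir, f"{k:03d}.png"))
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump({"n": n, "config": asdict(cfg)}, fh, indent=2)
    return samples
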