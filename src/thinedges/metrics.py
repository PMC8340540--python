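"""Evaluation metrics for thin edges: SDE and IoU-box.

*SDE* (symmetric distance error) integrates precision- and recall-like
directional errors: the mean Euclidean distance from each predicted pixel
to the nearest ground-truth pixel, and vice versa, averaged.  Lower is
better; 0 iff the pixel sets coincide.

*IoU-box* scores shape and absolute position: axis-aligned bounding boxes
of the 8-connected components on each side are matched greedily
(one-to-one, descending box IoU) and the matched IoUs are averaged over
ground-truth components (unmatched components score 0).

An entirely empty map would make both metrics ill-defined, so before
scoring, an empty map has a single edge pixel placed at its center
(``floor(h/2), floor(w/2)``).  The correction is applied inside the
metrics only; saved outputs are never mutated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import as_binary

__all__ = [
    "ensure_nonempty",
    "sde",
    "iou_box",
    "EvalScores",
    "EvalReport",
    "evaluate_pairs",
]

_STRUCTURE8 = np.ones((3, 3), dtype=int)


def ensure_nonempty(b: np.ndarray) -> np.ndarray:
    """Return *b*, or a copy with a single center pixel if *b* is empty."""
    b = as_binary(b)
    if b.any():
        return b
    out = b.copy()
    out[b.shape[0] // 2, b.shape[1] // 2] = True
    return out


def _check_same_shape(pred: np.ndarray, gt: np.ndarray):
    pred, gt = as_binary(pred), as_binary(gt)
    if pred.shape != gt.shape:
        raise ValueError(
            f"shape mismatch: prediction {pred.shape} vs ground truth {gt.shape}"
        )
    return pred, gt


def sde(pred: np.ndarray, gt: np.ndarray) -> float:
    """Symmetric distance error between two edge maps, in pixels."""
    pred, gt = _check_same_shape(pred, gt)
    p = ensure_nonempty(pred)
    g = ensure_nonempty(gt)
    dist_to_g = ndi.distance_transform_edt(~g)
    dist_to_p = ndi.distance_transform_edt(~p)
    return float(dist_to_g[p].mean() + dist_to_p[g].mean()) / 2.0


def _component_boxes(b: np.ndarray) -> list:
    """Inclusive (r0, r1, c0, c1) bounding boxes of 8-connected components."""
    labels, n = ndi.label(b, structure=_STRUCTURE8)
    boxes = []
    for sl in ndi.find_objects(labels, max_label=n):
        boxes.append((sl[0].start, sl[0].stop - 1, sl[1].start, sl[1].stop - 1))
    return boxes


def _box_iou(a, b) -> float:
    r0, r1 = max(a[0], b[0]), min(a[1], b[1])
    c0, c1 = max(a[2], b[2]), min(a[3], b[3])
    inter = max(0, r1 - r0 + 1) * max(0, c1 - c0 + 1)
    if inter == 0:
        return 0.0
    area_a = (a[1] - a[0] + 1) * (a[3] - a[2] + 1)
    area_b = (b[1] - b[0] + 1) * (b[3] - b[2] + 1)
    return inter / (area_a + area_b - inter)


def iou_box(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean bounding-box IoU over ground-truth components, in [0, 1]."""
    pred, gt = _check_same_shape(pred, gt)
    p_boxes = _component_boxes(ensure_nonempty(pred))
    g_boxes = _component_boxes(ensure_nonempty(gt))

    pairs = [
        (_box_iou(gb, pb), gi, pi)
        for gi, gb in enumerate(g_boxes)
        for pi, pb in enumerate(p_boxes)
    ]
    # Greedy one-to-one matching, best overlaps first; deterministic
    # tie-break by (gt index, pred index).
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_g, matched_p = set(), set()
    total = 0.0
    for iou, gi, pi in pairs:
        if iou <= 0.0:
            break
        if gi in matched_g or pi in matched_p:
            continue
        matched_g.add(gi)
        matched_p.add(pi)
        total += iou
    return total / len(g_boxes)


@dataclass(frozen=True)
class EvalScores:
    """Scores of one prediction/ground-truth pair."""

    sde: float
    iou_box: float


@dataclass
class EvalReport:
    """Per-image scores plus mean / median / population-std aggregates."""

    scores: list
    names: list = field(default_factory=list)

    def _values(self, metric: str) -> np.ndarray:
        return np.array([getattr(s, metric) for s in self.scores], dtype=float)

    def aggregate(self, metric: str) -> dict:
        v = self._values(metric)
        return {
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "std": float(v.std()),  # population standard deviation
        }

    @property
    def mean_sde(self) -> float:
        return self.aggregate("sde")["mean"]

    @property
    def mean_iou_box(self) -> float:
        return self.aggregate("iou_box")["mean"]

    def to_frame(self) -> pd.DataFrame:
        names = self.names or [str(i) for i in range(len(self.scores))]
        return pd.DataFrame(
            {
                "name": names,
                "sde": self._values("sde"),
                "iou_box": self._values("iou_box"),
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_json(self, path) -> None:
        payload = {
            "per_image": self.to_frame().to_dict(orient="records"),
            "aggregates": {
                "sde": self.aggregate("sde"),
                "iou_box": self.aggregate("iou_box"),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def evaluate_pairs(preds, gts, names=None) -> EvalReport:
    """Score matched prediction/ground-truth lists and aggregate."""
    preds, gts = list(preds), list(gts)
    if len(preds) != len(gts):
        raise ValueError(
            f"got {len(preds)} predictions but {len(gts)} ground-truth maps"
        )
    if not preds:
        raise ValueError("cannot evaluate an empty list of image pairs")
    scores = [EvalScores(sde(p, g), iou_box(p, g)) for p, g in zip(preds, gts)]
    return EvalReport(scores, list(names) if names else [])
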