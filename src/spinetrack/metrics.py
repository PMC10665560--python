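"""Overlap scores and detection-evaluation statistics.

Two families of overlap live here.  The standard Intersection over Union
(IoU) and the Intersection over Minimum (IoM), which divides the intersection
by the *smaller* of the two areas instead of the union:

    IoM_xy(D, G) = Area(D ∩ G) / min(Area(D), Area(G))

IoM is always >= IoU and is better behaved for small objects such as
dendritic spines, where slight positional offsets between two tight boxes
collapse the IoU but barely change the IoM.

For 3D spine tracks, an xy-score (IoM of the z-averaged boxes) and a z-score
(interval overlap over the shorter interval) are combined by an F-beta mean
with beta = 0.5, weighting the xy term more:

    IoM(D, G) = 5 * IoM_xy * IoM_z / (IoM_xy + 4 * IoM_z)

TP/FP/FN are decided at a threshold on this combined score (default 0.5, with
the boundary counting as a hit) and summarized by the F1 score
2*TP / (2*TP + FP + FN).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .types import Box2D, Detection2D, PipelineConfig, SpineTrack3D

logger = logging.getLogger(__name__)

__all__ = [
    "MatchReport",
    "box_area",
    "intersection_area",
    "iou_2d",
    "iom_xy_2d",
    "iom_z",
    "mean_box",
    "iom_3d",
    "f_beta",
    "f1_score",
    "match_3d",
    "evaluate_2d",
]

Interval = tuple[int, int]
MatchingMode = Literal["existential", "one_to_one"]


@dataclass
class MatchReport:
    """TP/FP/FN counts, matched pairs and the resulting F1 score."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    f1: float = 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "f1": self.f1,
            "pairs": [
                {"detection": d, "ground_truth": g, "score": s}
                for d, g, s in self.pairs
            ],
        }

    def to_json(self, config: PipelineConfig | None = None) -> str:
        out = self.to_dict()
        if config is not None:
            out["config"] = config.to_dict()
        return json.dumps(out, indent=2)


def box_area(b: Box2D) -> float:
    """Area of an axis-aligned box, (x_max - x_min) * (y_max - y_min)."""
    return b.area


def intersection_area(b1: Box2D, b2: Box2D) -> float:
    """Overlap area of two boxes; 0 when they are disjoint."""
    ox = min(b1.x_max, b2.x_max) - max(b1.x_min, b2.x_min)
    oy = min(b1.y_max, b2.y_max) - max(b1.y_min, b2.y_min)
    return max(0.0, ox) * max(0.0, oy)


def iou_2d(b1: Box2D, b2: Box2D) -> float:
    """Intersection over Union of two boxes, in [0, 1]."""
    inter = intersection_area(b1, b2)
    union = b1.area + b2.area - inter
    return inter / union


def iom_xy_2d(d: Box2D, g: Box2D) -> float:
    """Intersection over Minimum of two boxes, in [0, 1].

    Symmetric, and always >= :func:`iou_2d` of the same pair.
    """
    return intersection_area(d, g) / min(d.area, g.area)


def iom_z(
    d_interval: Interval,
    g_interval: Interval,
    convention: Literal["slice_count", "literal"] = "slice_count",
) -> float:
    """Fractional overlap of two inclusive slice-index intervals.

    ``slice_count`` (default) counts slices: the number of shared slices over
    the length of the shorter interval, with length z2 - z1 + 1.  This is
    well defined for single-slice intervals.

    ``literal`` uses the raw endpoint arithmetic
    max(0, min(z2s) - max(z1s)) / min(z2 - z1, ...), whose denominator is 0
    for single-slice intervals; that degenerate case is defined as 1 when the
    intervals are equal and 0 otherwise.
    """
    (d1, d2), (g1, g2) = d_interval, g_interval
    if d2 < d1 or g2 < g1:
        raise ValueError(f"malformed interval: {d_interval} vs {g_interval}")
    if convention == "slice_count":
        shared = max(0, min(d2, g2) - max(d1, g1) + 1)
        shorter = min(d2 - d1 + 1, g2 - g1 + 1)
        return shared / shorter
    if convention == "literal":
        num = max(0, min(d2, g2) - max(d1, g1))
        den = min(d2 - d1, g2 - g1)
        if den == 0:
            return 1.0 if (d1, d2) == (g1, g2) and d1 == d2 else 0.0
        return num / den
    raise ValueError(f"unknown z-length convention {convention!r}")


def mean_box(track: SpineTrack3D) -> Box2D:
    """Coordinate-wise mean of a track's per-slice boxes.

    The average runs over the slice count (z2 - z1 + 1 boxes), so a
    single-slice track returns its own box.
    """
    n = track.n_slices
    sums = [0.0, 0.0, 0.0, 0.0]
    for z in range(track.z_first, track.z_second + 1):
        for i, c in enumerate(track.boxes_by_slice[z].as_tuple()):
            sums[i] += c
    return Box2D(*(s / n for s in sums))


def f_beta(x: float, y: float, beta: float = 0.5) -> float:
    """Weighted harmonic mean (1 + b^2) x y / (b^2 x + y); 0 when x = y = 0.

    With beta = 0.5 this is 5xy / (x + 4y), weighting ``x`` more than ``y``.
    """
    b2 = beta * beta
    den = b2 * x + y
    if den == 0.0:
        return 0.0
    return (1.0 + b2) * x * y / den


def iom_3d(
    d: SpineTrack3D,
    g: SpineTrack3D,
    beta: float = 0.5,
    z_convention: Literal["slice_count", "literal"] = "slice_count",
) -> float:
    """Combined 3D IoM of two spine tracks, in [0, 1].

    The xy component is the IoM of the z-averaged boxes; the z component is
    the interval overlap.  The two are merged by :func:`f_beta`, which at the
    default beta = 0.5 is 5xy / (x + 4y), so 1 iff both components are 1.
    """
    x = iom_xy_2d(mean_box(d), mean_box(g))
    y = iom_z(d.z_interval, g.z_interval, convention=z_convention)
    return f_beta(x, y, beta=beta)


def f1_score(tp: int, fp: int, fn: int) -> float:
    """2*TP / (2*TP + FP + FN); 0 (with a warning) when all counts are 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    den = 2 * tp + fp + fn
    if den == 0:
        logger.warning("f1_score of empty-vs-empty sets is reported as 0")
        return 0.0
    return 2 * tp / den


def _match_scores(
    scores: list[list[float]], threshold: float, mode: MatchingMode
) -> MatchReport:
    """Match a detections x ground-truths score matrix at a threshold.

    ``existential``: a detection is TP iff some gt reaches score >= threshold
    (its best-scoring gt is recorded as the pair); a gt is FN iff no detection
    reaches the threshold against it.  Two detections may claim one gt.

    ``one_to_one``: greedy pairing by descending score, each side used at
    most once; ties break by (lower detection index, lower gt index).
    """
    n_d = len(scores)
    n_g = len(scores[0]) if n_d else 0
    pairs: list[tuple[int, int, float]] = []
    if mode == "existential":
        tp = 0
        for i in range(n_d):
            best_j, best_s = -1, -1.0
            for j in range(n_g):
                if scores[i][j] > best_s:
                    best_j, best_s = j, scores[i][j]
            if best_j >= 0 and best_s >= threshold:
                tp += 1
                pairs.append((i, best_j, best_s))
        fp = n_d - tp
        fn = sum(
            1
            for j in range(n_g)
            if all(scores[i][j] < threshold for i in range(n_d))
        )
    elif mode == "one_to_one":
        cand = [
            (-scores[i][j], i, j)
            for i in range(n_d)
            for j in range(n_g)
            if scores[i][j] >= threshold
        ]
        cand.sort()
        used_d: set[int] = set()
        used_g: set[int] = set()
        for neg_s, i, j in cand:
            if i in used_d or j in used_g:
                continue
            used_d.add(i)
            used_g.add(j)
            pairs.append((i, j, -neg_s))
        tp = len(pairs)
        fp = n_d - tp
        fn = n_g - tp
    else:
        raise ValueError(f"unknown matching mode {mode!r}")
    report = MatchReport(tp=tp, fp=fp, fn=fn, pairs=pairs)
    report.f1 = f1_score(tp, fp, fn) if (tp + fp + fn) else 0.0
    return report


def match_3d(
    detections: Sequence[SpineTrack3D],
    ground_truths: Sequence[SpineTrack3D],
    threshold: float = 0.5,
    mode: MatchingMode = "existential",
    beta: float = 0.5,
    z_convention: Literal["slice_count", "literal"] = "slice_count",
) -> MatchReport:
    """Match detected 3D tracks against ground-truth tracks by combined IoM.

    A score exactly at the threshold counts as a hit (TP requires
    IoM(D, G) >= threshold).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    scores = [
        [iom_3d(d, g, beta=beta, z_convention=z_convention) for g in ground_truths]
        for d in detections
    ]
    if not detections:
        rep = MatchReport(tp=0, fp=0, fn=len(ground_truths))
        rep.f1 = f1_score(0, 0, len(ground_truths)) if ground_truths else 0.0
        return rep
    return _match_scores(scores, threshold, mode)


def evaluate_2d(
    detections: Sequence[Detection2D],
    ground_truths: Sequence[tuple[int, Box2D]],
    threshold: float = 0.5,
    mode: MatchingMode = "existential",
) -> MatchReport:
    """Per-slice 2D evaluation with IoM_xy, aggregated into a single F1.

    Detections and ground truths are compared only within the same slice,
    with the same existential / one-to-one semantics as :func:`match_3d`;
    TP/FP/FN are summed over slices.  Reported pair indices refer to the
    positions in the input sequences.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    slices = sorted(
        {d.slice_index for d in detections} | {s for s, _ in ground_truths}
    )
    tp = fp = fn = 0
    pairs: list[tuple[int, int, float]] = []
    for s in slices:
        d_idx = [i for i, d in enumerate(detections) if d.slice_index == s]
        g_idx = [j for j, (gs, _) in enumerate(ground_truths) if gs == s]
        if not d_idx:
            fn += len(g_idx)
            continue
        scores = [
            [iom_xy_2d(detections[i].box, ground_truths[j][1]) for j in g_idx]
            for i in d_idx
        ]
        rep = _match_scores(scores, threshold, mode)
        tp += rep.tp
        fp += rep.fp
        fn += rep.fn
        pairs.extend((d_idx[i], g_idx[j], sc) for i, j, sc in rep.pairs)
    report = MatchReport(tp=tp, fp=fp, fn=fn, pairs=pairs)
    report.f1 = f1_score(tp, fp, fn) if (tp + fp + fn) else 0.0
    return report
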