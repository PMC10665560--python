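"""Reduce raw per-slice detections to relevant ones before tracking.

Three rules, all with *strict* inequalities: keep boxes with confidence
greater than the probability threshold, drop boxes whose area exceeds the
size cap (oversized boxes defeat the IoM, which divides by the smaller
area), and suppress same-slice duplicates whose pairwise IoM exceeds the
overlap threshold, keeping the highest-confidence one.
"""

from __future__ import annotations

from typing import Sequence

from .metrics import iom_xy_2d
from .types import Detection2D, PipelineConfig, detections_by_slice

__all__ = [
    "filter_by_confidence",
    "filter_by_area",
    "suppress_duplicates",
    "postprocess_slice",
    "postprocess_detections",
]


def filter_by_confidence(
    dets: Sequence[Detection2D], threshold: float = 0.5
) -> list[Detection2D]:
    """Keep exactly the detections with confidence strictly above threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return [d for d in dets if d.confidence > threshold]


def filter_by_area(
    dets: Sequence[Detection2D], area_threshold_px: float = 2000.0
) -> list[Detection2D]:
    """Remove detections whose box area strictly exceeds the threshold.

    A box of area exactly the threshold is kept.
    """
    if area_threshold_px <= 0:
        raise ValueError(f"area_threshold_px must be > 0, got {area_threshold_px}")
    return [d for d in dets if d.box.area <= area_threshold_px]


def suppress_duplicates(
    dets: Sequence[Detection2D], iom_threshold: float = 0.5
) -> list[Detection2D]:
    """Greedy same-slice duplicate suppression by descending confidence.

    A detection is accepted iff its IoM_xy with every already-accepted
    detection is <= the threshold; suppression fires only when the overlap is
    strictly greater.  All inputs must lie on one slice.  Ties in confidence
    break by input order, so the result is deterministic.
    """
    if not (0.0 <= iom_threshold <= 1.0):
        raise ValueError(f"iom_threshold must be in [0, 1], got {iom_threshold}")
    if len({d.slice_index for d in dets}) > 1:
        raise ValueError("suppress_duplicates expects detections on a single slice")
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    accepted: list[Detection2D] = []
    for i in order:
        d = dets[i]
        if all(iom_xy_2d(d.box, a.box) <= iom_threshold for a in accepted):
            accepted.append(d)
    return accepted


def postprocess_slice(
    dets: Sequence[Detection2D], config: PipelineConfig | None = None
) -> list[Detection2D]:
    """Confidence filter, then area filter, then duplicate suppression."""
    cfg = config or PipelineConfig()
    out = filter_by_confidence(dets, cfg.confidence_threshold)
    out = filter_by_area(out, cfg.area_threshold_px)
    return suppress_duplicates(out, cfg.duplicate_iom_threshold)


def postprocess_detections(
    dets: Sequence[Detection2D],
    config: PipelineConfig | None = None,
    depth: int | None = None,
) -> dict[int, list[Detection2D]]:
    """Apply :func:`postprocess_slice` per slice; returns slice -> detections."""
    cfg = config or PipelineConfig()
    grouped = detections_by_slice(dets, depth=depth)
    return {s: postprocess_slice(ds, cfg) for s, ds in sorted(grouped.items())}
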