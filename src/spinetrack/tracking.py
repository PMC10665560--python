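"""Assemble per-slice detections into 3D spine tracks.

The tracker sweeps the stack from the top slice downward.  On each slice the
surviving detections are compared to the open tracks by IoM_xy against each
track's last observed box; pairs are accepted greedily in descending score
order while the score strictly exceeds the match threshold.  A track tolerates
missed detections on consecutive slices up to a limit (default: it survives
one missed slice and is closed on the second consecutive miss); detections
left unmatched open new tracks.

On finalization a track's z-interval spans its first to last actual
detection; interior gap slices are filled by linear interpolation of the four
box coordinates between the flanking detections (configurable off, in which
case the gap slice carries the previous box); the track's confidence is the
maximum over its member detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .metrics import iom_xy_2d
from .types import Box2D, Detection2D, PipelineConfig, SpineTrack3D

__all__ = ["ActiveTrack", "step_match", "track_stack", "tracks_to_mip_boxes"]


@dataclass
class ActiveTrack:
    """Mutable state of a spine being tracked through the sweep."""

    spine_id: int
    last_box: Box2D
    miss_count: int = 0
    history: list[tuple[int, Box2D, float]] = field(default_factory=list)

    def append(self, slice_index: int, box: Box2D, confidence: float) -> None:
        if self.history and slice_index <= self.history[-1][0]:
            raise ValueError("history slice indices must be strictly increasing")
        self.history.append((slice_index, box, confidence))
        self.last_box = box
        self.miss_count = 0


def step_match(
    active: Sequence[ActiveTrack],
    dets: Sequence[Detection2D],
    threshold: float = 0.5,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy one-to-one matching of open tracks to one slice's detections.

    Scores every (track.last_box, detection) pair by IoM_xy and accepts pairs
    in descending score order, each track and each detection used at most
    once, only while the score strictly exceeds the threshold.  Ties break by
    (lower track position, lower detection position) for determinism.

    Returns ``(assignments, unmatched_det_indices, unmatched_track_indices)``
    where assignments are (track position, detection position) pairs into the
    input sequences.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if len({d.slice_index for d in dets}) > 1:
        raise ValueError("step_match expects detections on a single slice")
    cand = [
        (-iom_xy_2d(t.last_box, d.box), ti, di)
        for ti, t in enumerate(active)
        for di, d in enumerate(dets)
    ]
    cand.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    assignments: list[tuple[int, int]] = []
    for neg_s, ti, di in cand:
        if -neg_s <= threshold:
            break
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        assignments.append((ti, di))
    unmatched_dets = [i for i in range(len(dets)) if i not in used_d]
    unmatched_tracks = [i for i in range(len(active)) if i not in used_t]
    return assignments, unmatched_dets, unmatched_tracks


def _interpolate_box(b0: Box2D, b1: Box2D, frac: float) -> Box2D:
    c = [
        (1.0 - frac) * a + frac * b
        for a, b in zip(b0.as_tuple(), b1.as_tuple())
    ]
    return Box2D(*c)


def _finalize(track: ActiveTrack, interpolate_gaps: bool) -> SpineTrack3D:
    hist = track.history
    z1, z2 = hist[0][0], hist[-1][0]
    boxes: dict[int, Box2D] = {s: b for s, b, _ in hist}
    interpolated: set[int] = set()
    for (s0, b0, _), (s1, b1, _) in zip(hist, hist[1:]):
        for gap in range(s0 + 1, s1):
            if interpolate_gaps:
                boxes[gap] = _interpolate_box(b0, b1, (gap - s0) / (s1 - s0))
            else:
                boxes[gap] = b0
            interpolated.add(gap)
    confidence = max(c for _, _, c in hist)
    return SpineTrack3D.from_boxes(
        spine_id=track.spine_id,
        boxes_by_slice=boxes,
        confidence=confidence,
        interpolated_slices=frozenset(interpolated),
    )


def track_stack(
    dets_by_slice: Mapping[int, Sequence[Detection2D]],
    config: PipelineConfig | None = None,
) -> list[SpineTrack3D]:
    """Sweep the stack top to bottom and link detections into 3D tracks.

    ``dets_by_slice`` maps slice index to that slice's (post-processed)
    detections; absent slices are treated as empty.  A track increments its
    miss count on each slice without an assigned detection and is closed once
    the count reaches ``max_consecutive_misses`` (default 2: a track survives
    one missed slice and stops after two consecutive misses); while open, it
    is matched using its last observed box.  New tracks receive sequential ids
    in order of first appearance, then left to right by x_min.

    Returned tracks are finalized (contiguous boxes, gaps interpolated,
    mean_box computed) and sorted by spine_id.
    """
    cfg = config or PipelineConfig()
    depth = (max(dets_by_slice) + 1) if dets_by_slice else 0
    active: list[ActiveTrack] = []
    finished: list[ActiveTrack] = []
    next_id = 0
    for s in range(depth):
        dets = list(dets_by_slice.get(s, ()))
        assignments, unmatched_dets, unmatched_tracks = step_match(
            active, dets, cfg.track_match_threshold
        )
        for ti, di in assignments:
            d = dets[di]
            active[ti].append(s, d.box, d.confidence)
        survivors: list[ActiveTrack] = [active[ti] for ti, _ in assignments]
        for ti in unmatched_tracks:
            t = active[ti]
            t.miss_count += 1
            if t.miss_count >= cfg.max_consecutive_misses:
                finished.append(t)
            else:
                survivors.append(t)
        # keep sweep order stable: sort survivors back to id order
        survivors.sort(key=lambda t: t.spine_id)
        for di in sorted(unmatched_dets, key=lambda i: dets[i].box.x_min):
            d = dets[di]
            t = ActiveTrack(spine_id=next_id, last_box=d.box)
            t.append(s, d.box, d.confidence)
            next_id += 1
            survivors.append(t)
        active = survivors
    finished.extend(active)
    tracks = [_finalize(t, cfg.interpolate_gaps) for t in finished if t.history]
    tracks.sort(key=lambda t: t.spine_id)
    return tracks


def tracks_to_mip_boxes(
    tracks: Sequence[SpineTrack3D],
) -> list[tuple[Box2D, int]]:
    """Each track's mean box with its id, for overlay on a max projection."""
    return [(t.mean_box, t.spine_id) for t in tracks]
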