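"""Fuse labels from several annotators into consensus ground truths.

Each annotator's per-slice boxes are first assembled into 3D tracks with the
same tracker used for detections (confidence fixed at 1).  Tracks from
different annotators that refer to the same spine are then clustered by
single-linkage on the combined 3D IoM, and each cluster is summarized by a
representative track.  Keeping clusters supported by at least *k* annotators
yields the *minimal* (k=1), *majority* (k=3 of 5) and *maximal* (k=5 of 5)
ground truths; by construction these are nested (maximal ⊆ majority ⊆
minimal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .metrics import iom_3d
from .tracking import track_stack
from .types import AnnotationSet, Box2D, Detection2D, PipelineConfig, SpineTrack3D

__all__ = [
    "ConsensusCluster",
    "build_annotator_tracks",
    "cluster_annotations",
    "fuse_ground_truth",
]


@dataclass
class ConsensusCluster:
    """Tracks (at most one per annotator) judged to be the same spine."""

    members: list[tuple[int, SpineTrack3D]]  # (annotator index, track)
    representative: SpineTrack3D

    @property
    def support(self) -> int:
        return len({a for a, _ in self.members})


def build_annotator_tracks(
    ann: AnnotationSet, config: PipelineConfig | None = None
) -> list[SpineTrack3D]:
    """Run the stack tracker over one annotator's boxes (confidence 1.0)."""
    cfg = config or PipelineConfig()
    by_slice: dict[int, list[Detection2D]] = {}
    for s, b in ann.boxes:
        by_slice.setdefault(s, []).append(Detection2D(box=b, slice_index=s, confidence=1.0))
    return track_stack(by_slice, cfg)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _nearest_box(track: SpineTrack3D, s: int) -> Box2D:
    if s < track.z_first:
        return track.boxes_by_slice[track.z_first]
    if s > track.z_second:
        return track.boxes_by_slice[track.z_second]
    return track.boxes_by_slice[s]


def _representative(
    members: Sequence[SpineTrack3D], spine_id: int
) -> SpineTrack3D:
    """Consensus track: rounded-mean z-endpoints, per-slice coordinate means.

    On each slice of the consensus interval every member contributes a box —
    its own where it covers the slice, its nearest endpoint box otherwise —
    and the representative box is their coordinate-wise mean.
    """
    z1 = _round_half_up(sum(t.z_first for t in members) / len(members))
    z2 = _round_half_up(sum(t.z_second for t in members) / len(members))
    if z2 < z1:
        z2 = z1
    boxes = {}
    for s in range(z1, z2 + 1):
        coords = [_nearest_box(t, s).as_tuple() for t in members]
        mean = [sum(c[i] for c in coords) / len(coords) for i in range(4)]
        boxes[s] = Box2D(*mean)
    return SpineTrack3D.from_boxes(spine_id=spine_id, boxes_by_slice=boxes)


def cluster_annotations(
    tracks_by_annotator: Sequence[Sequence[SpineTrack3D]],
    iom_threshold: float = 0.5,
    config: PipelineConfig | None = None,
) -> list[ConsensusCluster]:
    """Single-linkage clustering of annotator tracks by combined 3D IoM.

    Edges join tracks from *different* annotators whose :func:`iom_3d`
    reaches the threshold.  Within a connected component each annotator may
    contribute at most one track: when several tracks of one annotator land in
    a component, the one with the highest IoM to the other annotators' members
    stays and the rest are split out as singleton clusters.  Every input track
    ends up in exactly one cluster.
    """
    if not tracks_by_annotator:
        raise ValueError("need at least one annotator")
    cfg = config or PipelineConfig()
    nodes = [
        (a, t)
        for a, tracks in enumerate(tracks_by_annotator)
        for t in tracks
    ]
    n = len(nodes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    score = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if nodes[i][0] == nodes[j][0]:
                continue
            s = iom_3d(nodes[i][1], nodes[j][1], z_convention=cfg.z_length_convention)
            score[i][j] = score[j][i] = s
            if s >= iom_threshold:
                union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)

    groups: list[list[int]] = []
    for root in sorted(components):
        comp = components[root]
        by_ann: dict[int, list[int]] = {}
        for i in comp:
            by_ann.setdefault(nodes[i][0], []).append(i)
        kept: list[int] = []
        split: list[int] = []
        for a, idxs in sorted(by_ann.items()):
            if len(idxs) == 1:
                kept.extend(idxs)
                continue
            # duplicate-annotator repair: keep the track best linked to the
            # rest of the component, split the others out
            others = [j for j in comp if nodes[j][0] != a]

            def link(i: int) -> float:
                return max((score[i][j] for j in others), default=0.0)

            best = max(idxs, key=lambda i: (link(i), -i))
            kept.append(best)
            split.extend(i for i in idxs if i != best)
        groups.append(sorted(kept))
        groups.extend([i] for i in sorted(split))

    clusters = []
    for cid, grp in enumerate(groups):
        members = [(nodes[i][0], nodes[i][1]) for i in grp]
        rep = _representative([t for _, t in members], spine_id=cid)
        clusters.append(ConsensusCluster(members=members, representative=rep))
    return clusters


def fuse_ground_truth(
    clusters: Sequence[ConsensusCluster], k: int
) -> list[SpineTrack3D]:
    """Representatives of clusters supported by at least ``k`` annotators.

    For five annotators, k=1 is the minimal, k=3 the majority and k=5 the
    maximal ground truth.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return [c.representative for c in clusters if c.support >= k]


def consensus_ground_truths(
    annotations: Sequence[AnnotationSet],
    ks: Sequence[int] = (1, 3, 5),
    config: PipelineConfig | None = None,
) -> dict[int, list[SpineTrack3D]]:
    """Convenience: annotator sets -> {k: fused ground truth} in one call."""
    cfg = config or PipelineConfig()
    tracks = [build_annotator_tracks(a, cfg) for a in annotations]
    clusters = cluster_annotations(tracks, cfg.eval_iom_threshold, cfg)
    return {k: fuse_ground_truth(clusters, k) for k in ks}
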