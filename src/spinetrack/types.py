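"""Core domain types for dendritic-spine detection in image stacks.

Coordinate conventions
----------------------
Boxes live in continuous pixel coordinates with the origin at the image's
top-left corner, x increasing rightward and y increasing downward.  Box
semantics are half-open: ``area = (x_max - x_min) * (y_max - y_min)`` with no
±1 pixel adjustments anywhere.  Slice indices are 0-based.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Box2D",
    "Detection2D",
    "SpineTrack3D",
    "ImageStack",
    "AnnotationSet",
    "PipelineConfig",
]


@dataclass(frozen=True)
class Box2D:
    """An axis-aligned rectangle in slice coordinates.

    The atom of both detection and annotation: every spine in a single
    optical slice is represented by its minimal bounding rectangle.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"box coordinates must be finite, got {vals}")
        if min(vals) < 0:
            raise ValueError(f"box coordinates must be >= 0, got {vals}")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box: need x_max > x_min and y_max > y_min, got {vals}"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    @staticmethod
    def from_xywh(x: float, y: float, w: float, h: float) -> "Box2D":
        return Box2D(x, y, x + w, y + h)


@dataclass(frozen=True)
class Detection2D:
    """A :class:`Box2D` on a specific slice with a detection confidence."""

    box: Box2D
    slice_index: int
    confidence: float

    def __post_init__(self) -> None:
        if self.slice_index < 0:
            raise ValueError(f"slice_index must be >= 0, got {self.slice_index}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass
class SpineTrack3D:
    """One spine across depth: a z-interval plus one box per covered slice.

    ``z_first``/``z_second`` are inclusive slice indices.  After gap
    interpolation ``boxes_by_slice`` covers every slice of the interval.
    ``mean_box`` is the coordinate-wise average of the per-slice boxes.
    """

    spine_id: int
    z_first: int
    z_second: int
    boxes_by_slice: dict[int, Box2D]
    mean_box: Box2D
    confidence: float = 1.0
    interpolated_slices: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.z_second < self.z_first:
            raise ValueError(
                f"need z_second >= z_first, got [{self.z_first}, {self.z_second}]"
            )
        covered = set(self.boxes_by_slice)
        expected = set(range(self.z_first, self.z_second + 1))
        if covered != expected:
            raise ValueError(
                f"boxes_by_slice must cover every slice of [{self.z_first}, "
                f"{self.z_second}]; missing {sorted(expected - covered)}, "
                f"extra {sorted(covered - expected)}"
            )

    @property
    def n_slices(self) -> int:
        return self.z_second - self.z_first + 1

    @property
    def z_interval(self) -> tuple[int, int]:
        return (self.z_first, self.z_second)

    @staticmethod
    def from_boxes(
        spine_id: int,
        boxes_by_slice: dict[int, Box2D],
        confidence: float = 1.0,
        interpolated_slices: frozenset[int] = frozenset(),
    ) -> "SpineTrack3D":
        """Build a track from a contiguous slice->box mapping, computing mean_box."""
        if not boxes_by_slice:
            raise ValueError("a track needs at least one box")
        z1, z2 = min(boxes_by_slice), max(boxes_by_slice)
        coords = np.array(
            [boxes_by_slice[z].as_tuple() for z in range(z1, z2 + 1)], dtype=float
        )
        mean = coords.mean(axis=0)
        return SpineTrack3D(
            spine_id=spine_id,
            z_first=z1,
            z_second=z2,
            boxes_by_slice=dict(boxes_by_slice),
            mean_box=Box2D(*mean),
            confidence=confidence,
            interpolated_slices=interpolated_slices,
        )


@dataclass
class ImageStack:
    """An ordered list of same-shape 2D grayscale slices with voxel geometry."""

    slices: list[np.ndarray]
    pixel_size_um: float = 0.1
    z_step_um: float = 0.5

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("a stack needs at least one slice")
        shape0 = self.slices[0].shape
        for i, s in enumerate(self.slices):
            if s.ndim != 2:
                raise ValueError(f"slice {i} is not 2D (shape {s.shape})")
            if s.shape != shape0:
                raise ValueError(
                    f"inconsistent slice shapes: slice 0 is {shape0}, slice {i} is {s.shape}"
                )

    @property
    def depth(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    def as_array(self) -> np.ndarray:
        return np.stack(self.slices, axis=0)

    def max_projection(self) -> np.ndarray:
        """Maximum intensity projection over depth."""
        return self.as_array().max(axis=0)


@dataclass
class AnnotationSet:
    """Per-annotator labeled boxes for a stack: a list of (slice, box) pairs."""

    annotator_id: str
    boxes: list[tuple[int, Box2D]] = field(default_factory=list)

    def boxes_on_slice(self, slice_index: int) -> list[Box2D]:
        return [b for s, b in self.boxes if s == slice_index]

    def by_slice(self) -> dict[int, list[Box2D]]:
        out: dict[int, list[Box2D]] = {}
        for s, b in self.boxes:
            out.setdefault(s, []).append(b)
        return out

    def __len__(self) -> int:
        return len(self.boxes)


_OVERLAP_FIELDS = (
    "confidence_threshold",
    "duplicate_iom_threshold",
    "track_match_threshold",
    "eval_iom_threshold",
)


@dataclass
class PipelineConfig:
    """All tunable constants of the detection/tracking/evaluation pipeline.

    Defaults are the pipeline's published operating point: detections kept at
    confidence > 0.5, same-slice duplicates suppressed at IoM > 0.5, boxes
    above 2000 px^2 discarded, tracks matched slice-to-slice at IoM > 0.5,
    tracks surviving one missed slice but not two, 3D evaluation at combined
    IoM >= 0.5 with the xy term weighted by beta = 0.5.
    """

    confidence_threshold: float = 0.5
    duplicate_iom_threshold: float = 0.5
    area_threshold_px: float = 2000.0
    track_match_threshold: float = 0.5
    max_consecutive_misses: int = 2
    eval_iom_threshold: float = 0.5
    beta: float = 0.5
    z_length_convention: Literal["slice_count", "literal"] = "slice_count"
    matching_mode: Literal["existential", "one_to_one"] = "existential"
    interpolate_gaps: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in _OVERLAP_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.area_threshold_px <= 0:
            raise ValueError("area_threshold_px must be > 0")
        if self.max_consecutive_misses < 0:
            raise ValueError("max_consecutive_misses must be >= 0")
        if self.z_length_convention not in ("slice_count", "literal"):
            raise ValueError(f"unknown z_length_convention {self.z_length_convention!r}")
        if self.matching_mode not in ("existential", "one_to_one"):
            raise ValueError(f"unknown matching_mode {self.matching_mode!r}")

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "confidence_threshold": self.confidence_threshold,
            "duplicate_iom_threshold": self.duplicate_iom_threshold,
            "area_threshold_px": self.area_threshold_px,
            "track_match_threshold": self.track_match_threshold,
            "max_consecutive_misses": self.max_consecutive_misses,
            "eval_iom_threshold": self.eval_iom_threshold,
            "beta": self.beta,
            "z_length_convention": self.z_length_convention,
            "matching_mode": self.matching_mode,
            "interpolate_gaps": self.interpolate_gaps,
            "random_seed": self.random_seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        return PipelineConfig(**d)

    @staticmethod
    def from_file(path) -> "PipelineConfig":
        """Load from a YAML or JSON file mirroring the field names."""
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return PipelineConfig.from_dict(yaml.safe_load(text) or {})
        return PipelineConfig.from_dict(json.loads(text))


def detections_by_slice(
    detections: Sequence[Detection2D], depth: int | None = None
) -> dict[int, list[Detection2D]]:
    """Group detections by slice index (all slices 0..depth-1 present if given)."""
    out: dict[int, list[Detection2D]] = {}
    if depth is not None:
        out = {i: [] for i in range(depth)}
    for d in detections:
        out.setdefault(d.slice_index, []).append(d)
    return out
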