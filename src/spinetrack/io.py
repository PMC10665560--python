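"""Readers and writers for stacks, annotations, detections and tracks.

On-disk formats:

* **Image stacks** — a multi-page TIFF, or a directory of single-slice
  PNG/TIFF images read in lexicographic filename order.
* **VIA annotations** — the VGG Image Annotator project JSON export;
  rectangle regions with ``x, y, width, height`` shape attributes.  The slice
  index is the trailing integer of the filename stem (``stack_s007.png`` is
  slice 7).
* **Detection CSV** — header ``slice,x_min,y_min,x_max,y_max,confidence``;
  rows sorted by (slice, confidence descending) on write; round-trips are
  lossless to 6 decimal places.
* **Track CSV** — header
  ``spine_id,slice,x_min,y_min,x_max,y_max,interpolated,confidence`` with one
  row per (track, slice).

Slice indices are 0-based everywhere.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from imageio import v3 as iio

from .types import AnnotationSet, Box2D, Detection2D, ImageStack, SpineTrack3D

logger = logging.getLogger(__name__)

__all__ = [
    "read_stack",
    "write_stack",
    "clip_intensity",
    "read_via_annotations",
    "write_via_annotations",
    "slice_index_from_filename",
    "read_detections_csv",
    "write_detections_csv",
    "read_annotations_csv",
    "write_annotations_csv",
    "read_tracks_csv",
    "write_tracks_csv",
]

_SLICE_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")

DETECTION_COLUMNS = ["slice", "x_min", "y_min", "x_max", "y_max", "confidence"]
TRACK_COLUMNS = [
    "spine_id",
    "slice",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "interpolated",
    "confidence",
]


# ---------------------------------------------------------------------------
# image stacks


def read_stack(
    path, pixel_size_um: float = 0.1, z_step_um: float = 0.5
) -> ImageStack:
    """Read a multi-page TIFF or a directory of single-slice images.

    Directory slices are ordered lexicographically by filename.  Pixel values
    are converted to float64 without any value transformation.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in _SLICE_IMAGE_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no slice images found in {p}")
        slices = [np.asarray(iio.imread(f), dtype=np.float64) for f in files]
    elif p.is_file():
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None, ...]
        if arr.ndim != 3:
            raise ValueError(f"expected a stack of 2D grayscale frames, got shape {arr.shape}")
        slices = [np.asarray(a, dtype=np.float64) for a in arr]
    else:
        raise FileNotFoundError(f"no such file or directory: {p}")
    return ImageStack(slices=slices, pixel_size_um=pixel_size_um, z_step_um=z_step_um)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as an 8-bit multi-page TIFF."""
    arr = np.clip(np.rint(stack.as_array()), 0, 255).astype(np.uint8)
    tifffile.imwrite(Path(path), arr)


def clip_intensity(stack: ImageStack, max_value: float = 255.0) -> ImageStack:
    """Clip every pixel at ``max_value``; values below are unchanged.

    Idempotent: clipping twice equals clipping once.
    """
    if max_value <= 0:
        raise ValueError(f"max_value must be > 0, got {max_value}")
    return ImageStack(
        slices=[np.minimum(s, max_value) for s in stack.slices],
        pixel_size_um=stack.pixel_size_um,
        z_step_um=stack.z_step_um,
    )


# ---------------------------------------------------------------------------
# VIA annotations

_TRAILING_INT = re.compile(r"(\d+)$")


def slice_index_from_filename(filename: str) -> int:
    """Slice index encoded as the trailing integer of the filename stem."""
    stem = Path(filename).stem
    m = _TRAILING_INT.search(stem)
    if m is None:
        raise ValueError(f"cannot infer slice index from filename {filename!r}")
    return int(m.group(1))


def read_via_annotations(json_document, annotator_id: str = "annotator") -> AnnotationSet:
    """Parse a VIA project JSON export into an :class:`AnnotationSet`.

    ``json_document`` may be a path, a JSON string, or an already-parsed
    dict.  Only rectangle regions are imported; other shapes are skipped
    with a logged warning.  The box is (x, y, x+width, y+height).
    """
    if isinstance(json_document, dict):
        doc = json_document
    else:
        text = None
        p = Path(str(json_document))
        try:
            if p.is_file():
                text = p.read_text()
        except OSError:
            text = None
        if text is None:
            text = str(json_document)
        doc = json.loads(text)
    # VIA exports either {"_via_img_metadata": {...}} or the metadata mapping
    # directly, keyed by "filename + size".
    meta = doc.get("_via_img_metadata", doc)
    boxes: list[tuple[int, Box2D]] = []
    skipped = 0
    for entry in meta.values():
        if not isinstance(entry, dict) or "filename" not in entry:
            continue
        slice_index = slice_index_from_filename(entry["filename"])
        for region in entry.get("regions", []):
            shape = region.get("shape_attributes", {})
            if shape.get("name") != "rect":
                skipped += 1
                continue
            try:
                x, y = float(shape["x"]), float(shape["y"])
                w, h = float(shape["width"]), float(shape["height"])
            except KeyError as e:
                raise ValueError(f"rect region missing shape attribute {e}") from e
            boxes.append((slice_index, Box2D(x, y, x + w, y + h)))
    if skipped:
        logger.warning("skipped %d non-rectangle VIA regions", skipped)
    ann = AnnotationSet(annotator_id=annotator_id, boxes=boxes)
    ann.skipped_regions = skipped  # type: ignore[attr-defined]
    return ann


def write_via_annotations(
    ann: AnnotationSet, path=None, filename_pattern: str = "slice_{:04d}.png"
) -> dict:
    """Serialize an :class:`AnnotationSet` as a VIA project JSON document.

    Returns the document; also writes it to ``path`` when given.  Re-importing
    reproduces the input rectangles exactly.
    """
    meta: dict[str, dict] = {}
    for s, b in ann.boxes:
        fname = filename_pattern.format(s)
        key = f"{fname}-1"
        entry = meta.setdefault(
            key, {"filename": fname, "size": -1, "regions": [], "file_attributes": {}}
        )
        entry["regions"].append(
            {
                "shape_attributes": {
                    "name": "rect",
                    "x": b.x_min,
                    "y": b.y_min,
                    "width": b.width,
                    "height": b.height,
                },
                "region_attributes": {},
            }
        )
    doc = {"_via_img_metadata": meta}
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


# ---------------------------------------------------------------------------
# detection / annotation / track CSV dialects


def write_detections_csv(dets: Sequence[Detection2D], path) -> None:
    """Write detections sorted by (slice, confidence descending)."""
    rows = sorted(dets, key=lambda d: (d.slice_index, -d.confidence))
    df = pd.DataFrame(
        [
            {
                "slice": d.slice_index,
                "x_min": d.box.x_min,
                "y_min": d.box.y_min,
                "x_max": d.box.x_max,
                "y_max": d.box.y_max,
                "confidence": d.confidence,
            }
            for d in rows
        ],
        columns=DETECTION_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_detections_csv(path) -> list[Detection2D]:
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Detection2D(
                box=Box2D(row.x_min, row.y_min, row.x_max, row.y_max),
                slice_index=int(row.slice),
                confidence=float(row.confidence),
            )
        )
    return out


def write_annotations_csv(ann: AnnotationSet, path) -> None:
    """Flat CSV dialect for annotations: slice,x_min,y_min,x_max,y_max."""
    df = pd.DataFrame(
        [
            {"slice": s, "x_min": b.x_min, "y_min": b.y_min, "x_max": b.x_max, "y_max": b.y_max}
            for s, b in sorted(ann.boxes, key=lambda sb: sb[0])
        ],
        columns=["slice", "x_min", "y_min", "x_max", "y_max"],
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_annotations_csv(path, annotator_id: str = "annotator") -> AnnotationSet:
    df = pd.read_csv(path)
    boxes = [
        (int(r.slice), Box2D(r.x_min, r.y_min, r.x_max, r.y_max))
        for r in df.itertuples(index=False)
    ]
    return AnnotationSet(annotator_id=annotator_id, boxes=boxes)


def write_tracks_csv(tracks: Sequence[SpineTrack3D], path) -> None:
    rows = []
    for t in sorted(tracks, key=lambda t: t.spine_id):
        for s in range(t.z_first, t.z_second + 1):
            b = t.boxes_by_slice[s]
            rows.append(
                {
                    "spine_id": t.spine_id,
                    "slice": s,
                    "x_min": b.x_min,
                    "y_min": b.y_min,
                    "x_max": b.x_max,
                    "y_max": b.y_max,
                    "interpolated": int(s in t.interpolated_slices),
                    "confidence": t.confidence,
                }
            )
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_tracks_csv(path) -> list[SpineTrack3D]:
    df = pd.read_csv(path)
    missing = {"spine_id", "slice", "x_min", "y_min", "x_max", "y_max"} - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    tracks = []
    for sid, grp in df.groupby("spine_id", sort=True):
        boxes = {
            int(r.slice): Box2D(r.x_min, r.y_min, r.x_max, r.y_max)
            for r in grp.itertuples(index=False)
        }
        interp = (
            frozenset(int(r.slice) for r in grp.itertuples(index=False) if getattr(r, "interpolated", 0))
            if "interpolated" in df.columns
            else frozenset()
        )
        conf = float(grp["confidence"].max()) if "confidence" in df.columns else 1.0
        tracks.append(
            SpineTrack3D.from_boxes(
                spine_id=int(sid),
                boxes_by_slice=boxes,
                confidence=conf,
                interpolated_slices=interp,
            )
        )
    return tracks
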