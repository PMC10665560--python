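"""Pluggable 2D detector contract plus region-proposal training geometry.

The spine detector proper is any callable mapping a 2D grayscale image to a
list of :class:`~spinetrack.types.Detection2D`.  A classical reference
detector (smoothing, background subtraction, thresholding, connected
components, shape filtering) is registered under the name ``"reference"`` so
the full pipeline can run without a trained network; adapters wrapping a CNN
can be registered the same way.

Also here: the anchor-grid generator and the region-proposal label-assignment
rule used when training such networks, the eight-orientation (dihedral)
augmentation with Gaussian noise/blur, and the combined-loss arithmetic
L = (L_obj^RPN + a*L_regr^RPN) + (L_obj^BoxC + a*L_regr^BoxC) + l*L_regu
with a = 2 and l = 3e-6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .types import Box2D, Detection2D

__all__ = [
    "AnchorConfig",
    "TrainingConstants",
    "ReferenceDetectorParams",
    "generate_anchors",
    "anchor_count",
    "assign_anchor_labels",
    "enumerate_orientations",
    "orientation_ops",
    "transform_box",
    "augment",
    "combine_losses",
    "reference_detect",
    "get_detector",
    "register_detector",
    "detect_stack",
]

Detector = Callable[[np.ndarray], list[Detection2D]]


@dataclass(frozen=True)
class AnchorConfig:
    """Anchor-grid geometry for a region proposal network.

    At every stride-grid center, one box per (scale, aspect ratio) is placed
    with base side scale*stride, width base*sqrt(ratio) and height
    base/sqrt(ratio); boxes may extend past the image (unclipped).
    """

    scales: tuple[float, ...] = (8.0,)
    strides: tuple[int, ...] = (4, 8, 16, 32, 64)
    aspect_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    image_size: tuple[int, int] = (512, 512)  # (height, width)

    def __post_init__(self) -> None:
        if not all(s > 0 for s in self.scales):
            raise ValueError("scales must be positive")
        if not all(s > 0 for s in self.strides):
            raise ValueError("strides must be positive")
        if not all(r > 0 for r in self.aspect_ratios):
            raise ValueError("aspect ratios must be positive")
        if not all(d > 0 for d in self.image_size):
            raise ValueError("image_size must be positive")


@dataclass(frozen=True)
class TrainingConstants:
    """Published training constants, kept as documented immutable defaults."""

    alpha: float = 2.0  # regression-loss weight relative to objectness
    lam: float = 3e-6  # L2 regularization weight
    momentum: float = 0.6
    learning_rate: float = 1e-3
    n_rpn: int = 1000
    n_boxc: int = 80
    rpn_pos_iou: float = 0.7
    rpn_neg_iou: float = 0.3
    nms_iou: float = 0.7


def anchor_count(cfg: AnchorConfig) -> int:
    """Closed-form anchor count: |ratios|*|scales|*sum_s floor(W/s)*floor(H/s)."""
    h, w = cfg.image_size
    return (
        len(cfg.aspect_ratios)
        * len(cfg.scales)
        * sum((w // s) * (h // s) for s in cfg.strides)
    )


def generate_anchors(cfg: AnchorConfig) -> list[tuple[float, float, float, float]]:
    """Enumerate the anchor grid of ``cfg`` as (x_min, y_min, x_max, y_max).

    Anchors near the border legitimately extend past the image edges (they
    are not clipped) and may carry negative coordinates, so they are returned
    as plain coordinate tuples rather than :class:`Box2D` instances, whose
    invariants require non-negative coordinates.
    """
    h, w = cfg.image_size
    anchors: list[tuple[float, float, float, float]] = []
    for s in cfg.strides:
        nx, ny = w // s, h // s
        for j in range(ny):
            cy = s / 2 + j * s
            for i in range(nx):
                cx = s / 2 + i * s
                for scale in cfg.scales:
                    base = scale * s
                    for r in cfg.aspect_ratios:
                        bw = base * math.sqrt(r)
                        bh = base / math.sqrt(r)
                        anchors.append(
                            (cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2)
                        )
    return anchors


def _iou_tuples(a: tuple, b: tuple) -> float:
    ox = min(a[2], b[2]) - max(a[0], b[0])
    oy = min(a[3], b[3]) - max(a[1], b[1])
    inter = max(0.0, ox) * max(0.0, oy)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def assign_anchor_labels(
    anchors: Sequence[tuple],
    gts: Sequence[Box2D],
    pos_iou: float = 0.7,
    neg_iou: float = 0.3,
    rule: Literal["printed", "standard"] = "printed",
) -> list[str]:
    """Label anchors ``positive`` / ``negative`` / ``ignore`` for RPN training.

    ``printed`` rule: for each ground truth, only its highest-IoU anchor is
    positive, and only if that IoU reaches ``pos_iou``; anchors below
    ``neg_iou`` against every ground truth are negative; the rest are ignored.

    ``standard`` rule (usual Faster R-CNN): additionally, any anchor with
    IoU >= ``pos_iou`` to some ground truth is positive, and each ground
    truth's argmax anchor is positive regardless of the threshold.
    """
    if not (0.0 <= neg_iou < pos_iou <= 1.0):
        raise ValueError("need 0 <= neg_iou < pos_iou <= 1")
    n = len(anchors)
    if not gts:
        return ["negative"] * n
    gt_tuples = [g.as_tuple() for g in gts]
    iou = np.array(
        [[_iou_tuples(a, g) for g in gt_tuples] for a in anchors], dtype=float
    )
    labels = ["ignore"] * n
    max_per_anchor = iou.max(axis=1)
    for i in range(n):
        if max_per_anchor[i] < neg_iou:
            labels[i] = "negative"
    for j in range(len(gts)):
        best = int(iou[:, j].argmax())
        if rule == "printed":
            if iou[best, j] >= pos_iou:
                labels[best] = "positive"
        else:
            labels[best] = "positive"
    if rule == "standard":
        for i in range(n):
            if max_per_anchor[i] >= pos_iou:
                labels[i] = "positive"
    return labels


# ---------------------------------------------------------------------------
# dihedral augmentation

# The 8 orientations of the square: rotate counter-clockwise by 90*k degrees,
# optionally followed by a horizontal (left-right) flip.
ORIENTATIONS: list[tuple[int, bool]] = [(k, f) for k in range(4) for f in (False, True)]


def orientation_ops(image: np.ndarray, k: int, flip: bool) -> np.ndarray:
    out = np.rot90(image, k)
    return np.fliplr(out) if flip else out


def enumerate_orientations(image: np.ndarray) -> list[np.ndarray]:
    """The 8 images of the dihedral group (rotations x flips).

    For a generic asymmetric image all 8 arrays are pairwise distinct; for a
    fully symmetric image they coincide.  Non-square images are allowed and
    transpose their shape under odd rotations.
    """
    return [orientation_ops(image, k, f) for k, f in ORIENTATIONS]


def _transform_point(x: float, y: float, k: int, flip: bool, shape) -> tuple[float, float]:
    h, w = shape[:2]
    for _ in range(k % 4):  # one CCW quarter turn: (x, y) -> (y, w - x)
        x, y = y, w - x
        h, w = w, h
    if flip:
        x = w - x
    return x, y


def transform_box(box: Box2D, k: int, flip: bool, shape) -> Box2D:
    """Map a box through an orientation; corners re-sorted to a valid box.

    All 8 orientations are isometries, so box areas are preserved exactly.
    """
    corners = [
        _transform_point(x, y, k, flip, shape)
        for x in (box.x_min, box.x_max)
        for y in (box.y_min, box.y_max)
    ]
    xs = [c[0] for c in corners]
    ys = [c[1] for c in corners]
    return Box2D(min(xs), min(ys), max(xs), max(ys))


def augment(
    image: np.ndarray,
    boxes: Sequence[Box2D],
    rng: np.random.Generator,
    noise_sigma: float = 5.0,
    blur_sigma: float = 1.0,
    clip_max: float = 255.0,
) -> tuple[np.ndarray, list[Box2D]]:
    """One training-time augmentation draw.

    A uniformly chosen orientation of the 8 is applied to image and boxes,
    then Gaussian white noise and Gaussian blur are each applied with
    probability 0.5; the result is clipped to [0, clip_max].
    """
    k, flip = ORIENTATIONS[int(rng.integers(len(ORIENTATIONS)))]
    out = orientation_ops(image, k, flip).astype(float)
    new_boxes = [transform_box(b, k, flip, image.shape) for b in boxes]
    if rng.random() < 0.5:
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    if rng.random() < 0.5:
        out = ndimage.gaussian_filter(out, blur_sigma)
    return np.clip(out, 0.0, clip_max), new_boxes


def combine_losses(
    l_obj_rpn: float,
    l_regr_rpn: float,
    l_obj_boxc: float,
    l_regr_boxc: float,
    l_regu: float,
    constants: TrainingConstants | None = None,
) -> float:
    """Total training loss: both stage losses (regression weighted by alpha)
    plus lambda times the L2 regularization term."""
    c = constants or TrainingConstants()
    return (
        (l_obj_rpn + c.alpha * l_regr_rpn)
        + (l_obj_boxc + c.alpha * l_regr_boxc)
        + c.lam * l_regu
    )


# ---------------------------------------------------------------------------
# classical reference detector


@dataclass(frozen=True)
class ReferenceDetectorParams:
    """Knobs of the classical blob detector; defaults tuned on the simulator."""

    smooth_sigma: float = 1.5
    background_sigma: float = 25.0
    threshold: float = 25.0  # gray levels above local background
    min_area_px: float = 20.0
    max_area_px: float = 2000.0
    max_elongation: float = 3.5  # major/minor axis ratio cap (rejects shafts)


def reference_detect(
    image: np.ndarray, params: ReferenceDetectorParams | None = None
) -> list[Detection2D]:
    """Classical single-slice spine detector.

    Gaussian smoothing, large-kernel background subtraction, intensity
    thresholding, connected components; components that are too small, too
    large or too elongated (dendritic shafts) are discarded.  Each surviving
    component yields its bounding box with confidence = peak original
    intensity / 255.  Deterministic.
    """
    p = params or ReferenceDetectorParams()
    img = np.asarray(image, dtype=float)
    smooth = ndimage.gaussian_filter(img, p.smooth_sigma)
    background = ndimage.gaussian_filter(img, p.background_sigma)
    response = smooth - background
    mask = response > p.threshold
    labels = measure.label(mask, connectivity=2)
    dets: list[Detection2D] = []
    for region in measure.regionprops(labels, intensity_image=img):
        if not (p.min_area_px <= region.area <= p.max_area_px):
            continue
        minor = max(region.axis_minor_length, 1.0)
        if region.axis_major_length / minor > p.max_elongation:
            continue
        minr, minc, maxr, maxc = region.bbox
        conf = float(np.clip(region.intensity_max / 255.0, 0.0, 1.0))
        dets.append(
            Detection2D(
                box=Box2D(float(minc), float(minr), float(maxc), float(maxr)),
                slice_index=0,
                confidence=conf,
            )
        )
    return dets


_DETECTOR_REGISTRY: dict[str, Detector] = {}


def register_detector(name: str, fn: Detector) -> None:
    _DETECTOR_REGISTRY[name] = fn


def get_detector(name: str) -> Detector:
    try:
        return _DETECTOR_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown detector {name!r}; registered: {sorted(_DETECTOR_REGISTRY)}"
        ) from None


register_detector("reference", reference_detect)


def detect_stack(stack, detector: str | Detector = "reference") -> list[Detection2D]:
    """Run a per-slice detector over a stack, fixing slice indices."""
    fn = get_detector(detector) if isinstance(detector, str) else detector
    out: list[Detection2D] = []
    for s, img in enumerate(stack.slices):
        for d in fn(img):
            out.append(Detection2D(box=d.box, slice_index=s, confidence=d.confidence))
    return out
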